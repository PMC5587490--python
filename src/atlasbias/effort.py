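"""Poisson regression of volunteer sampling effort on accessibility and
attractiveness covariates, with overdispersion-corrected inference and a
spatial-residual diagnostic.

Visit counts per pentad are modelled with a log-link Poisson GLM per group
(province analogue).  Predictors: log hub distance (natural log, km), road
distance (km), protected / urban / cultivated cover fractions, and the three
climate variables standardized within the group.  Inference is
quasi-Poisson: the Pearson chi-square dispersion scales the standard errors,
and t-values are referred to the t distribution on residual degrees of
freedom.  Spatial structure in the residuals is diagnosed with Moran's I
under a permutation null rather than being absorbed into a correlated random
effect, so the reported inference is approximate whenever the diagnostic
flags autocorrelation; point estimates are unaffected by that choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .atlas_io import haversine_km

PREDICTORS = (
    "log_dist_hub",
    "dist_road",
    "protected",
    "urban",
    "cultivated",
    "precip",
    "t_summer",
    "t_winter",
)

#: significance stars used in the fit report
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


class RankDeficientError(ValueError):
    """The design matrix is not full rank."""


@dataclass
class EffortDesign:
    """Response, predictors, grouping and coordinates for the effort model.

    ``frame`` must contain ``n_lists`` plus the columns in
    :data:`PREDICTORS`; ``group`` and coordinates align with its index.  Hub
    pentads must already be excluded (they have zero hub distance, which the
    log transform cannot represent).
    """

    frame: pd.DataFrame
    group: pd.Series | None = None
    coords: np.ndarray | None = None  # (n, 2) midpoint (lat, lon)
    predictors: tuple[str, ...] = PREDICTORS

    def __post_init__(self) -> None:
        needed = ("n_lists",) + tuple(self.predictors)
        missing = [c for c in needed if c not in self.frame.columns]
        if missing:
            raise ValueError(f"effort design missing columns: {missing}")
        y = self.frame["n_lists"].to_numpy()
        if (y < 0).any():
            raise ValueError("visit counts must be non-negative")
        if self.predictors and not np.all(
            np.isfinite(self.frame[list(self.predictors)].to_numpy(dtype=float))
        ):
            raise ValueError("predictors contain non-finite values")

    def groups(self) -> dict[str, pd.DataFrame]:
        if self.group is None:
            return {"all": self.frame}
        return {
            g: self.frame.loc[idx]
            for g, idx in self.frame.groupby(self.group.loc[self.frame.index]).groups.items()
        }


@dataclass
class EffortFit:
    """Quasi-Poisson fit summary for one group."""

    group: str
    coefficients: pd.Series
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    dispersion: float
    df_resid: int
    vif: pd.Series
    converged: bool
    n_obs: int
    deviance: float
    pearson_residuals: pd.Series = field(repr=False, default=None)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats

        tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        lo = self.coefficients - tcrit * self.std_errors
        hi = self.coefficients + tcrit * self.std_errors
        return pd.DataFrame({"lower": lo, "upper": hi})


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the columns involved in the deficiency via correlation of
        # residuals from a QR pivot
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [names[j] for j in np.flatnonzero(diag < tol)]
        raise RankDeficientError(
            f"design matrix rank {rank} < {x.shape[1]}; collinear columns: {bad or names}"
        )


def fit_poisson_glm(
    design: EffortDesign,
    standardize_climate: bool = True,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> dict[str, EffortFit]:
    """Fit the log-link Poisson effort model for each group.

    Climate predictors are standardized within the group before fitting;
    coefficients are reported on that standardized scale.  Standard errors
    are scaled by the square root of the Pearson chi-square dispersion
    (quasi-Poisson), and t-values / two-sided p-values use the t distribution
    on residual degrees of freedom.
    """
    out: dict[str, EffortFit] = {}
    preds = list(design.predictors)
    for name, frame in design.groups().items():
        df = frame.copy()
        if standardize_climate:
            for col in ("precip", "t_summer", "t_winter"):
                if col not in preds:
                    continue
                x = df[col].to_numpy(dtype=float)
                sd = x.std(ddof=1)
                if sd == 0:
                    raise ValueError(
                        f"group {name!r}: climate variable {col} is constant"
                    )
                df[col] = (x - x.mean()) / sd
        y = df["n_lists"].to_numpy(dtype=float)
        x_mat = sm.add_constant(
            df[preds].to_numpy(dtype=float).reshape(len(df), len(preds)),
            has_constant="add",
        )
        names = ["intercept"] + preds
        if len(y) <= x_mat.shape[1]:
            raise ValueError(
                f"group {name!r}: {len(y)} rows for {x_mat.shape[1]} parameters"
            )
        _check_rank(x_mat, names)
        model = sm.GLM(y, x_mat, family=sm.families.Poisson())
        res = model.fit(maxiter=maxiter, tol=tol, scale="X2", use_t=True)
        if not res.converged:
            raise RuntimeError(
                f"group {name!r}: IRLS did not converge in {maxiter} iterations "
                f"(deviance {res.deviance:.6g})"
            )
        idx = pd.Index(names)
        out[name] = EffortFit(
            group=name,
            coefficients=pd.Series(res.params, index=idx),
            std_errors=pd.Series(res.bse, index=idx),
            t_values=pd.Series(res.tvalues, index=idx),
            p_values=pd.Series(res.pvalues, index=idx),
            dispersion=float(res.scale),
            df_resid=int(res.df_resid),
            vif=variance_inflation(df[preds]) if len(preds) > 1 else pd.Series(dtype=float),
            converged=bool(res.converged),
            n_obs=len(y),
            deviance=float(res.deviance),
            pearson_residuals=pd.Series(res.resid_pearson, index=df.index),
        )
    return out


def variance_inflation(predictors: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R²_j) from regressing predictor j on the others.

    Perfect collinearity is reported as ``inf`` rather than raised.
    """
    x = predictors.to_numpy(dtype=float)
    n, p = x.shape
    out = {}
    for j, col in enumerate(predictors.columns):
        yj = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class MoranResult:
    """Moran's I of model residuals with a permutation p-value."""

    statistic: float | None
    expected: float
    p_value: float | None
    n_perm: int
    reason: str | None = None


def morans_i(
    residuals: np.ndarray | pd.Series,
    coordinates: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Moran's I with inverse-distance, row-standardized weights.

    Weights are 1/d(i,j) (great-circle km), zero diagonal, rows standardized
    to sum to one.  The p-value is a one-sided (positive autocorrelation)
    permutation p over ``n_perm`` random relabelings of residuals across
    locations: ``(1 + #{I_perm >= I_obs}) / (n_perm + 1)``.
    """
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 locations for Moran's I")
    coords = np.asarray(coordinates, dtype=float).reshape(n, 2)
    if np.allclose(z, z[0]):
        return MoranResult(
            statistic=None,
            expected=-1.0 / (n - 1),
            p_value=None,
            n_perm=n_perm,
            reason="all residuals equal; Moran's I undefined",
        )
    lat, lon = coords[:, 0], coords[:, 1]
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    d = np.asarray(d, dtype=float)
    np.fill_diagonal(d, np.inf)
    w = 1.0 / d
    w /= w.sum(axis=1, keepdims=True)

    zc = z - z.mean()
    denom = np.sum(zc**2)

    def stat(v: np.ndarray) -> float:
        # row-standardized weights: sum(W) == n, so I = z'Wz / z'z
        return float(v @ (w @ v) / denom)

    i_obs = stat(zc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(zc)) >= i_obs:
            count += 1
    return MoranResult(
        statistic=i_obs,
        expected=-1.0 / (n - 1),
        p_value=(1 + count) / (n_perm + 1),
        n_perm=n_perm,
    )


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return "n.s."


def fit_report(fits: dict[str, EffortFit]) -> pd.DataFrame:
    """Per-group t-value table with significance stars.

    One row per group, one column per predictor; entries like ``"-6.69****"``
    or ``"1.41 n.s."`` (stars at p < .05 / .01 / .001 / .0001).
    """
    rows = {}
    for name, fit in fits.items():
        row = {}
        for pred in fit.t_values.index:
            if pred == "intercept":
                continue
            t = fit.t_values[pred]
            p = fit.p_values[pred]
            stars = significance_stars(p)
            sep = " " if stars == "n.s." else ""
            row[pred] = f"{t:.2f}{sep}{stars}"
        rows[name] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out
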