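"""Evenness of sampling effort across environmental zones.

For each zone, the pentads with at least one contributed list (geographical
coverage) and at least ten lists (repeated samples sufficient to model the
observation process) are counted.  Under geographically homogeneous effort
the expected number of sampled pentads in a zone is

    expected = (n_pentads_in_zone / total_pentads) * total_sampled_pentads,

and the likelihood-ratio goodness-of-fit statistic

    G = 2 * sum O_z * ln(O_z / E_z)

is referred to the chi-square distribution on (zones - 1) degrees of
freedom.  Zones are ranked by the observed-minus-expected deficit at each
intensity threshold.  Williams' small-sample correction to G is not applied;
per-biome tests are reported without multiple-testing adjustment by default
(a Holm flag is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas_io import ChecklistTable
from .zonation import ZonePartition

DEFAULT_THRESHOLDS = (1, 10)


@dataclass
class GTestResult:
    """Likelihood-ratio goodness-of-fit test outcome."""

    g: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


class ZoneEffortTable:
    """Per-zone sampling counts, expecteds and deficits at each threshold.

    ``frame`` is indexed by zone_id with columns ``n_pentads`` and, per
    threshold t, ``n_sampled_{t}``, ``expected_{t}``, ``deficit_{t}``.
    """

    def __init__(self, frame: pd.DataFrame, thresholds: tuple[int, ...]):
        self.frame = frame
        self.thresholds = tuple(thresholds)
        for t in self.thresholds:
            obs = frame[f"n_sampled_{t}"]
            if (obs > frame["n_pentads"]).any():
                raise ValueError("sampled counts exceed zone sizes")
            exp_sum = frame[f"expected_{t}"].sum()
            if abs(exp_sum - obs.sum()) > 1e-9 * max(1.0, obs.sum()):
                raise ValueError("expected frequencies do not sum to total sampled")

    def observed(self, threshold: int) -> pd.Series:
        return self.frame[f"n_sampled_{threshold}"]

    def expected(self, threshold: int) -> pd.Series:
        return self.frame[f"expected_{threshold}"]

    def deficit(self, threshold: int) -> pd.Series:
        return self.frame[f"deficit_{threshold}"]


def zone_sampling_counts(
    checklists: ChecklistTable,
    zones: ZonePartition,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
) -> ZoneEffortTable:
    """Aggregate per-pentad list counts to zones at each intensity threshold."""
    lists_per_pentad = checklists.lists_per_pentad()
    unknown = [p for p in lists_per_pentad.index if p not in zones.frame.index]
    if unknown:
        raise ValueError(
            f"checklist pentads missing from the zone partition: {unknown[:10]}"
        )
    zone_of = zones.zone_of()
    counts = lists_per_pentad.reindex(zones.frame.index, fill_value=0)
    frame = pd.DataFrame({"n_pentads": zones.zone_sizes()})
    total_pentads = int(frame["n_pentads"].sum())
    for t in thresholds:
        sampled = counts >= t
        obs = sampled.groupby(zone_of).sum().reindex(frame.index, fill_value=0)
        exp = expected_frequencies(
            frame["n_pentads"], total_pentads, int(sampled.sum())
        )
        frame[f"n_sampled_{t}"] = obs.astype(int)
        frame[f"expected_{t}"] = exp
        frame[f"deficit_{t}"] = obs - exp
    frame.index.name = "zone_id"
    return ZoneEffortTable(frame, thresholds)


def expected_frequencies(
    zone_sizes: pd.Series | np.ndarray, total_pentads: int, total_sampled: int
) -> pd.Series | np.ndarray:
    """Expected sampled pentads per zone under geographically even effort:
    ``(zone size / total pentads) * total sampled``."""
    sizes = np.asarray(zone_sizes, dtype=float)
    if total_pentads <= 0 or not np.isclose(sizes.sum(), total_pentads):
        raise ValueError("total_pentads must equal the sum of zone sizes and be > 0")
    exp = sizes / total_pentads * total_sampled
    if isinstance(zone_sizes, pd.Series):
        return pd.Series(exp, index=zone_sizes.index)
    return exp


def g_test(observed, expected) -> GTestResult:
    """G = 2 * sum O ln(O/E) with 0 ln 0 = 0; df = cells - 1; chi-square p."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and expected must be 1-d vectors of equal length >= 2")
    if np.any(exp <= 0):
        raise ValueError(
            "expected frequencies must be positive everywhere; pool small zones first"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * float(terms.sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(g, df))
    return GTestResult(g=g, df=df, p_value=p, observed=obs, expected=exp)


def per_biome_g_tests(
    table: ZoneEffortTable,
    zones: ZonePartition,
    threshold: int,
    holm: bool = False,
) -> pd.DataFrame:
    """G-test of evenness among each biome's climate zones.

    Expected frequencies are recomputed within the biome (zone sizes over the
    biome's pentads, times the biome's sampled total).  With ``holm=True``
    p-values get a Holm step-down adjustment.
    """
    zone_biome = (
        zones.frame.groupby("zone_id")["biome"].first().reindex(table.frame.index)
    )
    rows = []
    for biome, zone_ids in zone_biome.groupby(zone_biome).groups.items():
        sub = table.frame.loc[zone_ids]
        if len(sub) < 2:
            rows.append(
                {"biome": biome, "g": np.nan, "df": len(sub) - 1, "p_value": np.nan}
            )
            continue
        obs = sub[f"n_sampled_{threshold}"].to_numpy(dtype=float)
        exp = expected_frequencies(
            sub["n_pentads"], int(sub["n_pentads"].sum()), int(obs.sum())
        )
        if obs.sum() == 0 or np.any(np.asarray(exp) <= 0):
            rows.append(
                {"biome": biome, "g": np.nan, "df": len(sub) - 1, "p_value": np.nan}
            )
            continue
        res = g_test(obs, exp)
        rows.append({"biome": biome, "g": res.g, "df": res.df, "p_value": res.p_value})
    out = pd.DataFrame(rows).set_index("biome")
    if holm:
        mask = out["p_value"].notna()
        p = out.loc[mask, "p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        out.loc[mask, "p_holm"] = adj
    return out


def rank_by_effort(table: ZoneEffortTable, threshold: int) -> pd.DataFrame:
    """Zones ordered by observed - expected sampled pentads, descending.

    The most oversampled zone ranks first; ties break by zone_id.
    """
    if threshold not in table.thresholds:
        raise ValueError(
            f"threshold {threshold} not in table thresholds {table.thresholds}"
        )
    cols = ["n_pentads", f"n_sampled_{threshold}", f"expected_{threshold}", f"deficit_{threshold}"]
    # stable sort: ties in the deficit resolve by zone_id (the index)
    out = (
        table.frame[cols]
        .sort_index(kind="mergesort")
        .sort_values(f"deficit_{threshold}", ascending=False, kind="mergesort")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
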