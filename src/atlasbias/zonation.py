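"""Environmental stratification: climate PCA, histogram climate classes,
majority-cover biome assignment with minority-biome reassignment, and pooling
of small biome x climate-class zones.

The stratification backbone is a partition of the pentad grid into
environmental zones.  Three climate variables (mean annual precipitation,
mean summer temperature, mean winter temperature) are reduced to their first
principal component; the PCA is computed on the correlation matrix, i.e. on
standardized variables, since mm/yr and °C are not commensurable.  PC1 scores
are cut into equal-width histogram classes (class 1 = hot and dry, highest
class = moist and mild).  Each pentad is assigned the biome covering the
largest fraction of its area; designated minority biomes (e.g. Forest and
Desert, which cover too few pentads to stratify) are reassigned to the modal
biome of their queen-neighbourhood, iterated to a fixed point.  Biome x class
zones whose expected sampled-pentad frequency falls below a Cochran-style
minimum are pooled with the nearest climate class within the same biome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas_io import CLIMATE_COLUMNS, PentadCovariates, decode_pentad, haversine_km


class DegenerateClimateError(ValueError):
    """A climate variable is constant and cannot be standardized."""


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the three climate variables.

    ``loadings`` has one column per component, rows in (precip, t_summer,
    t_winter) order; the sign of each component is fixed so that its
    precipitation loading is non-negative, making high PC1 scores mean wetter
    (and, along the dominant gradient, milder) pentads.
    """

    loadings: np.ndarray  # (3, 3), columns = components
    scores: pd.DataFrame  # per-pentad component values, columns PC1..PC3
    variance_explained: np.ndarray  # (3,), fractions summing to 1

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


@dataclass
class ZonePartition:
    """Pentad -> environmental zone mapping after pooling.

    ``frame`` has columns ``biome``, ``climate_class``, ``zone_id`` indexed by
    pentad; ``zone_id`` encodes merged class ranges, e.g. ``"Fynbos:7+8"``.
    """

    frame: pd.DataFrame
    merges: list[str] = field(default_factory=list)

    @property
    def zone_ids(self) -> list[str]:
        return sorted(self.frame["zone_id"].unique())

    @property
    def n_zones(self) -> int:
        return self.frame["zone_id"].nunique()

    def zone_members(self) -> dict[str, list[str]]:
        return {
            z: list(idx)
            for z, idx in self.frame.groupby("zone_id").groups.items()
        }

    def zone_sizes(self) -> pd.Series:
        return self.frame.groupby("zone_id").size()

    def zone_of(self) -> pd.Series:
        return self.frame["zone_id"]

    def summary(self) -> pd.DataFrame:
        rows = []
        for zone, grp in self.frame.groupby("zone_id"):
            classes = sorted(grp["climate_class"].unique())
            rows.append(
                {
                    "zone_id": zone,
                    "n_pentads": len(grp),
                    "classes": "+".join(str(c) for c in classes),
                }
            )
        return pd.DataFrame(rows).set_index("zone_id")


def climate_pca(covariates: PentadCovariates) -> PCAResult:
    """PCA of the correlation matrix of the three climate variables.

    Raises :class:`DegenerateClimateError` if any variable is constant, and
    ``ValueError`` for fewer than three complete rows.
    """
    frame = covariates.frame
    x = frame.loc[:, list(CLIMATE_COLUMNS)].to_numpy(dtype=float)
    complete = ~np.isnan(x).any(axis=1)
    if complete.sum() < 3:
        raise ValueError("need at least 3 pentads with complete climate data")
    x = x[complete]
    sd = x.std(axis=0, ddof=1)
    for name, s in zip(CLIMATE_COLUMNS, sd):
        if s == 0:
            raise DegenerateClimateError(f"climate variable {name!r} is constant")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # sign convention: precipitation loading non-negative in every component
    for k in range(eigvec.shape[1]):
        if eigvec[0, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = z @ eigvec
    score_frame = pd.DataFrame(
        scores,
        index=frame.index[complete],
        columns=[f"PC{k + 1}" for k in range(eigvec.shape[1])],
    )
    return PCAResult(
        loadings=eigvec,
        scores=score_frame,
        variance_explained=eigval / eigval.sum(),
    )


def assign_climate_classes(scores: pd.Series, n_classes: int = 10) -> pd.Series:
    """Cut PC1 scores into equal-width classes over [min, max].

    Class 1 is the low-score (hot, dry) end; the maximum score falls in class
    ``n_classes`` (right edge closed).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain non-finite values")
    lo, hi = s.min(), s.max()
    if hi == lo:
        raise ValueError("all scores are equal; climate classes are degenerate")
    width = (hi - lo) / n_classes
    cls = np.minimum((np.floor((s - lo) / width)).astype(int) + 1, n_classes)
    return pd.Series(cls, index=scores.index, name="climate_class")


def _queen_neighbours(codes: pd.Index) -> dict[str, list[str]]:
    rc = {c: (decode_pentad(c).row, decode_pentad(c).col) for c in codes}
    by_rc = {v: k for k, v in rc.items()}
    out: dict[str, list[str]] = {}
    for code, (r, c) in rc.items():
        nbrs = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                n = by_rc.get((r + dr, c + dc))
                if n is not None:
                    nbrs.append(n)
        out[code] = nbrs
    return out


def assign_biome(
    biome_fractions: pd.DataFrame, reassign: set[str] | frozenset[str] = frozenset()
) -> pd.Series:
    """Majority-cover biome per pentad, with minority biomes reassigned.

    Each pentad takes the biome with the largest cover fraction (ties broken
    toward the lexicographically smallest label, with a warning).  Pentads
    whose winning biome is in ``reassign`` take the modal biome among their
    queen-neighbourhood pentads not in ``reassign``, iterated until no pentad
    changes; isolated leftovers fall back to the nearest (great-circle)
    resolved pentad, with a warning.
    """
    if biome_fractions.empty:
        raise ValueError("biome fraction table is empty")
    fr = biome_fractions.to_numpy(dtype=float)
    if np.any(fr.sum(axis=1) <= 0):
        bad = biome_fractions.index[fr.sum(axis=1) <= 0][0]
        raise ValueError(f"pentad {bad} has all-zero biome fractions")
    cols = list(biome_fractions.columns)
    winners = []
    tie_seen = False
    for i in range(len(fr)):
        best = fr[i].max()
        cands = sorted(cols[j] for j in np.flatnonzero(fr[i] == best))
        if len(cands) > 1:
            tie_seen = True
        winners.append(cands[0])
    if tie_seen:
        warnings.warn(
            "biome cover ties broken toward the lexicographically smallest label",
            stacklevel=2,
        )
    biome = pd.Series(winners, index=biome_fractions.index, name="biome")

    reassign = set(reassign)
    if not reassign:
        return biome
    if not (set(biome.unique()) - reassign):
        raise ValueError("every pentad's biome is in the reassignment set")
    nbrs = _queen_neighbours(biome.index)
    pending = set(biome.index[biome.isin(reassign)])
    while pending:
        changed = {}
        for code in pending:
            votes = [biome[n] for n in nbrs[code] if biome[n] not in reassign]
            if votes:
                counts = pd.Series(votes).value_counts()
                top = counts[counts == counts.iloc[0]].index.min()
                changed[code] = top
        if not changed:
            break
        for code, lab in changed.items():
            biome[code] = lab
        pending -= set(changed)
    if pending:
        warnings.warn(
            f"{len(pending)} isolated pentads reassigned to the nearest resolved biome",
            stacklevel=2,
        )
        resolved = biome.index[~biome.isin(reassign)]
        res_pts = np.array(
            [
                (decode_pentad(c).midpoint_lat, decode_pentad(c).midpoint_lon)
                for c in resolved
            ]
        )
        for code in sorted(pending):
            p = decode_pentad(code)
            d = haversine_km(p.midpoint_lat, p.midpoint_lon, res_pts[:, 0], res_pts[:, 1])
            biome[code] = biome[resolved[int(np.argmin(d))]]
    return biome


class MergeImpossibleError(ValueError):
    """A biome's total expected frequency is below the pooling minimum."""

    def __init__(self, message: str, biome: str | None = None):
        super().__init__(message)
        self.biome = biome


def build_zones(
    biomes: pd.Series,
    classes: pd.Series,
    total_sampled: int,
    min_expected: float = 5.0,
) -> ZonePartition:
    """Overlay biomes and climate classes, then pool undersized zones.

    Initial zones are every occupied biome x class combination.  The expected
    sampled-pentad frequency of zone ``z`` under a goodness-of-fit test with
    ``total_sampled`` sampled pentads is ``(n_z / N) * total_sampled`` (use
    the stricter intensity threshold's sampled total, which gives the
    smallest expecteds).  While any zone's expected frequency is below
    ``min_expected``, the zone with the smallest expected frequency is merged
    into the zone of the nearest climate class within the same biome (ties
    toward the lower class).  Zone ids record merged class ranges, e.g.
    ``"Fynbos:7+8"``.
    """
    if not biomes.index.equals(classes.index):
        classes = classes.reindex(biomes.index)
        if classes.isna().any():
            raise ValueError("every pentad needs both a biome and a climate class")
    n_total = len(biomes)
    if total_sampled <= 0:
        raise ValueError("total_sampled must be positive")

    # zone state: {biome: {frozenset(classes): n_pentads}}
    sizes: dict[str, dict[frozenset, int]] = {}
    for (b, c), n in (
        pd.DataFrame({"biome": biomes, "cls": classes}).groupby(["biome", "cls"]).size().items()
    ):
        sizes.setdefault(b, {})[frozenset([int(c)])] = int(n)

    for b, zones in sizes.items():
        if sum(zones.values()) / n_total * total_sampled < min_expected:
            raise MergeImpossibleError(
                f"biome {b!r}: total expected frequency below {min_expected}; "
                "use coarser climate classes or reassign the biome",
                biome=b,
            )

    def expected(n: int) -> float:
        return n / n_total * total_sampled

    merges: list[str] = []
    while True:
        # the zone with the smallest expected frequency, deterministic tie-break
        worst = None
        for b in sorted(sizes):
            for cls_set, n in sizes[b].items():
                key = (expected(n), b, min(cls_set))
                if worst is None or key < worst[0]:
                    worst = (key, b, cls_set)
        (exp_val, _, _), b, cls_set = worst
        if exp_val >= min_expected:
            break
        others = [c for c in sizes[b] if c != cls_set]
        if not others:  # cannot happen after the biome-total check
            raise MergeImpossibleError(
                f"biome {b!r} has a single undersized zone", biome=b
            )

        def class_distance(other: frozenset) -> tuple[int, int]:
            d = min(abs(a - o) for a in cls_set for o in other)
            return (d, min(other))

        target = min(others, key=class_distance)
        merged = frozenset(cls_set | target)
        n_new = sizes[b].pop(cls_set) + sizes[b].pop(target)
        sizes[b][merged] = n_new
        merges.append(
            f"{b}: classes {sorted(cls_set)} -> {sorted(target)} (expected "
            f"{exp_val:.2f} < {min_expected})"
        )

    def zone_id(b: str, cls_set: frozenset) -> str:
        return f"{b}:" + "+".join(str(c) for c in sorted(cls_set))

    lookup: dict[tuple[str, int], str] = {}
    for b, zones in sizes.items():
        for cls_set in zones:
            for c in cls_set:
                lookup[(b, c)] = zone_id(b, cls_set)
    frame = pd.DataFrame(
        {
            "biome": biomes,
            "climate_class": classes.astype(int),
            "zone_id": [
                lookup[(b, int(c))] for b, c in zip(biomes, classes)
            ],
        },
        index=biomes.index,
    )
    frame.index.name = "pentad"
    part = ZonePartition(frame=frame, merges=merges)
    assert part.zone_sizes().sum() == n_total  # partition property
    return part
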