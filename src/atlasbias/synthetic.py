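"""Synthetic atlas generator: landscape, biased volunteer effort, community,
and checklists, with the ground truth recorded for recovery tests.

The generator emulates the statistical structure a volunteer bird atlas
produces on a rectangular pentad grid:

* three smooth climate surfaces (mean annual precipitation, mean summer and
  winter temperature) built from a linear gradient plus a few low-frequency
  sinusoids — cheap, deterministic, and sufficient to create spatially
  contiguous climate classes;
* a biome partition by nearest seed point, softened into per-pentad biome
  cover fractions near boundaries;
* sampling hubs, densified road polylines, and protected / urban / cultivated
  cover fields;
* per-pentad visit counts drawn from a Poisson log-linear model of the
  accessibility and attractiveness covariates, with a distance-decay from
  hubs entering through log distance (hub pentads themselves are excluded,
  matching the convention that hubs are removed before modelling);
* a zone-structured species community with per-pentad Bernoulli occupancy and
  a configurable fraction of widespread species shared across zones;
* per-visit detection: each visit detects each occupying species
  independently with probability ``p_det``; empty lists are dropped (a real
  checklist always has at least one species) but counted in the truth record.

There are no false-positive detections: atlas records are vetted, so the
observation model is false-negative only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas_io import (
    ChecklistTable,
    PentadCovariates,
    decode_pentad,
    encode_code_string,
    haversine_km,
)

#: biome labels used by the default synthetic landscape
DEFAULT_BIOMES = (
    "AlbanyThicket",
    "Fynbos",
    "Grassland",
    "IOCB",
    "NamaKaroo",
    "Savanna",
    "SucculentKaroo",
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class LandscapeConfig:
    """Shape and texture of the synthetic landscape.

    Climate surfaces are ``base + gradient + noise_amplitude * sinusoids``
    where the gradient runs NW (hot, dry) to SE (mild, wet) across the grid
    and the sinusoid mixture is seeded.  Amplitude 0 gives exactly linear
    surfaces.
    """

    rows: int = 40
    cols: int = 40
    lat0: float = -22.0  # NW corner latitude of the grid (deg, south negative)
    lon0: float = 16.0  # NW corner longitude (deg east)
    # (value at NW corner, value at SE corner), units mm/yr and °C
    precip_range: tuple[float, float] = (150.0, 950.0)
    t_summer_range: tuple[float, float] = (31.0, 21.0)
    # winter means rise toward the milder, wetter coast
    t_winter_range: tuple[float, float] = (6.0, 13.0)
    # noise amplitude as a fraction of each variable's gradient span
    climate_noise: float = 0.15
    n_biomes: int = 7
    biome_labels: tuple[str, ...] = DEFAULT_BIOMES
    biome_mix_cells: float = 1.5  # boundary softening width, in cells
    n_hubs: int = 3
    n_road_waypoints: int = 6
    road_vertex_spacing_km: float = 1.0
    n_protected_patches: int = 6
    protected_patch_cells: float = 3.0
    urban_decay_km: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.rows < 4 or self.cols < 4:
            raise ConfigError("grid extent must be at least 4 x 4 pentads")
        if self.climate_noise < 0:
            raise ConfigError("climate noise amplitude must be >= 0")
        if self.n_biomes < 1 or self.n_biomes > len(self.biome_labels):
            raise ConfigError("n_biomes must be between 1 and len(biome_labels)")
        if self.n_hubs < 1:
            raise ConfigError("need at least one sampling hub")


@dataclass
class EffortCoefficients:
    """Log-linear effort model coefficients.

    ``b_loghub`` multiplies the natural log of hub distance in km; ``b_road``
    is per km of road distance; cover coefficients are per unit fraction;
    climate coefficients are per standardized unit.  Sign conventions are
    generator defaults only: effort decays with distance from hubs and roads
    and is drawn toward protected and urban pentads.
    """

    b0: float = 4.1
    b_loghub: float = -0.55
    b_road: float = -0.035
    b_prot: float = 1.3
    b_urban: float = 2.2
    b_cult: float = -0.3
    b_precip: float = 0.15
    b_tsummer: float = -0.10
    b_twinter: float = 0.05

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "intercept": self.b0,
                "log_dist_hub": self.b_loghub,
                "dist_road": self.b_road,
                "protected": self.b_prot,
                "urban": self.b_urban,
                "cultivated": self.b_cult,
                "precip": self.b_precip,
                "t_summer": self.b_tsummer,
                "t_winter": self.b_twinter,
            }
        )


@dataclass
class Landscape:
    """Generated landscape: covariates plus landmark geometry."""

    covariates: PentadCovariates
    hub_codes: list[str]
    hub_points: np.ndarray  # (n_hubs, 2) midpoint (lat, lon)
    road_vertices: np.ndarray  # (n_vertices, 2) (lat, lon)
    biome: pd.Series  # majority (nearest-seed) biome per pentad
    province: pd.Series  # quadrant grouping label per pentad
    config: LandscapeConfig


@dataclass
class Community:
    """Zone-structured community with per-pentad occupancy."""

    species: list[str]
    occupancy: np.ndarray  # (n_pentads, n_species) bool
    pentads: list[str]
    richness: dict[str, int]  # true pool size per zone
    occupancy_prob: float  # mean per-species occupancy
    shared_fraction: float
    occupancy_q: np.ndarray | None = None  # per-species occupancy probabilities

    def pool_richness(self, zone: str) -> int:
        return self.richness[zone]


@dataclass
class SyntheticTruth:
    """Everything the generator knows that an analyst would have to estimate."""

    coefficients: EffortCoefficients
    richness: dict[str, int]
    p_det: float
    seeds: dict[str, int]
    n_empty_lists_dropped: int = 0
    eta: pd.Series | None = None  # linear predictor of the effort model

    def to_dict(self) -> dict:
        return {
            "coefficients": asdict(self.coefficients),
            "richness": self.richness,
            "p_det": self.p_det,
            "seeds": self.seeds,
            "n_empty_lists_dropped": self.n_empty_lists_dropped,
        }


def _smooth_surface(
    rows: int,
    cols: int,
    lo: float,
    hi: float,
    noise: float,
    rng: np.random.Generator,
    direction: tuple[float, float] = (0.5, 0.5),
) -> np.ndarray:
    """Linear gradient along ``direction`` (row, col weights summing to 1)
    plus a seeded low-frequency sinusoid mixture."""
    r = np.arange(rows)[:, None] / max(rows - 1, 1)
    c = np.arange(cols)[None, :] / max(cols - 1, 1)
    wr, wc = direction
    surface = lo + (hi - lo) * (wr * r + wc * c)
    if noise > 0:
        span = abs(hi - lo)
        for _ in range(3):
            fr, fc = rng.uniform(0.5, 2.5, size=2)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.5, 1.0) * noise * span / 3.0
            surface = surface + amp * np.sin(2 * np.pi * (fr * r + fc * c) + phase)
    return surface


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Build the full synthetic landscape deterministically from its seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.rows, config.cols

    codes = np.empty((rows, cols), dtype=object)
    for i in range(rows):
        for j in range(cols):
            lat = config.lat0 - i * 5 / 60.0
            lon = config.lon0 + j * 5 / 60.0
            codes[i, j] = encode_code_string(lat, lon)
    flat_codes = [codes[i, j] for i in range(rows) for j in range(cols)]
    mids = np.array(
        [
            (decode_pentad(c).midpoint_lat, decode_pentad(c).midpoint_lon)
            for c in flat_codes
        ]
    )

    # precipitation and summer temperature follow the dominant NW->SE
    # gradient (anti-correlated); winter temperature runs mostly with
    # latitude and carries more local texture, so it loads weakly on the
    # leading climate component as in real climate fields
    precip = _smooth_surface(rows, cols, *config.precip_range, config.climate_noise, rng)
    t_summer = _smooth_surface(
        rows, cols, *config.t_summer_range, config.climate_noise, rng
    )
    t_winter = _smooth_surface(
        rows,
        cols,
        *config.t_winter_range,
        2.5 * config.climate_noise,
        rng,
        direction=(0.85, 0.15),
    )

    # biome partition: nearest seed point in grid coordinates, softened into
    # cover fractions near boundaries
    labels = list(config.biome_labels[: config.n_biomes])
    seeds_rc = rng.uniform(0, [rows, cols], size=(config.n_biomes, 2))
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    dists = np.stack(
        [np.hypot(rr - s[0], cc - s[1]) for s in seeds_rc], axis=-1
    )  # rows x cols x n_biomes
    order = np.argsort(dists, axis=-1)
    nearest = order[..., 0]
    d1 = np.take_along_axis(dists, order[..., :1], axis=-1)[..., 0]
    if config.n_biomes > 1:
        d2 = np.take_along_axis(dists, order[..., 1:2], axis=-1)[..., 0]
        # fraction of the nearest biome: 1 deep inside, ~0.5 on the boundary
        f1 = np.clip(0.5 + (d2 - d1) / (2.0 * config.biome_mix_cells), 0.5, 1.0)
    else:
        f1 = np.ones_like(d1)
    biome_fracs = {lab: np.zeros((rows, cols)) for lab in labels}
    for i in range(rows):
        for j in range(cols):
            b1 = labels[nearest[i, j]]
            biome_fracs[b1][i, j] = f1[i, j]
            if config.n_biomes > 1:
                b2 = labels[order[i, j, 1]]
                biome_fracs[b2][i, j] += 1.0 - f1[i, j]

    # sampling hubs: well-separated random cells
    hub_rc: list[tuple[int, int]] = []
    min_sep = max(rows, cols) / (config.n_hubs + 1)
    attempts = 0
    while len(hub_rc) < config.n_hubs and attempts < 1000:
        cand = (int(rng.integers(rows)), int(rng.integers(cols)))
        if all(np.hypot(cand[0] - h[0], cand[1] - h[1]) >= min_sep for h in hub_rc):
            hub_rc.append(cand)
        attempts += 1
    while len(hub_rc) < config.n_hubs:  # pragma: no cover - dense fallback
        hub_rc.append((int(rng.integers(rows)), int(rng.integers(cols))))
    hub_codes = [codes[i, j] for i, j in hub_rc]
    hub_points = np.array(
        [
            (decode_pentad(c).midpoint_lat, decode_pentad(c).midpoint_lon)
            for c in hub_codes
        ]
    )

    # roads: polylines linking consecutive hubs plus random waypoints,
    # densified to the requested vertex spacing
    waypoints = rng.uniform(0, [rows, cols], size=(config.n_road_waypoints, 2))
    nodes_rc = np.vstack([np.array(hub_rc, dtype=float), waypoints])
    nodes_ll = np.column_stack(
        [
            config.lat0 - (nodes_rc[:, 0] + 0.5) * 5 / 60.0,
            config.lon0 + (nodes_rc[:, 1] + 0.5) * 5 / 60.0,
        ]
    )
    segs = []
    for k in range(len(nodes_ll) - 1):
        a, b = nodes_ll[k], nodes_ll[k + 1]
        seg_km = haversine_km(a[0], a[1], b[0], b[1])
        n_pts = max(2, int(np.ceil(seg_km / config.road_vertex_spacing_km)) + 1)
        segs.append(
            np.column_stack(
                [np.linspace(a[0], b[0], n_pts), np.linspace(a[1], b[1], n_pts)]
            )
        )
    road_vertices = np.vstack(segs)

    # distance covariates from pentad midpoints
    def _min_dist(points: np.ndarray) -> np.ndarray:
        out = np.empty(len(mids))
        for k in range(len(mids)):
            out[k] = np.min(
                haversine_km(mids[k, 0], mids[k, 1], points[:, 0], points[:, 1])
            )
        return out

    dist_hub = _min_dist(hub_points)
    dist_road = _min_dist(road_vertices)

    # cover fields
    urban = np.clip(
        rng.beta(2.0, 2.0, size=len(mids)) * 0.9 * np.exp(-dist_hub / config.urban_decay_km),
        0.0,
        1.0,
    )
    # protected cover: Gaussian patch kernels, combined with max so dense
    # patch layouts cannot saturate the whole grid to a constant
    prot_centers = rng.uniform(0, [rows, cols], size=(config.n_protected_patches, 2))
    rc_flat = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    prot = np.zeros(len(mids))
    for ctr in prot_centers:
        d = np.hypot(rc_flat[:, 0] - ctr[0], rc_flat[:, 1] - ctr[1])
        prot = np.maximum(
            prot, 0.95 * np.exp(-0.5 * (d / config.protected_patch_cells) ** 2)
        )
    protected = prot
    precip_flat = precip.ravel()
    precip_rank = pd.Series(precip_flat).rank(pct=True).to_numpy()
    cultivated = np.clip(
        rng.beta(2.0, 3.0, size=len(mids)) * precip_rank * (1.0 - urban), 0.0, 1.0
    )

    frame = pd.DataFrame(
        {
            "pentad": flat_codes,
            "precip": precip_flat,
            "t_summer": t_summer.ravel(),
            "t_winter": t_winter.ravel(),
            "protected": protected,
            "urban": urban,
            "cultivated": cultivated,
            "dist_hub_km": dist_hub,
            "dist_road_km": dist_road,
        }
    )
    for lab in labels:
        frame[f"biome_{lab}"] = biome_fracs[lab].ravel()

    biome = pd.Series(
        [labels[nearest[i, j]] for i in range(rows) for j in range(cols)],
        index=flat_codes,
        name="biome",
    )
    province = pd.Series(
        [
            f"P{1 + 2 * (i >= rows // 2) + (j >= cols // 2)}"
            for i in range(rows)
            for j in range(cols)
        ],
        index=flat_codes,
        name="province",
    )
    return Landscape(
        covariates=PentadCovariates(frame),
        hub_codes=hub_codes,
        hub_points=hub_points,
        road_vertices=road_vertices,
        biome=biome,
        province=province,
        config=config,
    )


def effort_design_frame(landscape: Landscape) -> pd.DataFrame:
    """Model-scale covariates for the effort model, hub pentads excluded.

    Climate variables are standardized (z-scores over the included pentads);
    hub distance enters as its natural log.
    """
    cov = landscape.covariates.frame
    keep = ~cov.index.isin(landscape.hub_codes)
    cov = cov.loc[keep]
    if (cov["dist_hub_km"] <= 0).any():
        bad = cov.index[cov["dist_hub_km"] <= 0][0]
        raise ValueError(
            f"pentad {bad} has zero hub distance but is not excluded as a hub"
        )
    out = pd.DataFrame(index=cov.index)
    out["log_dist_hub"] = np.log(cov["dist_hub_km"])
    out["dist_road"] = cov["dist_road_km"]
    out["protected"] = cov["protected"]
    out["urban"] = cov["urban"]
    out["cultivated"] = cov["cultivated"]
    for col in ("precip", "t_summer", "t_winter"):
        x = cov[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"climate variable {col} is constant; cannot standardize")
        out[col] = (x - x.mean()) / sd
    return out


def generate_effort(
    landscape: Landscape,
    coeffs: EffortCoefficients | None = None,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Draw Poisson visit counts per non-hub pentad.

    Returns ``(counts, eta)`` where ``eta`` is the linear predictor; both are
    indexed by pentad code with hub pentads excluded.
    """
    coeffs = coeffs or EffortCoefficients()
    design = effort_design_frame(landscape)
    beta = coeffs.as_series()
    eta = (
        beta["intercept"]
        + design["log_dist_hub"] * beta["log_dist_hub"]
        + design["dist_road"] * beta["dist_road"]
        + design["protected"] * beta["protected"]
        + design["urban"] * beta["urban"]
        + design["cultivated"] * beta["cultivated"]
        + design["precip"] * beta["precip"]
        + design["t_summer"] * beta["t_summer"]
        + design["t_winter"] * beta["t_winter"]
    )
    rng = np.random.default_rng(seed)
    counts = pd.Series(
        rng.poisson(np.exp(eta.to_numpy())), index=design.index, name="n_lists"
    )
    return counts, eta.rename("eta")


def default_zone_richness(
    zones: pd.Series, classes: pd.Series, base: int = 60, per_class: int = 12
) -> dict[str, int]:
    """Default true richness per zone: wetter/milder zones are richer.

    ``R_z = base + per_class * mean climate class of the zone`` — mirrors the
    broad richness gradient from arid to mesic environments.
    """
    out: dict[str, int] = {}
    for zone in sorted(zones.unique()):
        mean_class = float(classes[zones == zone].mean())
        out[zone] = max(1, int(round(base + per_class * mean_class)))
    return out


def generate_community(
    landscape: Landscape,
    zones: pd.Series,
    richness_model: Mapping[str, int] | Callable[[str], int] | None = None,
    seed: int = 0,
    occupancy_prob: float = 0.35,
    shared_fraction: float = 0.25,
    occupancy_alpha: float | None = None,
) -> Community:
    """Build the zone-structured community and its occupancy matrix.

    Each zone ``z`` gets a species pool of size ``R_z``; a fraction of the
    smallest pool is shared (widespread species present in every zone's
    pool).  Pool species occupy each pentad of their zone independently with
    probability ``occupancy_prob``.  With ``occupancy_alpha`` set, each
    species instead draws its own occupancy from a Beta distribution with
    that shape parameter and mean ``occupancy_prob`` — a small alpha gives
    the long tail of rare species that keeps real accumulation curves rising,
    while the mean per-pentad richness is unchanged.
    """
    pentads = list(landscape.covariates.frame.index)
    missing = [p for p in pentads if p not in zones.index]
    if missing:
        raise ValueError(f"pentads without a zone assignment: {missing[:5]}")
    zone_ids = sorted(zones.loc[pentads].unique())
    if richness_model is None:
        richness = {z: 120 for z in zone_ids}
    elif callable(richness_model):
        richness = {z: int(richness_model(z)) for z in zone_ids}
    else:
        richness = {z: int(richness_model[z]) for z in zone_ids}
    for z, r in richness.items():
        if r < 1:
            raise ConfigError(f"zone {z} has richness {r} < 1")
    if not 0 < occupancy_prob <= 1:
        raise ConfigError("occupancy_prob must be in (0, 1]")
    if not 0 <= shared_fraction <= 1:
        raise ConfigError("shared_fraction must be in [0, 1]")

    n_shared = int(round(shared_fraction * min(richness.values())))
    shared = [f"wide{k:04d}" for k in range(n_shared)]
    species: list[str] = list(shared)
    pools: dict[str, list[int]] = {}
    for z in zone_ids:
        own = [f"{z}|sp{k:04d}" for k in range(richness[z] - n_shared)]
        start = len(species)
        species.extend(own)
        pools[z] = list(range(n_shared)) + list(range(start, start + len(own)))

    rng = np.random.default_rng(seed)
    if occupancy_alpha is not None:
        if occupancy_alpha <= 0:
            raise ConfigError("occupancy_alpha must be positive")
        if occupancy_prob >= 1:
            raise ConfigError("heterogeneous occupancy needs occupancy_prob < 1")
        beta_b = occupancy_alpha * (1.0 - occupancy_prob) / occupancy_prob
        q = rng.beta(occupancy_alpha, beta_b, size=len(species))
    else:
        q = np.full(len(species), occupancy_prob)
    occ = np.zeros((len(pentads), len(species)), dtype=bool)
    zone_of = zones.loc[pentads]
    for z in zone_ids:
        rows_idx = np.flatnonzero((zone_of == z).to_numpy())
        cols_idx = np.array(pools[z], dtype=int)
        occ[np.ix_(rows_idx, cols_idx)] = (
            rng.random((len(rows_idx), len(cols_idx))) < q[cols_idx][None, :]
        )
    return Community(
        species=species,
        occupancy=occ,
        pentads=pentads,
        richness=richness,
        occupancy_prob=occupancy_prob,
        shared_fraction=shared_fraction,
        occupancy_q=q,
    )


def generate_checklists(
    visit_counts: pd.Series,
    community: Community,
    p_det: float = 0.55,
    seed: int = 0,
    coefficients: EffortCoefficients | None = None,
    eta: pd.Series | None = None,
) -> tuple[ChecklistTable, SyntheticTruth]:
    """Simulate per-visit checklists from occupancy and detection.

    Each visit detects each occupying species independently with probability
    ``p_det``.  Visits that detect nothing are dropped from the output table
    (a contributed list always has at least one species) but tallied in the
    truth record.
    """
    if not 0 < p_det <= 1:
        raise ConfigError("p_det must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pentad_index = {p: i for i, p in enumerate(community.pentads)}
    species = np.asarray(community.species, dtype=object)
    rows: list[tuple[str, str, frozenset]] = []
    n_empty = 0
    for pentad, n_visits in visit_counts.items():
        n_visits = int(n_visits)
        if n_visits <= 0:
            continue
        if pentad not in pentad_index:
            raise ValueError(f"visit counts reference unknown pentad {pentad}")
        occ_idx = np.flatnonzero(community.occupancy[pentad_index[pentad]])
        if occ_idx.size == 0:
            n_empty += n_visits
            continue
        detected = rng.random((n_visits, occ_idx.size)) < p_det
        for v in range(n_visits):
            sp = species[occ_idx[detected[v]]]
            if sp.size == 0:
                n_empty += 1
                continue
            rows.append((pentad, f"{pentad}-v{v:04d}", frozenset(sp)))
    if n_empty:
        warnings.warn(f"dropped {n_empty} empty checklists", stacklevel=2)
    table = ChecklistTable.from_records(rows) if rows else ChecklistTable(
        pd.DataFrame(columns=["pentad", "visit_id", "species"])
    )
    truth = SyntheticTruth(
        coefficients=coefficients or EffortCoefficients(),
        richness=dict(community.richness),
        p_det=p_det,
        seeds={"checklists": seed},
        n_empty_lists_dropped=n_empty,
        eta=eta,
    )
    return table, truth
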