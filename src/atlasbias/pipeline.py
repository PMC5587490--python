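"""End-to-end pipeline: simulate (or load) an atlas, stratify it into
environmental zones, model effort determinants, and assess representativeness
and inventory completeness.

Every stage writes its machine-readable outputs (CSV/JSON/GeoJSON) into the
configured output directory together with a run manifest (config, seeds,
package version) that suffices to reproduce every number bit-for-bit with the
same build.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas_io import (
    ChecklistTable,
    PentadCovariates,
    pentads_to_geojson,
    read_checklists,
    read_covariates,
    read_landmarks_geojson,
    write_checklists,
    write_covariates,
    write_geojson,
)
from .accumulation import (
    build_incidence,
    fit_richness_model,
    mao_tau,
    permutation_accumulation,
    completeness_rank,
    MODELS,
)
from .effort import EffortDesign, EffortFit, fit_poisson_glm, fit_report, morans_i
from .representativeness import (
    per_biome_g_tests,
    g_test,
    rank_by_effort,
    zone_sampling_counts,
)
from .synthetic import (
    EffortCoefficients,
    LandscapeConfig,
    default_zone_richness,
    effort_design_frame,
    generate_checklists,
    generate_community,
    generate_effort,
    generate_landscape,
)
from .zonation import assign_biome, assign_climate_classes, build_zones, climate_pca

logger = logging.getLogger("atlasbias")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either ``inputs`` (paths to checklist/covariate/landmark files) or a
    simulation block must be provided; with neither, the default synthetic
    atlas is simulated.  All randomness flows from the ``seed`` via fixed
    per-stage offsets (no hidden global RNG state).
    """

    thresholds: tuple[int, ...] = (1, 10)
    n_classes: int = 10
    min_expected: float = 5.0
    models: tuple[str, ...] = MODELS
    curve_method: str = "exact"  # or "permutation"
    n_runs: int = 1000
    reassign_biomes: tuple[str, ...] = ()
    seed: int = 0
    outdir: str | Path = "atlasbias_out"
    simulate: bool = True
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    coefficients: EffortCoefficients = field(default_factory=EffortCoefficients)
    occupancy_prob: float = 0.2
    occupancy_alpha: float | None = 0.35
    shared_fraction: float = 0.25
    richness_base: int = 100
    richness_per_class: int = 15
    p_det: float = 0.55
    morans_n_perm: int = 199
    inputs: dict | None = None  # {"checklists": .., "covariates": .., "landmarks": ..}

    def __post_init__(self) -> None:
        t = tuple(int(x) for x in self.thresholds)
        if any(x <= 0 for x in t) or list(t) != sorted(set(t)):
            raise ValueError("thresholds must be strictly increasing positive integers")
        self.thresholds = t
        unknown = set(self.models) - set(MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.inputs is not None:
            self.simulate = False
            for key in ("checklists", "covariates"):
                path = self.inputs.get(key)
                if path is None or not Path(path).exists():
                    raise ValueError(f"input file for {key!r} missing: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "landscape" in kwargs and isinstance(kwargs["landscape"], dict):
            kwargs["landscape"] = LandscapeConfig(**kwargs["landscape"])
        if "coefficients" in kwargs and isinstance(kwargs["coefficients"], dict):
            kwargs["coefficients"] = EffortCoefficients(**kwargs["coefficients"])
        for key in ("thresholds", "models", "reassign_biomes"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        d["version"] = __version__
        blob = json.dumps(d, sort_keys=True, default=str)
        d["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()
        return d


@dataclass
class ReportBundle:
    """Everything a pipeline run computed, plus where it was written."""

    config: PipelineConfig
    covariates: PentadCovariates
    checklists: ChecklistTable
    zones: object
    pca: object
    effort_table: object
    g_overall: dict
    g_per_biome: dict
    effort_fits: dict[str, EffortFit]
    moran: object
    curves: dict
    fits: dict
    rankings: dict
    completeness: dict
    truth: object | None
    outdir: Path


def _simulate_stage(config: PipelineConfig):
    land_cfg = dataclasses.replace(
        config.landscape, seed=config.stage_seed("landscape")
    )
    landscape = generate_landscape(land_cfg)
    counts, eta = generate_effort(
        landscape, config.coefficients, seed=config.stage_seed("effort")
    )
    return landscape, counts, eta


def _zonate(config: PipelineConfig, covariates: PentadCovariates, total_sampled_strict: int):
    from .zonation import MergeImpossibleError

    pca = climate_pca(covariates)
    classes = assign_climate_classes(pca.pc1, config.n_classes)
    # biomes too small to satisfy the pooling minimum are reassigned to their
    # neighbours and the stratification redone (minority-biome policy)
    reassign = set(config.reassign_biomes)
    n_biomes = len(covariates.biome_fractions.columns)
    while True:
        biome = assign_biome(covariates.biome_fractions, reassign=reassign)
        try:
            zones = build_zones(
                biome,
                classes,
                total_sampled=total_sampled_strict,
                min_expected=config.min_expected,
            )
            break
        except MergeImpossibleError as exc:
            if exc.biome is None or exc.biome in reassign or len(reassign) >= n_biomes - 1:
                raise
            logger.info("reassigning undersized biome %r", exc.biome)
            reassign.add(exc.biome)
    return pca, zones


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute simulate -> zonate -> effort model -> assess and write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _cleanup_partial():
        for pattern in ("*.csv", "*.json", "*.geojson"):
            for p in outdir.glob(pattern):
                p.unlink()

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    _cleanup_partial()
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Timer()

    truth = None
    landscape = None
    with _stage("inputs"):
        if config.simulate:
            landscape, counts, eta = _simulate_stage(config)
            covariates = landscape.covariates
        else:
            covariates = read_covariates(config.inputs["covariates"])
            checklists = read_checklists(config.inputs["checklists"])
            if covariates.needs_distances:
                lm = read_landmarks_geojson(config.inputs["landmarks"])
                covariates = covariates.with_distances(lm["hubs"], lm["roads"])
            counts = checklists.lists_per_pentad().reindex(
                covariates.frame.index, fill_value=0
            )

    strict = max(config.thresholds)
    with _stage("zonation"):
        pca, zones = _zonate(config, covariates, int((counts >= strict).sum()))

    with _stage("community"):
        if config.simulate:
            classes = zones.frame["climate_class"]
            richness = default_zone_richness(
                zones.zone_of(), classes, config.richness_base, config.richness_per_class
            )
            community = generate_community(
                landscape,
                zones.zone_of(),
                richness,
                seed=config.stage_seed("community"),
                occupancy_prob=config.occupancy_prob,
                shared_fraction=config.shared_fraction,
                occupancy_alpha=config.occupancy_alpha,
            )
            checklists, truth = generate_checklists(
                counts,
                community,
                p_det=config.p_det,
                seed=config.stage_seed("checklists"),
                coefficients=config.coefficients,
                eta=eta,
            )

    with _stage("effort_model"):
        if config.simulate:
            design_frame = effort_design_frame(landscape)
            group = landscape.province
        else:
            cov = covariates.frame
            design_frame = pd.DataFrame(
                {
                    "log_dist_hub": np.log(cov["dist_hub_km"].where(cov["dist_hub_km"] > 0)),
                    "dist_road": cov["dist_road_km"],
                    "protected": cov["protected"],
                    "urban": cov["urban"],
                    "cultivated": cov["cultivated"],
                    "precip": cov["precip"],
                    "t_summer": cov["t_summer"],
                    "t_winter": cov["t_winter"],
                }
            ).dropna()
            group = None
        design_frame = design_frame.copy()
        design_frame["n_lists"] = counts.reindex(design_frame.index, fill_value=0)
        mids = covariates.midpoints()
        mid_lookup = dict(zip(covariates.frame.index, mids))
        coords = np.array([mid_lookup[p] for p in design_frame.index])
        design = EffortDesign(
            frame=design_frame, group=group, coords=coords
        )
        # pooled fit for the spatial diagnostic; per-group fits for the report
        pooled = fit_poisson_glm(
            EffortDesign(frame=design_frame, group=None, coords=coords)
        )["all"]
        fits = fit_poisson_glm(design) if group is not None else {"all": pooled}
        moran = morans_i(
            pooled.pearson_residuals.to_numpy(),
            coords,
            n_perm=config.morans_n_perm,
            seed=config.stage_seed("morans"),
        )

    with _stage("representativeness"):
        effort_table = zone_sampling_counts(checklists, zones, config.thresholds)
        g_overall = {}
        g_biome = {}
        rankings = {}
        for t in config.thresholds:
            g_overall[t] = g_test(
                effort_table.observed(t).to_numpy(),
                effort_table.expected(t).to_numpy(),
            )
            g_biome[t] = per_biome_g_tests(effort_table, zones, t)
            rankings[t] = rank_by_effort(effort_table, t)

    with _stage("accumulation"):
        curves = {}
        fits_acc = {}
        completeness = {}
        for t in config.thresholds:
            incidence = build_incidence(checklists, zones, t)
            curves[t] = {}
            fits_acc[t] = {}
            lomolino_fits = {}
            for zone, inc in incidence.items():
                if config.curve_method == "permutation":
                    curve = permutation_accumulation(
                        inc, n_runs=config.n_runs, seed=config.stage_seed(f"curve:{t}:{zone}")
                    )
                else:
                    curve = mao_tau(inc)
                curves[t][zone] = curve
                fits_acc[t][zone] = {m: fit_richness_model(curve, m) for m in config.models}
                if "lomolino" in config.models:
                    lomolino_fits[zone] = fits_acc[t][zone]["lomolino"]
            if lomolino_fits:
                completeness[t] = completeness_rank(lomolino_fits)

    with _stage("write"):
        write_covariates(covariates, outdir / "covariates.csv")
        write_checklists(checklists, outdir / "checklists.csv")
        zones.frame.to_csv(outdir / "zones.csv")
        zones.summary().to_csv(outdir / "zone_summary.csv")
        effort_table.frame.to_csv(outdir / "effort_table.csv")
        fit_report(fits).to_csv(outdir / "effort_report.csv")
        gdict = {
            "overall": {
                str(t): {"g": r.g, "df": r.df, "p_value": r.p_value}
                for t, r in g_overall.items()
            },
            "per_biome": {
                str(t): g_biome[t].reset_index().to_dict(orient="records")
                for t in config.thresholds
            },
            "moran": {
                "statistic": moran.statistic,
                "expected": moran.expected,
                "p_value": moran.p_value,
                "n_perm": moran.n_perm,
            },
        }
        (outdir / "gtests.json").write_text(json.dumps(gdict, indent=2, default=float))
        curve_rows = []
        for t, zc in curves.items():
            for zone, c in zc.items():
                for n_i, s_i in zip(c.n, c.s):
                    curve_rows.append(
                        {"zone_id": zone, "threshold": t, "n": int(n_i), "S_mao": float(s_i)}
                    )
        pd.DataFrame(curve_rows).to_csv(outdir / "curves.csv", index=False)
        fit_rows = []
        for t, zf in fits_acc.items():
            for zone, by_model in zf.items():
                for m, f in by_model.items():
                    pvals = list(f.params.values())
                    fit_rows.append(
                        {
                            "zone_id": zone,
                            "threshold": t,
                            "model": m,
                            "Asym": f.params.get("asym", np.nan),
                            "param2": pvals[1] if len(pvals) > 1 else np.nan,
                            "param3": pvals[2] if len(pvals) > 2 else np.nan,
                            "rss": f.rss,
                            "S_obs": f.s_obs,
                            "S_est": f.s_est,
                            "completeness_pct": f.completeness,
                            "converged": f.converged,
                        }
                    )
        pd.DataFrame(fit_rows).to_csv(outdir / "fits.csv", index=False)
        for t in config.thresholds:
            rankings[t].to_csv(outdir / f"effort_ranking_ge{t}.csv")
            if t in completeness:
                completeness[t].to_csv(outdir / f"completeness_ge{t}.csv")
        props = zones.frame[["biome", "climate_class", "zone_id"]].copy()
        props["n_lists"] = counts.reindex(props.index, fill_value=0).astype(int)
        write_geojson(
            pentads_to_geojson(list(props.index), props), outdir / "pentads.geojson"
        )
        if truth is not None:
            (outdir / "truth.json").write_text(
                json.dumps(truth.to_dict(), indent=2, default=float)
            )
        manifest = config.to_manifest()
        manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return ReportBundle(
        config=config,
        covariates=covariates,
        checklists=checklists,
        zones=zones,
        pca=pca,
        effort_table=effort_table,
        g_overall=g_overall,
        g_per_biome=g_biome,
        effort_fits=fits,
        moran=moran,
        curves=curves,
        fits=fits_acc,
        rankings=rankings,
        completeness=completeness,
        truth=truth,
        outdir=outdir,
    )


def summarize(bundle: ReportBundle) -> str:
    """Human-readable run summary: coverage, G-tests, extreme zones."""
    lines = []
    n_pentads = len(bundle.covariates)
    counts = bundle.checklists.lists_per_pentad().reindex(
        bundle.covariates.frame.index, fill_value=0
    )
    for t in bundle.config.thresholds:
        pct = 100.0 * float((counts >= t).sum()) / n_pentads
        lines.append(f"{pct:.1f}% of pentads sampled at the >={t}-list threshold")
    for t, res in bundle.g_overall.items():
        lines.append(
            f"G-test (>= {t} lists): G = {res.g:.3f}, df = {res.df}, p = {res.p_value:.3g}"
        )
    t0 = bundle.config.thresholds[0]
    ranking = bundle.rankings[t0]
    dcol = f"deficit_{t0}"
    lines.append("most oversampled zones (observed - expected pentads):")
    for zone, row in ranking.head(5).iterrows():
        lines.append(f"  {zone}: {row[dcol]:+.1f}")
    lines.append("most undersampled zones:")
    for zone, row in ranking.tail(5).iloc[::-1].iterrows():
        lines.append(f"  {zone}: {row[dcol]:+.1f}")
    if t0 in bundle.completeness:
        comp = bundle.completeness[t0]
        lines.append("least complete species inventories (% of estimated richness):")
        for zone, row in comp.head(5).iterrows():
            val = row["completeness_pct"]
            shown = f"{val:.1f}%" if np.isfinite(val) else "NA (fit flagged)"
            lines.append(f"  {zone}: {shown}")
    return "\n".join(lines)
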