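# Methods

This note documents the models implemented in `atlasbias`, the defaults of
the synthetic-atlas generator, and the numerical and design choices that
were genuinely open.

## Grid conventions and geometry

The sampling unit is the pentad, a 5′ × 5′ cell named by its north-west
corner as `ddmm_ddmm` (degrees + minutes of south latitude, then east
longitude; a three-digit degree field is accepted east of 100°E).
Coordinates are decimal degrees, south and west negative. Cells are
half-open toward the south-east, so every point belongs to exactly one cell
and a cell's own NW corner maps back to it; the midpoint is the corner
shifted 2.5′ south-east. Distances are great circles on a sphere of radius
6371.0 km. No ellipsoid is used: distances enter the effort model only
through a natural log (hubs) or a small linear slope (roads), so the
sub-0.3 % spherical error cannot move any conclusion. Road distance is
measured from the pentad midpoint to the nearest vertex of a densified
polyline; with vertices spaced ≤ 1 km the error against true
point-to-segment distance is bounded by half the vertex spacing, which is
why segment projection is deliberately not implemented. Hub distance is
midpoint-to-midpoint; road distance uses the midpoint as well, for
consistency with the hub convention.

## Effort model

Visit counts per pentad are assumed Poisson with log link:

    log E[y_i] = β0 + β_hub·log d_hub,i + β_road·d_road,i
               + β_prot·prot_i + β_urb·urb_i + β_cult·cult_i
               + β_P·z(precip_i) + β_S·z(t_summer,i) + β_W·z(t_winter,i)

Hub pentads themselves are excluded before fitting (their log-distance is
undefined and their effort is definitionally extreme). Climate variables
are standardized within each fitted group so coefficients are per SD and
the design stays well conditioned; cover fractions and road km are left on
their natural scales. Fitting is IRLS (via statsmodels) to a relative
deviance tolerance of 1e-10 within 100 iterations. Inference is
quasi-Poisson: the dispersion is the Pearson χ² divided by residual df,
standard errors scale by its square root, and t-values are referred to the
t distribution on residual df — so quasi-Poisson t-values are exactly the
naive Poisson z-values divided by √dispersion. Collinearity is reported as
VIF_j = 1/(1 − R²_j). Groups (a "province" analogue — grid quadrants in
the synthetic atlas) are fitted separately, mirroring the per-region
reporting convention of volunteer atlases.

Spatially correlated random effects are out of scope. Instead the pooled
model's Pearson residuals get a Moran's I diagnostic with inverse-distance,
row-standardized weights and a one-sided permutation p-value
((1 + #{I_perm ≥ I_obs}) / (n_perm + 1)). When the diagnostic flags
autocorrelation, quasi-Poisson standard errors are optimistic and should be
read qualitatively; point estimates are unaffected. This is a deliberate
trade of exactness for transparency and testability.

## Environmental stratification

PCA is computed on the correlation matrix of the three climate variables —
mm/yr and °C are incommensurable, so covariance PCA would be meaningless —
and each component's sign is fixed so its precipitation loading is
non-negative (high PC1 = wetter, milder). PC1 scores are cut into ten
equal-width classes over [min, max]; equal-width was chosen over quantiles
so that climatically extreme classes stay small rather than being forced to
equal counts, and the right edge is closed so the maximum lands in the top
class. Each pentad takes the biome with the largest cover fraction (ties →
lexicographically smallest label, with a warning). Biomes designated for
reassignment take the modal biome of their queen neighbourhood (non-
reassigned cells only), iterated to a fixed point, with a nearest-neighbour
fallback for isolated cells. The pipeline also applies this reassignment
policy automatically to any biome whose total expected frequency cannot
reach the pooling minimum — the stratification analogue of folding minority
vegetation units into their neighbours.

Zones are the occupied biome × class combinations. Pooling: while any
zone's expected frequency (zone size / total pentads × sampled total under
the stricter intensity threshold) is below `min_expected`, the smallest such
zone merges with the zone of the nearest climate class within the same
biome (ties toward the lower class); zone ids record the merged range, e.g.
`Fynbos:7+8`. `min_expected` is an expected **count** of 5 (Cochran's rule
for χ²-family tests). Each merge only ever raises the minimum expected
frequency, so pooling terminates.

## Representativeness

Observed zone counts are pentads with ≥ 1 and ≥ 10 lists; expected counts
are size-proportional: E_z = (n_z / N) · n_sampled. The evenness test is
G = 2 Σ O ln(O/E) with 0·ln 0 = 0, df = zones − 1, upper-tail χ² p-value.
Williams' small-sample correction is not applied (expected counts are ≥ 5
by construction, where the correction is negligible). Per-biome tests are
the same statistic on the biome's zones with expecteds recomputed within
the biome; they are reported unadjusted by default, with an optional Holm
step-down flag. Zones are ranked by observed − expected at each threshold;
deficits sum to zero by construction and this is asserted at run time.

## Accumulation and completeness

The accumulation unit is the pentad: a pentad contains a species if any of
its lists records it, and only pentads meeting the intensity threshold
enter a zone's incidence matrix. The default curve is exact sample-based
rarefaction, S(n) = Σ_j [1 − C(N−f_j, n)/C(N, n)], evaluated with log-gamma
arithmetic (stable to N in the thousands) and with the endpoint pinned to
S_obs. A randomized-ordering mean (default 1000 runs) is retained as a
fidelity mode; it converges to the exact curve at rate sd/√runs and the
across-run SD is reported so the Monte-Carlo error is known.

Three asymptotic models are fitted by Levenberg–Marquardt least squares:
Lomolino `Asym/(1 + slope^log10(xmid/n))` (log base 10 — other bases only
rescale the slope), Clench `Asym·n/(B + n)`, and Weibull
`Asym·(1 − exp(−(n/scale)^shape))`. Starts: Asym₀ = 1.1·S_obs; xmid₀/B₀
(and the Weibull half-point) at the interpolated n where the curve reaches
half of S_obs; slope₀ = 2; shape₀ = 1. Scale and shape parameters are
fitted on the log scale so the optimizer cannot step them non-positive;
tolerances are 1e-8. Non-convergence (or fewer than 4 curve points) flags
the fit rather than raising; flagged zones rank last with NA completeness.
Curve points are unweighted — rarefaction variances are not propagated into
the fit. Completeness is 100·S_obs/Asym; an asymptote below S_obs is
reported with a warning on the fit. Completeness is computed from the
Lomolino fit, which also wins the residual-SS comparison on sigmoidal
curves in ≥ 90 % of simulated replicates.

## Synthetic atlas: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes,
with every hidden parameter recorded for recovery tests.

* **Landscape** (default 40 × 40 pentads): climate surfaces are a linear
  gradient plus three seeded low-frequency sinusoids — cheap, fully
  deterministic, and spatially smooth enough to yield contiguous climate
  classes; a Gaussian-process field would add realism but no testable
  structure. Precipitation (150–950 mm/yr) and summer temperature
  (31–21 °C) run along the NW→SE diagonal in opposite directions; winter
  temperature (6–13 °C) runs mostly with latitude and carries extra
  texture, so it loads weakly on PC1 — the (+, −, +) leading-loading
  pattern characteristic of real summer-rainfall climate fields. Biomes are
  a nearest-seed partition (seven southern-African labels) softened into
  cover fractions near boundaries. Three hubs are placed well apart; roads
  are densified polylines linking hubs and random waypoints; urban cover
  decays exponentially from hubs (20 km scale), protected cover is the max
  over Gaussian patch kernels (capped at 0.95 so it can never saturate to a
  constant), cultivated cover tracks the precipitation rank.
* **Effort**: Poisson counts from the same log-linear model the analysis
  fits. Default coefficients: β_hub = −0.55 per log-km, β_road = −0.035 per
  km, β_prot = +1.3, β_urb = +2.2, β_cult = −0.3, small climate effects
  (+0.15, −0.10, +0.05 per SD), intercept 4.1. The signs encode the
  accessibility/attractiveness structure of volunteer effort; the intercept
  is set so the default atlas reproduces the coverage conditions typical of
  a mature volunteer atlas — roughly three quarters of pentads visited at
  least once and well under 16 % visited ten or more times.
* **Community**: each zone has a species pool of size
  R_z = 100 + 15 × (mean climate class), so mesic zones are richer; 25 % of
  the smallest pool is shared as widespread species. Per-species occupancy
  is Beta-distributed (shape 0.35, mean 0.2): the long tail of rare species
  is what keeps real accumulation curves rising and puts default
  completeness in the realistic 80–95 % band rather than at saturation.
* **Observation**: each visit detects each occupying species independently
  with p_det = 0.55; detection is false-negative only (atlas vetting removes
  false positives), so a checklist is always a subset of the pentad's true
  occupants. Visits that detect nothing are dropped (a contributed list has
  ≥ 1 species) but tallied in the truth record.

Not emulated: observer skill heterogeneity, seasonal/temporal structure,
within-pentad habitat coverage (detection is i.i.d. across visits), spatial
autocorrelation in effort beyond the covariates, and multi-day protocol
variants. Passing recovery tests on this generator therefore shows the
estimators are correct under the stated model, not that real atlas data
satisfy that model — in particular, real effort counts are overdispersed
and spatially correlated, which is exactly what the dispersion estimate and
the Moran diagnostic are there to flag.

## Determinism and problem sizes

All randomness flows from explicit seeds; the pipeline derives per-stage
seeds from a master seed by hashing, and the manifest (config hash, seeds,
version) reproduces every output byte-for-byte. The test-suite and
acceptance problem sizes — 40 × 40 default grids, a 60 × 60 grid with 200
replicates for coefficient-coverage checks, 1000-run permutation curves at
N = 40, 2000-table G-test calibration — were chosen as the smallest sizes
at which the Monte-Carlo error of each check is comfortably below the
property being asserted.
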