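# Methods

## Data model and units

Input coordinate tables carry one row per annotated cell: subject id,
class (`cancer` or `cd8`), x/y in µm as exported by the image-analysis
platform, and optionally the platform's shortest distance from a CD8⁺
cell to a tumor gland (µm).  All spatial computation happens in mm after
an exact 1:1000 rescaling.  The observation window is the per-subject
bounding box of all annotated points of both classes: the platform
exports points, not region polygons, and the bounding box is the only
window reproducible from the coordinates alone.  All operations
downstream are translation-invariant, so the exported origin and axis
orientation are immaterial.

## TIL selection and subject inclusion

Tumor-infiltrating CD8⁺ cells are those within 50 µm of a tumor gland
(boundary inclusive).  When the platform's distance column is present it
is preferred — it measures distance to annotated gland objects rather
than to cell centroids; otherwise the nearest cancer-centroid distance
(KD-tree) stands in, and the source used is recorded per subject.
Subjects with fewer than 10 cancer cells or fewer than 10 CD8⁺ cells are
excluded with the rule that fired; by default the rule is evaluated on
post-filter counts, since every downstream statistic consumes filtered
cells (a pre-filter evaluation is a config switch).

## Quadrat grids

Square quadrats of 0.5 mm (configurable) are anchored at the window's
minimum corner, with `ceil(extent/size)` rows/columns; partial edge
quadrats are retained as ordinary quadrats (their area deficit is
absorbed by the count model, which conditions on the observed cancer
count rather than on exposure).  Point assignment is half-open — a point
on an interior boundary belongs to the higher-index quadrat — with the
final row/column closed so nothing at the maximum edge is lost.  Counts
are conserved by construction and checked against brute-force binning in
the tests.  Quadrats with zero counts of both classes (tissue outside
the cancer region) are flagged inactive and excluded before any summary
or model, including the quadrat-wise SDs; excluding them after the
summaries is possible in principle but empty-tissue quadrats would then
dominate the SD, so the pre-exclusion convention is fixed here.

Per-subject quadrat summaries are the mean and sample SD (ddof = 1) of
each class's counts over active quadrats; a single active quadrat
reports SD 0 with a warning.

Kernel intensity maps use the radially symmetric quartic (biweight)
kernel K(u) = (3/π)(1 − ‖u‖²)² on ‖u‖ ≤ 1, scaled to a bandwidth radius
of 0.25 mm by default (half a quadrat; no bandwidth is canonical for
this analysis, and the maps are presentation-layer only — no downstream
statistic consumes them).  No edge correction is applied; mass
conservation away from edges is tested.

## Per-subject slope

Over a subject's active quadrats, CD8⁺ counts follow an NB2 GLM with log
link in the cancer count.  Coefficients and dispersion are estimated by
joint maximum likelihood (equivalent to the familiar alternating
IRLS/θ-profile scheme at the optimum).  When the estimated
overdispersion 1/θ collapses below 1e-4 — equidispersed data — the fit
falls back to a Poisson GLM, θ is reported as infinite and the family
used is recorded.  Constant cancer counts are a degenerate design and an
error; non-converged subjects are excluded from cohort models and always
reported.  Slopes are presented at 4 decimals and fold changes
exp(n·β) at 2, matching the conventional reporting precision.

Subjects are dichotomized at the whole-cohort median slope, with
β ≥ median labelled HigherSlope (ties therefore all land in
HigherSlope).

## Cohort models

**Log-slope OLS.**  The slope distribution is right-skewed, so OLS runs
on log β with treatment (reference: naïve), sex, age (linear, years),
grade (reference: G1) and stage (reference: I).  The treatment
coefficient exponentiates to the NAT/naïve ratio of typical slopes.
Slopes ≤ 0 have no logarithm and the analysis that motivated this model
left its handling unstated; the default policy excludes them and reports
the excluded ids, with a shifted-log alternative (log(β + c),
configurable c) for sensitivity analysis.  Single-level factors are
dropped with a warning; rank-deficient designs are a hard error naming
the aliased terms.

**Heterogeneity OLS.**  Same covariates, response = subject's
quadrat-wise cancer-count SD.  The treatment coefficient is the adjusted
NAT−naïve difference in counts per quadrat (negative = NAT less
heterogeneous).

**NB GLMM.**  Pooled active quadrats follow
cd8 ~ NB(exp(b₀ + b_c·cancer + b_t·NAT + b_x·cancer·NAT + u_subject), θ)
with u ~ N(0, σ²).  Only the three fixed effects and the interaction are
included — the cohort contrast of interest — with no additional
clinical covariates.  The marginal likelihood integrates u out per
subject: the inner mode is found by a safeguarded Newton iteration (the
joint density is strictly concave in u), and the integral uses a Laplace
approximation by default or adaptive Gauss–Hermite quadrature (≥ 5
nodes, default 7) as a verification mode; the two agree to < 0.01% on
the test fixtures.  The outer problem optimizes (b, log θ, log σ) by
L-BFGS-B (monotone over accepted iterates; bounds keep θ ∈ [1e-3, 1e4]
and σ ∈ [1e-4, 10]), starting from the pooled NB GLM with σ = 0.3, with
three seeded jitter restarts on failure.  Standard errors come from the
central-difference Hessian of the marginal log-likelihood; convergence
diagnostics (gradient norm, Hessian condition) are always attached.
exp(100·b_c) and exp(100·(b_c+b_x)) are the per-100-cancer-cell fold
changes for the naïve and NAT arms, exp(100·b_x) their ratio.  Random
slopes are deliberately out of the default model (subject-level
variation beyond the intercept is left to the per-subject GLMs).

## Survival

Kaplan–Meier curves use the product-limit estimator with log-log
pointwise intervals; the median CI is read off where the interval
crosses ½, and a curve that never reaches ½ reports the median as not
reached.  The Cox model regresses survival on the slope group
(reference: LowerSlope, so HR < 1 for HigherSlope reads as protection),
treatment, sex, AgeCat (age ≥ 70 years = upper, matching the cohort
median age of 70; linear age is a config alternative), grade and stage,
with Efron tie handling.  Factor levels with fewer than 2 events can be
collapsed into the adjacent level (flagged, logged) — stage IV is rare
enough in realistic cohorts to separate otherwise.  On a
monotone-likelihood failure the fit retries with a small ridge penalty
and the result is flagged as not cleanly converged.

## Synthetic cohorts

The generator emulates the structure the analysis models assume, at the
scale of the motivating cohort; its defaults are the study conditions
and are not tuned per run.

* **Cancer cells**: Thomas cluster process — Poisson parents at
  κ = 1.5 /mm², Poisson(μ = 72) offspring displaced by isotropic
  Gaussian σ = 0.1 mm, clipped to an 8 × 6 mm window (192 quadrats).
  This yields ≈ 4–5·10³ cancer cells per subject and, crucially, a
  heavy-tailed per-quadrat count distribution (mean ≈ 28, SD ≈ 26 per
  active quadrat) of gland-like clusters.
* **CD8⁺ cells**: per quadrat, NB(exp(α + β·cancer), θ = 2) — the exact
  generative twin of the fitted subject GLM.  Subject slopes are
  lognormal about arm medians 0.0078 (naïve) and 0.017 (NAT) with log-SD
  0.6, covering the observed −0.006…0.105 range after estimation noise.
  The intercept is anchored per subject so the mean CD8⁺ count per
  cancer-bearing quadrat is 5 regardless of β (this also bounds the NB
  means, guarding against overflow for steep slopes).  Within a quadrat,
  CD8⁺ cells scatter around randomly chosen cancer cells (Gaussian
  20 µm), so simulated TILs sit near glands and the 50-µm filter behaves
  as it does on platform data; an alternative continuous mode draws an
  inhomogeneous Poisson pattern with intensity exp(a + b·smoothed cancer
  density) by thinning.
* **Clinical and survival**: covariate margins follow the cohort mix
  (54.5% male, age ≈ N(69.5, 9) clipped to 46–88 giving a median near
  70, grade 18/50/32%, stage 24/58/15/3%).  Survival is exponential
  under a log-linear predictor: HigherSlope log-HR log(0.33) (the
  protective effect the survival analysis targets), NAT log 2.0
  (NAT patients present with worse baseline disease), grade and stage
  effects rising to log 2.4 / log 3.5, AgeCat log 1.3.  The baseline
  rate (ln 2 / 2400 d⁻¹) and the independent Uniform(0, 4200 d)
  censoring were calibrated once against the cohort targets — overall
  KM median ≈ 678 days and ≈ 73% observed deaths — and then frozen.
* **Determinism**: one `SeedSequence` per cohort, spawned per subject,
  so the same seed reproduces the cohort byte-for-byte even under
  subject-level parallelism.

What the generator does **not** emulate: anisotropic gland shapes,
tissue-boundary effects, spatial autocorrelation of CD8⁺ counts beyond
what the shared cancer pattern induces, platform segmentation error, or
informative censoring.  Passing recovery tests therefore demonstrate
that the estimators are correct under the models' own assumptions — not
that those assumptions hold in tissue.

## Problem sizes and tolerances in the test suite

Recovery studies run at desk scale: 200-quadrat subjects; 1000 subjects
per arm for the slope bias/coverage study (the NB ML slope carries a
genuine small finite-sample bias of ≈ −1.5·10⁻⁴ at 200 quadrats, about
5–7% of its sampling SD, so the bias estimate needs Monte-Carlo error
well below the 10% bound being checked); 60 subjects × 200 quadrats for
the GLMM self-consistency run; 100 replicates of n = 244 for hazard-ratio
CI coverage; 500 replicates for the two null-calibration studies.  Exact
oracles (brute-force binning, exhaustive pairwise distances, hand
product-limit arithmetic, an explicit Efron partial likelihood optimized
independently) back the counting and survival layers.  All stochastic
tests are seeded and deterministic.

## Known limitations

* Quadrats are treated as independent within a subject, as the count
  model assumes; no spatially correlated error structure is offered.
* Partial edge quadrats carry no exposure offset.
* The GLMM's Wald inference relies on the Laplace-approximated
  likelihood; with very few subjects per arm the random-intercept
  variance can sit on its lower bound.
* Density maps are uncorrected at edges and intended for display only.
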