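# tilspatial

Quadrat-based spatial coupling of CD8⁺ tumor-infiltrating lymphocytes and
cancer cells in resected pancreatic ductal adenocarcinoma (PDAC), with
cohort-level contrasts between neoadjuvant-treated (NAT) and
treatment-naïve patients and survival analysis of the resulting groups.

## Who this is for

Digital-pathology and biostatistics groups that have per-cell coordinate
tables (cell class, x/y in µm, optionally a distance-to-gland column)
exported from an image-analysis platform, plus a subject-level clinical
table, and want a tested, reproducible implementation of the
quadrat-count spatial-coupling analysis — or a fully synthetic cohort
generator to study the method's operating characteristics.

## The statistic

For one subject, the window is tessellated into 500 × 500 µm quadrats and
both cell classes are counted per quadrat (quadrats empty of both classes
are excluded).  CD8⁺ counts are modelled by a negative-binomial GLM with
log link:

    cd8_i ~ NB(μ_i, θ),   log μ_i = α + β · cancer_i

The slope β is the subject's spatial-coupling statistic: an increase of
*n* cancer cells per quadrat multiplies the expected CD8⁺ count by
exp(*n*·β).  A slope of 0.0282 therefore reads as a 1.33-fold change in
CD8⁺ cells per 10 extra cancer cells.

Around this, the package provides:

* **TIL selection** — CD8⁺ cells ≤ 50 µm from a tumor gland (platform
  distance column when present, nearest cancer-centroid otherwise), and
  exclusion of subjects with fewer than 10 cells of either class;
* **cohort contrasts** — OLS of log β on treatment + sex, age, grade,
  stage; OLS of the quadrat-wise cancer-count SD (an intratumoral
  heterogeneity proxy) on the same covariates; and a negative-binomial
  GLMM over all subjects' quadrats with a cancer × treatment interaction
  and subject random intercepts (Laplace, with adaptive Gauss–Hermite as
  a verification mode);
* **survival** — Kaplan–Meier curves and a multivariate Cox model (Efron
  ties) of the median-split slope groups (β ≥ cohort median =
  HigherSlope), adjusted for treatment, sex, AgeCat (≥ 70 years), grade
  and stage;
* **synthetic cohorts** — Thomas-process cancer patterns, a
  quadrat-generative NB twin for CD8⁺ cells, clinical margins and
  proportional-hazards survival with known ground truth.

## Worked example

```python
import numpy as np
from tilspatial.simulate import simulate_quadrat_counts
from tilspatial.models.subject import SubjectSlopeModel, fold_change

rng = np.random.default_rng(7)
cancer, cd8 = simulate_quadrat_counts(192, alpha=np.log(5) - 0.017 * 28,
                                      beta=0.017, theta=2.0, rng=rng)
res = SubjectSlopeModel(cancer, cd8, subject_id="S001").fit()
print(res.summary())
```

prints

```
Subject S001: NB GLM of CD8+ on cancer quadrat counts
  quadrats used (active): 192
  intercept  +1.2118 (SE 0.0989)
  slope beta +0.0142 (SE 0.0028)
  dispersion theta 1.56  family negbin
  fold change per 10 cancer cells: 1.15
  converged: True
```

The subject was simulated with a true slope of 0.017 — the NAT-arm median
— and the fit recovers 0.0142 ± 0.0028: CD8⁺ density rises ≈ 15% per 10
extra cancer cells in a quadrat.  `fold_change(beta, n)` exposes the
exp(n·β) reading directly; dispersion θ is the NB size parameter
(variance = μ + μ²/θ).

The full pipeline runs from the command line; without `--cells` it
simulates a 66-subject cohort first:

```
tilspatial run --seed 11 --out out/
tilspatial config --show-defaults
```

`out/report.txt` summarises per-arm median slopes with their fold
changes, the log-slope treatment ratio, the GLMM fold changes per 100
cancer cells, the heterogeneity contrast, the overall Kaplan–Meier
median, and the HigherSlope-vs-LowerSlope hazard ratio; delimited
intermediates (slope table, quadrat counts, KM step functions, forest
data) sit alongside it.

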