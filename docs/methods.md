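# Methods

This note documents the models, defaults and numerical choices behind
`physiodys`, and what the synthetic-data tests do and do not establish.

## The synthetic cohort

The generator emulates a two-season, two-stage repeated-measures study of
breeding females. Structure: `n_females` (default 93) split 60/40 between the
two entry years; first-year females return the next season with probability
0.35; every female-season contributes an incubation sample, a chick-rearing
first-brood sample with recapture probability 0.5, and occasionally a sampled
second-brood chick-rearing row (second-brood rate 0.35, sampling rate 0.25).
These rates were fixed once to land near the motivating study's scale
(93 females, ~150–190 samples, chick-rearing cell sizes of ~40–55,
complete-case multivariate sets of ~80 with and ~120 without reticulocytes)
and are not tuned thereafter.

Biomarker values follow a variance-components model per year-stage cell
(y, s):

    x = mean[y,s] + a_i · sd[y,s] · √icc + e · sd[y,s] · √(1 − icc)

with `a_i` a per-female standard-normal draw shared across all samples (so
`icc` is the between-individual variance fraction a repeatability analysis
should recover) and `e` a row-level draw from a multivariate normal whose
correlation matrix defaults to near-diagonal (hematocrit–hemoglobin 0.5,
OXY–dROMs 0.3, agglutination–lysis 0.3, dROMs–uric acid −0.2), consistent
with panels that show little cross-system co-variation. Cell means for
reticulocytes, OXY and glucose follow the published year-by-stage patterns
(e.g. reticulocytes 15.6 → 8.2% across stages in the first year but flat in
the second); the remaining means/SDs are plausible round values for breeding
starlings, documented as defaults rather than data. Draws for non-negative
assays are clipped at an assay floor (`lower_bound`, usually 0) so that
log/sqrt transforms stay defined; at the default mean/SD ratios the clipping
probability is < 0.2% and the induced mean bias is negligible.

Outcomes are drawn per female-season from three families — Gaussian
(visit rate, fledging masses, next-season lay date), Poisson counts (brood
sizes), Bernoulli (second-brood initiation, return) — independent of
physiology unless `effect_map` plants effects on the linear predictor via the
female's standardized chick-rearing biomarker values. Season totals
(young fledged, fledgling mass, two-season productivity) are derived sums,
which makes them mildly overdispersed relative to Poisson — deliberate, and
absorbed by the quasi-Poisson fits below. Missingness is completely at
random per biomarker (reticulocytes 0.30, most assays 0.03), reflecting
plasma-volume limits rather than biology. Brood-2 outcomes exist only when a
second brood happened; first-brood fledging mass is undefined for total
failures.

What the generator does **not** emulate: within-stage temporal dynamics,
non-random missingness, female-level random effects on outcomes,
density/weather covariates, and measurement error in outcomes. Passing tests
therefore establish the statistical machinery's correctness and calibration
under the stated structure, not field validity of any biological conclusion.

## Pre-treatment

Right-skewed assays are natural-log transformed (corticosterone, creatine
kinase, triglycerides, dROMs, haptoglobin) and reticulocyte percentages are
square-root transformed; the map is configurable and recorded in the run
manifest. Females with baseline corticosterone strictly above 80 ng/ml
(stress-induced territory) are excluded from the univariate path only; the
multivariate path keeps them for sample size, with a sensitivity flag to drop
them. Agglutination + lysis and OXY + dROMs are each compressed by a PCA of
the two centered/reduced scores; axes are oriented so PC1 is "activation"
(both loadings positive where the inputs co-vary positively, otherwise the
dominant loading positive) and PC2 the "balance" contrast.

Standardization removes year and stage means by regression: per variable an
additive OLS fit `value ~ year + stage` supplies the cell mean to subtract —
the four year-stage cells are too small for robust direct means — and the
residual SD supplies the scale (not the raw cell SD, for the same
small-cell reason). An effectively exact additive fit (residual SD below
1e−10 of the data scale) keeps its zero residuals instead of dividing float
noise by a vanishing scale. Stage deltas are chick-rearing minus incubation
per female-season, first broods only, computed on the transformed scale.
Unknown-sex nest visits are allocated to the sexes in proportion to the known
counts (totals conserved exactly); wing loading is mass/area mean-centered
within year because measurers differed between years.

## Dysregulation scores

Scores are Mahalanobis distances on the standardized panel. The covariance is
estimated once from all complete-case standardized rows, pooled across cells
(per-cell n is too small), with two policies: `sample` (error on singular
input, pointing at the alternative) and `shrinkage` (convex combination with
its own diagonal, smallest weight on a 0–1 grid that bounds the condition
number below 1e6; weight 0 whenever the sample covariance is well
conditioned, so the policies agree there). Distances are computed via
Cholesky solves, never explicit inverses. The default variable set is the 10
single markers plus the four composite axes (14 variables; 13 without
reticulocytes); whether composites or their raw constituents enter is
configurable. Centroid versions v1–v4 are illustrative a-priori hypotheses
built from direction arguments (low oxidative activation/balance; low damage
and turnover markers; high aerobic and immune capacity; metabolic directions)
— the plausible-optimum assignments, like the raw per-cell tables, are not
published, so these are package defaults. v5 draws one MEAN/HIGH/LOW choice
per biomarker from the run seed and records it in the manifest.

## PCA summaries

All PCAs fix signs deterministically (each axis's dominant loading positive;
the reproduction axis additionally flipped so the loading sum is positive,
making higher scores mean higher productivity). The deviational transform is
`ln(|z| + 1e−8)`; the floor keeps exactly-mean observations finite, and
re-centering/re-scaling the transformed columns makes the result invariant to
sign flips of any input. Group membership defaults — aerobic {hematocrit,
hemoglobin, reticulocytes}, metabolism {triglycerides, NEFA, uric acid},
oxidative {OXY, dROMs, creatine kinase} — are configurable; a group without
exactly three members warns and proceeds. No rotations, no axis-stability
bootstrap.

## Association models

* **Gaussian outcomes**: linear mixed model with an individual random
  intercept, fitted by REML with the variance ratio profiled out (Brent
  search); fixed-effect tests use a Satterthwaite-style df from
  finite-difference curvature of the restricted likelihood, falling back to
  n − rank(X) at the boundary. When every individual contributes one row the
  random term is dropped with a note (the component is inestimable). Year
  enters as a fixed covariate — with two year levels a year random effect is
  not meaningfully estimable — and body mass is a covariate in stage-specific
  univariate fits. The fitter matches statsmodels MixedLM to numerical
  precision (cross-checked in the tests) but runs ~two orders of magnitude
  faster, which is what makes 200-cohort calibration runs affordable.
* **Count outcomes** (brood sizes, fledged totals): quasi-Poisson — log-link
  Poisson by Newton/IRLS with the Fisher covariance scaled by the Pearson
  dispersion (floored at 1) and a t(n − p) reference. This absorbs the
  derived totals' mild overdispersion while staying near nominal size at
  n ≈ 40–120, where cluster-sandwich estimators are anticonservative.
* **Binary outcomes** (second brood, return): logistic regression reporting
  the odds ratio with a 95% Wald CI; complete separation (non-convergence or
  |β| > 15) is flagged, with the CI reported as unbounded, rather than
  raised.
* **Repeatability**: r = σ²_between / (σ²_between + σ²_within) from a
  random-intercept REML fit; p from the boundary likelihood-ratio test with
  the equal-mixture χ²₀/χ²₁ null. Per-year and pooled estimates are reported
  side by side because pooling across shifted year means manufactures
  "apparent" repeatability.
* **Multiple testing** is deliberately not adjusted across the grids (the
  design reads patterns, not single cells); Benjamini–Hochberg FDR applies
  only to the pairwise correlation screen.

Grid accounting is exact: every planned cell yields a result row; fit
failures are flagged (`degenerate`, with the reason) and counted in totals,
never dropped. The annual-mean window averages each female-season's available
scores (mean of scores, not score of means). The survival block fits one
logistic per DM version on chick-rearing scores from the without-reticulocyte
subset (the larger complete-case set).

## Determinism and problem sizes

One global seed fans out to fixed per-stage sub-seeds (simulation, the v5
centroid draw) via `SeedSequence`, so stages re-run in isolation reproduce
the full run. The Monte-Carlo acceptance checks use 200 null cohorts at the
default 93-female design for type-I calibration (each grid's pooled
significant fraction at α = 0.05 must lie in [0.035, 0.065], as must each
model family's), 30–50 cohorts for icc and slope recovery, and a ~1,400-row
standardized cohort for the E[DM²] = p trace identity. Repeatability
tolerances are stated for Monte-Carlo means: a single icc estimate at 100
females × 2 observations has sampling SD ≈ 0.1, so per-replicate agreement
within ±0.1 cannot be guaranteed by any correct estimator.

## Known limitations

Kenward-Roger df (used by the original lme4 workflow) are approximated by the
Satterthwaite-style scheme above; differences are negligible at these sample
sizes. The Poisson family is marginal (quasi-likelihood), not a conditional
GLMM; with at most two rows per female and outcome draws independent across
seasons this is a calibration-neutral simplification. Logistic fits carry no
random effects (matching the original `glm` usage). The exact published
centroid assignments, per-variable transforms and raw per-cell moments are
not deposited; all corresponding defaults are configurable and logged, and
none of the package's acceptance checks depend on them beyond the printed
main-text values.
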