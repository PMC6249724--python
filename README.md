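# physiodys

Multivariate physiological-state analysis for repeated-measures field studies
of breeding birds — and, more generally, for any cohort in which individuals
carry a multi-system biomarker panel sampled at a few life-history stages and
a set of workload / fitness outcomes.

The motivating design is a two-year study of female European starlings
(*Sturnus vulgaris*) blood-sampled during incubation and chick-rearing: 13
physiological variables spanning aerobic capacity (hematocrit, hemoglobin,
reticulocytes, corticosterone), oxidative stress and muscle damage (OXY,
dROMs, creatine kinase), intermediary metabolism (NEFA, triglycerides,
glucose, uric acid) and immune function (haptoglobin, natural-antibody
agglutination/lysis), related to provisioning workload, current and future
reproduction, and local return (survival).

## What the package computes

**Dysregulation scores.** For a standardized biomarker vector `x`, centroid
`μ` and pooled covariance `S`, the dysregulation score is the Mahalanobis
distance

    DM = sqrt((x − μ)ᵀ S⁻¹ (x − μ))

DM = 0 means the profile sits at the presumed physiological optimum; larger
values mean a more abnormal joint profile. Because some markers plausibly
have optima away from the population mean, the centroid is configurable per
biomarker: MEAN (0 on the z scale), HIGH (+3 SD) or LOW (−3 SD). Six versions
ship: v0 (all means), v1–v4 (a-priori direction hypotheses) and v5 (seeded
random choices), each with and without the reticulocyte variable (which has
heavy missingness and shrinks the complete-case set).

**PCA summaries.** Directional PCA of the standardized panel (signed
co-variation), deviational PCA of `ln(|z| + ε)` (shared *magnitudes* of
departure, the structure the dysregulation idea posits), PC1 of three
3-variable functional groups, and a 4-variable reproduction composite.

**Association grids.** Every predictor × outcome contrast is fitted with the
outcome's family — Gaussian linear mixed model with an individual random
intercept (REML, Satterthwaite-style df), quasi-Poisson count regression, or
logistic regression — yielding 13×12 = 156 absolute and 14×12 = 168
stage-change (delta) univariate contrasts, a 6×2×3×11 = 396-test DM grid and
a 9×3×11 = 297-test PCA grid over three observation windows (incubation,
chick-rearing, annual mean), plus a survival logistic per DM version.
Repeatability (intraclass correlation) comes from random-intercept fits with
boundary likelihood-ratio p-values; the pairwise correlation screen carries
Benjamini–Hochberg FDR adjustment.

**Synthetic cohorts.** A seeded generator reproduces the study's data
structure — stage/year mean shifts, individual repeatability (`icc`),
cross-biomarker residual correlation, assay missingness, recapture and
second-brood/return structure — with configurable physiology→outcome effect
sizes (`effect_map`), so every stage is testable with no field data. The
default is the global null: outcomes carry no physiological signal.

## Worked example

```python
from physiodys import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1))
for name, s in report.summaries.items():
    print(f"{name}: {s.n_significant}/{s.total_tests} significant "
          f"({s.proportion:.1%}) at alpha={s.alpha}")
```

prints

```
univariate_absolute: 11/156 significant (7.1%) at alpha=0.05
univariate_delta: 12/168 significant (7.1%) at alpha=0.05
dm: 17/396 significant (4.3%) at alpha=0.05
pca: 7/297 significant (2.4%) at alpha=0.05
```

Read this the way the analysis is meant to be read: under the default null
cohort, roughly 5% of the hundreds of contrasts come up significant by chance
alone, so a real dataset showing ~5–10% scattered, unreplicated hits provides
no coherent evidence that physiological state drives workload or fitness.
The `examples/` directory has one narrative script per capability
(simulation, preprocessing, dysregulation scoring, PCA summaries, association
grids, repeatability — including the pooled-year "apparent repeatability"
artifact); each prints the numbers it computes and what they mean.

A thin CLI wraps the same pipeline:

```bash
physiodys all --seed 1 --out results/run1   # writes CSVs + manifest.json
physiodys dm --seed 1                        # stage-wise, same sub-seeds
```

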