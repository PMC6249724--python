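"""Integrated physiology and performance summaries by PCA.

Directional PCA looks for signed co-variation in the standardized panel;
deviational PCA (on log absolute z) looks for shared *magnitudes* of
departure from the adjusted means; group PCAs compress three-variable
functional groups; the reproduction PCA compresses four productivity
measures into one composite axis.
"""

from physiodys import RunConfig, reproduction_pca, run_pipeline

report = run_pipeline(RunConfig(seed=1))

for kind in ("directional", "deviational"):
    res = report.pca_results[kind]
    frac = ", ".join(f"{v:.1%}" for v in res.variance_fraction)
    print(f"{kind} PCA, first 3 axes explain: {frac}")
print("(weak leading axes: little coherent co-variation across systems)")

for kind, res in report.pca_results.items():
    if kind.startswith("group_"):
        print(f"{kind}: PC1 explains {res.variance_fraction[0]:.1%}")

repro = reproduction_pca(report.outcomes)
print("\nreproduction PC1 loadings (oriented so higher score = more "
      "productive; under a null cohort weakly related measures load weakly):")
print(repro.loadings.round(3))
print(f"explains {repro.variance_fraction[0]:.1%} of productivity variance")
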