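"""The association grids: does physiology predict workload or fitness?

Every predictor x outcome contrast is fitted with the outcome's model family
(Gaussian mixed model, quasi-Poisson count model, logistic regression).  The
question is answered by the *pattern*: if physiology carries no signal, about
5% of tests come up significant at alpha = 0.05 by chance alone.
"""

from physiodys import RunConfig, run_pipeline
from physiodys.association import results_frame

report = run_pipeline(RunConfig(seed=1))

for name, summary in report.summaries.items():
    print(f"{name}: {summary.n_significant}/{summary.total_tests} significant "
          f"({summary.proportion:.1%}) at alpha={summary.alpha}")
print("fractions near 5% are what a physiology-blind null produces")

surv = results_frame(report.results["survival"])
print("\nsurvival (local return) logistic per DM version:")
print(surv[["predictor", "odds_ratio", "or_low", "or_high", "p", "n"]]
      .round(3).to_string(index=False))
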