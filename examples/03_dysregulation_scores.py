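"""Mahalanobis dysregulation scores under alternative centroid hypotheses.

DM = sqrt((x - mu)' S^-1 (x - mu)) on the standardized panel: 0 means the
profile sits at the presumed physiological optimum, larger values mean a more
abnormal multivariate profile.  v0 takes every optimum at the mean; v1-v4
move selected optima to mean +/- 3 SD from a-priori direction hypotheses
(e.g. low oxidative activation is better); v5 randomizes the choices.
"""

import pandas as pd

from physiodys import RunConfig, dm_sensitivity, run_pipeline
from physiodys.dysregulation import DMConfig, default_centroid_specs

report = run_pipeline(RunConfig(seed=1))

for label in ("dm_v0_with_retics", "dm_v0_no_retics", "dm_v3_no_retics"):
    s = report.dm_scores[label]
    print(f"{label}: n={len(s.scores)} mean={s.scores.mean():.2f} "
          f"max={s.scores.max():.2f} dropped={len(s.dropped)} incomplete rows")

configs = [DMConfig(spec=s, include_reticulocytes=False)
           for s in default_centroid_specs()]
corr = dm_sensitivity(report.panel, configs)
print("\ncorrelation between centroid versions (shared complete cases):")
print(corr.round(2))
print("high correlations mean conclusions are robust to the centroid choice")
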