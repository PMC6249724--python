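"""Pre-treatment: transforms, outlier policy, composites, standardization.

Right-skewed assays are log/sqrt-transformed; agglutination+lysis and
OXY+dROMs are collapsed to activation/balance PC pairs; year and stage means
are removed by regression (the four year-stage cells are too small for robust
direct means) and each variable is scaled by its residual SD.
"""

import pandas as pd

from physiodys import (default_config, exclude_cort_outliers, generate_cohort,
                       immune_composite, normalize_variables,
                       oxidative_composite, standardize_by_cell)
from physiodys.pipeline import PANEL_VARIABLES

cohort = generate_cohort(default_config(), seed=1)
data, applied = normalize_variables(cohort)
print("transforms applied:", applied)

kept, excluded = exclude_cort_outliers(cohort, threshold=80.0)
print(f"corticosterone outliers excluded (univariate path): {len(excluded)}")

nab = immune_composite(data["agglutination"], data["lysis"])
ox = oxidative_composite(data["oxy"], data["droms"])
print("NAb PC variance fractions:", nab.variance_fraction.round(3),
      "(PC1 = immune activation, PC2 = balance)")
print("Ox PC variance fractions:", ox.variance_fraction.round(3))

data = pd.concat([data, nab.scores, ox.scores], axis=1)
panel = standardize_by_cell(data, PANEL_VARIABLES)
print("\nstandardized panel:", panel.values.shape,
      "- per-variable adjustment betas (first rows):")
print(panel.adjustment_betas.head(3).round(2))
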