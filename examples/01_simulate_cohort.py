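"""Simulate a synthetic starling cohort and inspect its structure.

The generator emulates a two-year, two-stage repeated-measures field study:
93 females, blood-sampled at incubation and (when recaptured) chick-rearing,
with 14 assay columns, body mass, nest-visit counts and per-season breeding
outcomes.  Everything is seeded and reproducible.
"""

from physiodys import default_config, generate_cohort

cohort = generate_cohort(default_config(), seed=1)

print(f"observations: {len(cohort)} rows from "
      f"{cohort['female_id'].nunique()} females")
print(cohort.groupby(["year", "stage"]).size().rename("n"))
print("\nreticulocyte means by cell (%, note the 2013 stage drop):")
print(cohort.groupby(["year", "stage"])["reticulocytes"].mean().round(1))
print("\nmissing reticulocyte fraction:",
      round(cohort["reticulocytes"].isna().mean(), 2),
      "(many samples lack a usable smear)")
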