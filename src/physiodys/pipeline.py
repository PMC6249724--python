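"""End-to-end orchestration: simulate -> preprocess -> score -> associate.

A single seeded call runs the full analysis on a synthetic (or supplied)
cohort and returns every intermediate product plus a manifest of the run
(grid sizes, drop counts, covariance condition numbers, the random-centroid
draws, exclusions).  Stages re-run in isolation reproduce the full run
because the one global seed is fanned out to fixed per-stage sub-seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import dysregulation as dysreg
from . import pca as pcamod
from . import preprocess as prep
from .cohort import (CHICK_REARING, INCUBATION, OUTCOME_COLUMNS, CohortConfig,
                     default_config, generate_cohort, read_cohort)

log = logging.getLogger("physiodys")

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "make_fixtures"]

#: standardized-panel variables: transformed assays plus composite axes
PANEL_VARIABLES = [
    "hematocrit", "hemoglobin", "reticulocytes", "corticosterone",
    "creatine_kinase", "oxy", "droms", "nefa", "triglycerides", "glucose",
    "uric_acid", "haptoglobin", "nab_pc1", "nab_pc2", "ox_pc1", "ox_pc2",
]


@dataclass
class RunConfig:
    source: str = "simulate"               # "simulate" or a CSV path
    seed: int = 0
    cohort: CohortConfig = field(default_factory=default_config)
    transform_map: dict = field(default_factory=lambda: dict(prep.DEFAULT_TRANSFORM_MAP))
    centroid_specs: list = field(default_factory=dysreg.default_centroid_specs)
    dm_subset: list = field(default_factory=lambda: list(dysreg.DM_VARIABLES))
    reticulocyte_options: tuple = (True, False)   # DM subsets to score
    covariance_policy: str = "sample"
    group_members: dict = field(default_factory=lambda: dict(pcamod.DEFAULT_GROUPS))
    univariate_outcomes: list = field(
        default_factory=lambda: list(assoc.UNIVARIATE_OUTCOMES))
    multivariate_outcomes: list = field(
        default_factory=lambda: list(assoc.MULTIVARIATE_OUTCOMES))
    alpha: float = 0.05
    drop_cort_outliers_multivariate: bool = False   # sensitivity flag
    cort_threshold: float = 80.0
    outdir: str | None = None

    def to_yaml(self, path) -> None:
        doc = {
            "source": self.source,
            "seed": self.seed,
            "alpha": self.alpha,
            "covariance_policy": self.covariance_policy,
            "reticulocyte_options": list(self.reticulocyte_options),
            "cort_threshold": self.cort_threshold,
            "drop_cort_outliers_multivariate": self.drop_cort_outliers_multivariate,
            "transform_map": self.transform_map,
            "group_members": self.group_members,
            "univariate_outcomes": self.univariate_outcomes,
            "multivariate_outcomes": self.multivariate_outcomes,
            "dm_subset": self.dm_subset,
            "cohort": {"n_females": self.cohort.n_females,
                       "years": list(self.cohort.years),
                       "seed": self.cohort.seed},
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "reticulocyte_options" in doc:
            doc["reticulocyte_options"] = tuple(doc["reticulocyte_options"])
        cohort_doc = doc.pop("cohort", {})
        cohort = default_config(**{k: (tuple(v) if k == "years" else v)
                                   for k, v in cohort_doc.items()})
        return cls(cohort=cohort, **doc)


@dataclass
class PipelineReport:
    cohort: pd.DataFrame
    univariate_data: pd.DataFrame          # chick-rearing rows, outliers removed
    delta_data: pd.DataFrame
    outcomes: pd.DataFrame                 # one row per female-year
    panel: prep.StandardizedPanel
    dm_scores: dict                        # label -> DMScore
    pca_results: dict                      # kind -> PCAResult
    window_scores: dict                    # window -> per-row/female-year table
    results: dict                          # grid name -> list[ModelResult]
    summaries: dict                        # grid name -> GridSummary
    manifest: dict


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _validate_names(config: RunConfig, columns) -> None:
    unresolved = []
    cols = set(columns) | {"nab_pc1", "nab_pc2", "ox_pc1", "ox_pc2",
                           "visit_rate", "reproduction_pc1"}
    for name in config.transform_map:
        if name not in cols:
            unresolved.append(f"transform_map: {name}")
    for name in config.dm_subset:
        if name not in cols:
            unresolved.append(f"dm_subset: {name}")
    for grp, members in config.group_members.items():
        unresolved += [f"group {grp}: {m}" for m in members if m not in cols]
    for name in config.univariate_outcomes + config.multivariate_outcomes:
        if name not in cols:
            unresolved.append(f"outcome: {name}")
    if unresolved:
        raise ValueError("unresolved column names: " + "; ".join(unresolved))


def _outcomes_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-(female, year) outcomes incl. partitioned visit rate and the
    reproduction composite."""
    outcome_cols = [c for c in OUTCOME_COLUMNS if c in df.columns]
    base = (df.groupby(["female_id", "year"], sort=True)
              .first()
              .reset_index())
    f_tot, _ = prep.partition_unknown_visits(
        base["female_visits_known"], base["male_visits_known"],
        base["visits_unknown"])
    base["visit_rate"] = f_tot / base["observation_hours"]
    table = base[["female_id", "year", "visit_rate"] + outcome_cols]
    try:
        repro = pcamod.reproduction_pca(table)
        table = table.copy()
        table.loc[repro.scores.index, "reproduction_pc1"] = repro.scores.iloc[:, 0]
    except ValueError as err:
        log.warning("reproduction PCA skipped: %s", err)
        table = table.assign(reproduction_pc1=np.nan)
    return table


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run every stage; deterministic given (config, config.seed)."""
    sim_seed, dm_seed = _child_seeds(config.seed, 2)
    manifest: dict = {"seed": config.seed,
                      "stage_seeds": {"simulate": sim_seed, "dm_v5": dm_seed}}

    # --- input -------------------------------------------------------------
    if config.source == "simulate":
        cohort = generate_cohort(config.cohort, seed=sim_seed)
    else:
        cohort = read_cohort(config.source)
    _validate_names(config, cohort.columns)
    manifest["n_observations"] = int(len(cohort))
    manifest["n_females"] = int(cohort["female_id"].nunique())

    # --- preprocess ---------------------------------------------------------
    data, applied = prep.normalize_variables(cohort, config.transform_map)
    manifest["transforms"] = applied

    nab = prep.immune_composite(data["agglutination"], data["lysis"])
    ox = prep.oxidative_composite(data["oxy"], data["droms"])
    data = pd.concat([data, nab.scores, ox.scores], axis=1)

    cr_rows = data["stage"] == CHICK_REARING
    data.loc[cr_rows, "wing_loading"] = prep.wing_loading(
        data.loc[cr_rows, "body_mass"], data.loc[cr_rows, "wing_area"],
        data.loc[cr_rows, "year"])

    outcomes = _outcomes_table(data)

    # univariate path: cort outliers excluded (raw scale threshold)
    cort_raw = cohort["corticosterone"]
    excluded = sorted(pd.unique(
        cohort.loc[cort_raw > config.cort_threshold, "female_id"]))
    uni_all = data.loc[~data["female_id"].isin(excluded)].reset_index(drop=True)
    manifest["cort_excluded_females"] = excluded

    cr_brood1 = uni_all.loc[(uni_all["stage"] == CHICK_REARING)
                            & (uni_all["brood"] == 1)]
    uni_abs = (cr_brood1.drop(columns=[c for c in outcomes.columns
                                       if c not in ("female_id", "year")],
                              errors="ignore")
               .merge(outcomes, on=["female_id", "year"], how="left"))

    delta_vars = assoc.UNIVARIATE_PREDICTORS + ["body_mass"]
    delta_panel = prep.compute_delta(uni_all, delta_vars)
    delta_data = delta_panel.values.merge(outcomes, on=["female_id", "year"],
                                          how="left")
    manifest["delta_omitted"] = [list(t) for t in delta_panel.omitted]

    # multivariate path: outliers kept unless the sensitivity flag is set
    multi = data
    if config.drop_cort_outliers_multivariate:
        multi = data.loc[~data["female_id"].isin(excluded)].reset_index(drop=True)
    panel = prep.standardize_by_cell(multi, PANEL_VARIABLES)

    # --- dysregulation scores ----------------------------------------------
    dm_scores: dict = {}
    specs = list(config.centroid_specs) + [dysreg.CentroidSpec("v5", {})]
    for spec in specs:
        for retics in config.reticulocyte_options:
            cfg = dysreg.DMConfig(spec=spec, include_reticulocytes=retics,
                                  covariance_policy=config.covariance_policy,
                                  subset=config.dm_subset)
            score = dysreg.score_dm(panel, cfg, seed=dm_seed)
            dm_scores[f"dm_{score.config.label}"] = score
    manifest["dm"] = {
        label: {"n_scored": int(len(s.scores)),
                "n_dropped": len(s.dropped),
                "condition_number": s.condition_number,
                "shrinkage_weight": s.shrinkage_weight,
                "centroid": {k: v for k, v in s.config.spec.choice.items()}}
        for label, s in dm_scores.items()
    }

    # --- PCA summaries -------------------------------------------------------
    pca_results = {
        "directional": pcamod.directional_pca(panel),
        "deviational": pcamod.deviational_pca(panel),
    }
    for grp, members in config.group_members.items():
        pca_results[f"group_{grp}"] = pcamod.group_pca(panel, grp, members)
    manifest["pca_variance_fractions"] = {
        k: [float(v) for v in r.variance_fraction] for k, r in pca_results.items()
    }

    # --- window score tables --------------------------------------------------
    score_table = panel.meta.copy()
    for label, s in dm_scores.items():
        score_table[label] = s.scores
    for r in pca_results.values():
        for col in r.scores.columns:
            score_table[col] = r.scores[col]
    score_cols = [c for c in score_table.columns
                  if c not in ("female_id", "year", "stage", "brood")]
    window_scores = {
        INCUBATION: score_table.loc[score_table["stage"] == INCUBATION,
                                    ["female_id", "year"] + score_cols],
        CHICK_REARING: score_table.loc[score_table["stage"] == CHICK_REARING,
                                       ["female_id", "year"] + score_cols],
        "annual_mean": (score_table.groupby(["female_id", "year"])[score_cols]
                        .mean().reset_index()),
    }

    # --- association grids -----------------------------------------------------
    abs_res, abs_sum, delta_res, delta_sum = assoc.run_univariate_grid(
        uni_abs, delta_data, outcomes=config.univariate_outcomes,
        alpha=config.alpha)
    dm_labels = list(dm_scores)
    pca_labels = [c for c in score_cols if not c.startswith("dm_")]
    dm_res, dm_sum, pca_res, pca_sum, surv_res = assoc.run_multivariate_grid(
        window_scores, outcomes, dm_labels, pca_labels,
        outcomes=config.multivariate_outcomes, alpha=config.alpha)

    results = {"univariate_absolute": abs_res, "univariate_delta": delta_res,
               "dm": dm_res, "pca": pca_res, "survival": surv_res}
    summaries = {"univariate_absolute": abs_sum, "univariate_delta": delta_sum,
                 "dm": dm_sum, "pca": pca_sum}
    manifest["grid_sizes"] = {k: s.total_tests for k, s in summaries.items()}
    manifest["significant"] = {
        k: {"n": s.n_significant, "proportion": s.proportion}
        for k, s in summaries.items()}
    manifest["alpha"] = config.alpha

    report = PipelineReport(cohort, uni_abs, delta_data, outcomes, panel,
                            dm_scores, pca_results, window_scores, results,
                            summaries, manifest)
    if config.outdir:
        _write_report(report, config)
    return report


def _write_report(report: PipelineReport, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.cohort.to_csv(out / "cohort.csv", index=False, na_rep="")
    report.outcomes.to_csv(out / "outcomes.csv", index=False, na_rep="")
    dm_long = []
    for label, s in report.dm_scores.items():
        block = s.meta.copy()
        block["version"] = label
        block["dm"] = s.scores
        dm_long.append(block)
    pd.concat(dm_long).to_csv(out / "dm_scores.csv", index=False, na_rep="")
    for name, res in report.results.items():
        assoc.results_frame(res).to_csv(out / f"results_{name}.csv",
                                        index=False, na_rep="")
    for name, res in report.results.items():
        if name == "survival":
            continue
        assoc.effect_matrix(res, config.alpha).to_csv(
            out / f"effects_{name}.csv", na_rep="")
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2,
                                                  default=str))
    config.to_yaml(out / "config.yaml")


# ---------------------------------------------------------------------------
# bundled toy fixtures


def make_fixtures(seed: int = 0) -> dict:
    """Small named datasets used in examples and tests; byte-stable per seed."""
    rng = np.random.default_rng(seed)

    # 2x2 contingency layout (a, b, c, d) = (20, 10, 10, 20): odds ratio 4
    logistic_2x2 = pd.DataFrame({
        "exposed": [1] * 30 + [0] * 30,
        "event": [1] * 20 + [0] * 10 + [1] * 10 + [0] * 20,
    })

    mahalanobis_2d = {
        "x": np.array([1.0, 1.0]),
        "centroid": np.array([0.0, 0.0]),
        "covariance": np.array([[1.0, 0.5], [0.5, 1.0]]),
        "expected": float(np.sqrt(2.0 / 1.5)),
    }

    bh_vector = {"p": [0.01, 0.02, 0.03, 0.04],
                 "adjusted": [0.04, 0.04, 0.04, 0.04]}

    # cohort with exactly 7 females pushed above the corticosterone threshold
    cohort_cfg = default_config(n_females=40, seed=seed)
    cohort = generate_cohort(cohort_cfg, seed=seed)
    planted = rng.choice(cohort["female_id"].unique(), size=7, replace=False)
    for f in planted:
        idx = cohort.index[cohort["female_id"] == f][0]
        cohort.loc[idx, "corticosterone"] = 80.1 + float(rng.random()) * 40.0
    cort_outliers = cohort

    # additive two-cell fixture: year effect +2, stage effect +1, no noise
    grid = [(y, s) for y in (2013, 2014) for s in (INCUBATION, CHICK_REARING)]
    additive = pd.DataFrame([
        {"female_id": f"A{i}{j}", "year": y, "stage": s, "brood": 1,
         "value": 10.0 + 2.0 * (y == 2014) + 1.0 * (s == CHICK_REARING)}
        for i, (y, s) in enumerate(grid) for j in range(3)
    ])

    rho = 0.5
    C = np.full((3, 3), rho) + np.diag(np.full(3, 1 - rho))
    triple = rng.multivariate_normal(np.zeros(3), C, size=400)
    equicorrelated_triple = pd.DataFrame(triple, columns=["x1", "x2", "x3"])

    paired = pd.DataFrame({
        "female_id": ["P1", "P1", "P2", "P2", "P3"],
        "year": [2013] * 5,
        "brood": [1] * 5,
        "stage": [INCUBATION, CHICK_REARING] * 2 + [INCUBATION],
        "value": [5.0, 5.0, 10.0, 7.0, 3.0],
    })

    return {
        "logistic_2x2": logistic_2x2,
        "mahalanobis_2d": mahalanobis_2d,
        "bh_vector": bh_vector,
        "cort_outliers": cort_outliers,
        "additive_cells": additive,
        "equicorrelated_triple": equicorrelated_triple,
        "paired_stages": paired,
    }
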