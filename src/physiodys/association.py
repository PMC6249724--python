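"""Association grids linking physiology to workload and fitness outcomes.

The analysis design crosses many predictors with many outcomes and inspects
the *pattern* of results rather than any single test: univariate grids
(13 absolute chick-rearing biomarkers x 12 outcomes = 156 contrasts;
14 stage-change deltas x 12 outcomes = 168), a dysregulation-score grid
(6 centroid versions x 2 reticulocyte subsets x 3 observation windows x 11
outcomes = 396) and a PCA-summary grid (9 axes x 3 windows x 11 outcomes
= 297).  Model family follows the outcome: Gaussian linear mixed model with an
individual random intercept for continuous outcomes, Poisson regression with
cluster-robust errors for brood counts, logistic regression for binary
outcomes.  Multiple testing across grids is deliberately not adjusted;
FDR (Benjamini-Hochberg) applies only to the pairwise correlation screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CHICK_REARING, INCUBATION
from .lmm import fit_glm, fit_random_intercept_lmm, reml_criterion_at_lambda

__all__ = [
    "ModelResult",
    "RepeatabilityResult",
    "GridSummary",
    "OUTCOME_FAMILY",
    "UNIVARIATE_PREDICTORS",
    "UNIVARIATE_OUTCOMES",
    "MULTIVARIATE_OUTCOMES",
    "WINDOWS",
    "fit_gaussian_lmm",
    "fit_poisson_glmm",
    "fit_logistic",
    "repeatability",
    "fdr_adjust",
    "correlation_screen",
    "stage_year_contrasts",
    "univariate_grid_plan",
    "multivariate_grid_plan",
    "run_univariate_grid",
    "run_multivariate_grid",
    "summarize_grid",
    "effect_matrix",
    "results_frame",
]

WINDOWS = (INCUBATION, CHICK_REARING, "annual_mean")

#: the 13 univariate physiological predictors (single markers + NAb PC1)
UNIVARIATE_PREDICTORS = [
    "hematocrit", "hemoglobin", "reticulocytes", "corticosterone",
    "creatine_kinase", "oxy", "droms", "nefa", "triglycerides", "glucose",
    "uric_acid", "haptoglobin", "nab_pc1",
]

#: 12 univariate outcomes: workload, current productivity, future fecundity,
#: survival, cumulative productivity (the year-1 fledgling-mass total is the
#: configurable 12th member)
UNIVARIATE_OUTCOMES = [
    "visit_rate", "brood_size_d6", "bsf1", "mean_fledging_mass_b1",
    "total_fledged_year", "second_brood", "bsf2", "mean_fledging_mass_b2",
    "bsf1_year2", "returned_year2", "fledglings_2yr",
    "total_fledgling_mass_year",
]

#: 11 outcomes tested against the multivariate physiology summaries
MULTIVARIATE_OUTCOMES = [
    "brood_size_d6", "bsf1", "mean_fledging_mass_b1", "visit_rate",
    "total_fledged_year", "total_fledgling_mass_year", "reproduction_pc1",
    "second_brood", "bsf2", "bsf1_year2", "lay_date_year2",
]

OUTCOME_FAMILY = {
    "visit_rate": "gaussian_lmm",
    "brood_size_d6": "poisson_glmm",
    "bsf1": "poisson_glmm",
    "mean_fledging_mass_b1": "gaussian_lmm",
    "total_fledged_year": "poisson_glmm",
    "second_brood": "logistic",
    "bsf2": "poisson_glmm",
    "mean_fledging_mass_b2": "gaussian_lmm",
    "bsf1_year2": "poisson_glmm",
    "returned_year2": "logistic",
    "fledglings_2yr": "poisson_glmm",
    "total_fledgling_mass_year": "gaussian_lmm",
    "lay_date_year2": "gaussian_lmm",
    "reproduction_pc1": "gaussian_lmm",
}


@dataclass
class ModelResult:
    predictor: str
    outcome: str
    window: str
    family: str
    estimate: float = np.nan
    se: float = np.nan
    statistic: float = np.nan      # F for the LMM, z otherwise
    df: float = np.nan
    p: float = np.nan
    n: int = 0
    odds_ratio: float | None = None
    or_low: float | None = None
    or_high: float | None = None
    degenerate: bool = False
    note: str = ""

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(np.isfinite(self.p) and self.p < alpha)


@dataclass
class RepeatabilityResult:
    variable: str
    grouping: str
    r: float                        # pooled intraclass correlation
    p: float                        # boundary LRT (equal-mixture null)
    n_groups: int
    n_obs: int
    per_year: dict = field(default_factory=dict)   # year -> (r, p)


@dataclass
class GridSummary:
    total_tests: int
    n_significant: int
    alpha: float
    per_window: dict = field(default_factory=dict)
    per_family: dict = field(default_factory=dict)

    @property
    def proportion(self) -> float:
        return self.n_significant / self.total_tests


def _design(data: pd.DataFrame, outcome: str, predictor: str, covariates,
            group: str | None):
    """Complete-case design matrix with categorical covariates dummy-coded."""
    cols = [outcome, predictor, *covariates] + ([group] if group else [])
    sub = data.dropna(subset=[c for c in cols if c is not None]).copy()
    if len(sub) < len(covariates) + 3:
        raise ValueError(
            f"too few complete observations ({len(sub)}) for "
            f"{predictor} -> {outcome}"
        )
    if sub[predictor].nunique() <= 1:
        raise ValueError(f"predictor column {predictor!r} is constant")
    parts = [np.ones(len(sub)), sub[predictor].to_numpy(dtype=float)]
    for cov in covariates:
        col = sub[cov]
        if col.dtype == object or str(col.dtype) == "category" or cov in ("year", "stage"):
            dummies = pd.get_dummies(col, drop_first=True)
            for c in dummies.columns:
                d = dummies[c].to_numpy(dtype=float)
                if d.std() > 0:
                    parts.append(d)
        else:
            v = col.to_numpy(dtype=float)
            if np.std(v) > 0:
                parts.append(v)
    X = np.column_stack(parts)
    y = sub[outcome].to_numpy(dtype=float)
    g = sub[group].to_numpy() if group else None
    return y, X, g, len(sub)


def fit_gaussian_lmm(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=(),
    group: str = "female_id",
    window: str = "",
) -> ModelResult:
    """Gaussian LMM (REML) with an individual random intercept.

    Reports the predictor's slope, its SE, an F statistic (squared t) with
    Satterthwaite-style denominator df, and the two-sided p-value.  When every
    individual contributes a single row the random term is dropped with a
    note (the variance component is not estimable).
    """
    y, X, g, n = _design(data, outcome, predictor, covariates, group)
    fit = fit_random_intercept_lmm(y, X, g)
    return ModelResult(
        predictor=predictor, outcome=outcome, window=window,
        family="gaussian_lmm",
        estimate=float(fit.beta[1]), se=float(fit.se[1]),
        statistic=float(fit.tvalues[1] ** 2), df=float(fit.df[1]),
        p=float(fit.pvalues[1]), n=n,
        degenerate=fit.degenerate, note=fit.note,
    )


def fit_poisson_glmm(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=(),
    group: str = "female_id",
    window: str = "",
) -> ModelResult:
    """Poisson (log link) count regression, z statistic and p reported.

    Quasi-Poisson covariance: the Fisher covariance scaled by the Pearson
    dispersion (floored at 1) with a t(n - p) reference, which absorbs the
    mild overdispersion of derived brood totals while staying near nominal
    size at the study's sample sizes.
    """
    sub = data.dropna(subset=[outcome])
    vals = sub[outcome].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError(f"count outcome {outcome!r} has negative entries")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError(f"count outcome {outcome!r} has non-integer entries")
    if np.all(vals == 0):
        raise ValueError(f"count outcome {outcome!r} is all zero")
    y, X, g, n = _design(data, outcome, predictor, covariates, group)
    fit = fit_glm(y, X, "poisson", quasi=True)
    return ModelResult(
        predictor=predictor, outcome=outcome, window=window,
        family="poisson_glmm",
        estimate=float(fit.beta[1]), se=float(fit.se[1]),
        statistic=float(fit.zvalues[1]), df=fit.df_resid or np.nan,
        p=float(fit.pvalues[1]), n=n,
        degenerate=not fit.converged, note="" if fit.converged else "no convergence",
    )


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=(),
    window: str = "",
) -> ModelResult:
    """Logistic regression reporting the odds ratio with a 95% Wald CI.

    Complete separation is flagged rather than raised: the estimate diverges,
    so the CI is reported as unbounded.
    """
    sub = data.dropna(subset=[outcome])
    classes = set(pd.unique(sub[outcome].dropna()))
    if not classes <= {0, 1, 0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary 0/1")
    if len(classes) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class")
    y, X, g, n = _design(data, outcome, predictor, covariates, None)
    fit = fit_glm(y, X, "binomial")
    b, se = float(fit.beta[1]), float(fit.se[1])
    if fit.separated:
        return ModelResult(
            predictor=predictor, outcome=outcome, window=window,
            family="logistic", estimate=b, se=se,
            statistic=float(fit.zvalues[1]), p=np.nan, n=n,
            odds_ratio=float(np.exp(np.clip(b, -700, 700))),
            or_low=0.0, or_high=np.inf,
            degenerate=True, note="complete separation",
        )
    return ModelResult(
        predictor=predictor, outcome=outcome, window=window,
        family="logistic", estimate=b, se=se,
        statistic=float(fit.zvalues[1]), p=float(fit.pvalues[1]), n=n,
        odds_ratio=float(np.exp(b)),
        or_low=float(np.exp(b - 1.959963984540054 * se)),
        or_high=float(np.exp(b + 1.959963984540054 * se)),
    )


def repeatability(
    data: pd.DataFrame,
    variable: str,
    grouping: str = "female_id",
    year_column: str | None = None,
) -> RepeatabilityResult:
    """Intraclass correlation from a random-intercept model.

    r = sigma2_between / (sigma2_between + sigma2_within); the p-value is a
    boundary likelihood-ratio test of the random-intercept variance against
    the equal-mixture chi2(0)/chi2(1) null.  With ``year_column`` set, per-year
    estimates are computed alongside the pooled one (pooling across years can
    manufacture apparent repeatability when year means differ).
    """

    def _fit(sub: pd.DataFrame) -> tuple[float, float, int, int]:
        sub = sub.dropna(subset=[variable])
        sizes = sub.groupby(grouping).size()
        if (sizes >= 2).sum() < 5:
            raise ValueError(
                f"{variable}: need >= 2 observations for >= 5 groups, "
                f"got {(sizes >= 2).sum()}"
            )
        y = sub[variable].to_numpy(dtype=float)
        X = np.ones((len(y), 1))
        g = sub[grouping].to_numpy()
        fit = fit_random_intercept_lmm(y, X, g)
        lr = max(reml_criterion_at_lambda(y, X, g, 0.0) - fit.reml_criterion, 0.0)
        p = 0.5 * stats.chi2.sf(lr, 1) if lr > 0 else 0.5
        return fit.icc, float(p), len(sizes), len(sub)

    r, p, n_groups, n_obs = _fit(data)
    per_year = {}
    if year_column is not None:
        for year, sub in data.groupby(year_column):
            try:
                ry, py, *_ = _fit(sub)
                per_year[year] = (ry, py)
            except ValueError:
                per_year[year] = (np.nan, np.nan)
    return RepeatabilityResult(variable, grouping, r, p, n_groups, n_obs,
                               per_year)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_screen(
    data: pd.DataFrame, variables, min_pairs: int = 4
) -> pd.DataFrame:
    """Pairwise Pearson correlations with raw and FDR-adjusted p columns.

    All unordered pairs are reported (13 variables -> 78 rows); correlations
    use pairwise-complete observations.
    """
    variables = list(variables)
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            pair = data[[a, b]].dropna()
            if len(pair) < min_pairs:
                rows.append((a, b, len(pair), np.nan, np.nan))
                continue
            x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((a, b, len(pair), np.nan, np.nan))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((a, b, len(pair), float(r), float(p)))
    out = pd.DataFrame(rows, columns=["var_a", "var_b", "n", "r", "p"])
    adj = np.full(len(out), np.nan)
    ok = out["p"].notna().to_numpy()
    if ok.any():
        adj[ok] = fdr_adjust(out.loc[ok, "p"].to_numpy())
    out["p_fdr"] = adj
    return out


def stage_year_contrasts(
    data: pd.DataFrame,
    variables,
    year_column: str = "year",
    stage_column: str = "stage",
    group: str = "female_id",
) -> pd.DataFrame:
    """Stage/year structure per biomarker: interaction test, stage effect,
    per-year stage means and percent change 100 * (CR - inc) / inc.

    Degenerate fixtures (e.g. zero within-cell variance) yield NaN test
    columns but exact means and percent changes.
    """
    stages = data[stage_column].unique()
    if len(stages) < 2:
        raise ValueError("both breeding stages required")
    rows = []
    for var in variables:
        sub = data.dropna(subset=[var]).copy()
        sub["_stage_cr"] = (sub[stage_column] == CHICK_REARING).astype(float)

        inter_p = np.nan
        stage_p = np.nan
        stage_est = np.nan
        try:
            years = pd.get_dummies(sub[year_column], drop_first=True).astype(float)
            if years.shape[1] >= 1:
                yv = years.iloc[:, 0].to_numpy()
                X = np.column_stack([
                    np.ones(len(sub)), sub["_stage_cr"].to_numpy() * yv,
                    sub["_stage_cr"].to_numpy(), yv,
                ])
                fit = fit_random_intercept_lmm(sub[var].to_numpy(float), X,
                                               sub[group].to_numpy())
                inter_p = float(fit.pvalues[1])
        except (ValueError, np.linalg.LinAlgError):
            pass
        try:
            res = fit_gaussian_lmm(
                sub.rename(columns={"_stage_cr": "stage_cr"}),
                var, "stage_cr",
                covariates=(year_column,) if sub[year_column].nunique() > 1 else (),
                group=group,
            )
            stage_p, stage_est = res.p, res.estimate
        except (ValueError, np.linalg.LinAlgError):
            pass

        means = sub.groupby([year_column, stage_column])[var].mean()
        for year in sorted(sub[year_column].unique()):
            try:
                inc = float(means[(year, INCUBATION)])
                cr = float(means[(year, CHICK_REARING)])
            except KeyError:
                continue
            pct = round(100.0 * (cr - inc) / inc, 1) if inc != 0 else np.nan
            rows.append({
                "variable": var, "year": year,
                "incubation_mean": inc, "chick_rearing_mean": cr,
                "percent_change": pct,
                "interaction_p": inter_p,
                "stage_p": stage_p, "stage_estimate": stage_est,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grids


def univariate_grid_plan(predictors=None, outcomes=None, delta: bool = False):
    """Enumerate (predictor, outcome, family) cells of a univariate grid."""
    if predictors is None:
        base = UNIVARIATE_PREDICTORS + (["body_mass"] if delta else [])
        predictors = [f"delta_{p}" for p in base] if delta else list(base)
    outcomes = UNIVARIATE_OUTCOMES if outcomes is None else list(outcomes)
    return [(p, o, OUTCOME_FAMILY[o]) for p in predictors for o in outcomes]


def multivariate_grid_plan(dm_labels=None, pca_labels=None, windows=WINDOWS,
                           outcomes=None):
    """Enumerate DM-grid and PCA-grid cells: (predictor, window, outcome, family)."""
    if dm_labels is None:
        dm_labels = [f"dm_{v}_{s}" for v in ("v0", "v1", "v2", "v3", "v4", "v5")
                     for s in ("with_retics", "no_retics")]
    if pca_labels is None:
        pca_labels = ([f"dir_pc{k}" for k in (1, 2, 3)]
                      + [f"dev_pc{k}" for k in (1, 2, 3)]
                      + [f"{g}_pc1" for g in
                         ("aerobic_capacity", "metabolism_energy", "oxidative_stress")])
    outcomes = MULTIVARIATE_OUTCOMES if outcomes is None else list(outcomes)
    dm = [(p, w, o, OUTCOME_FAMILY[o])
          for p in dm_labels for w in windows for o in outcomes]
    pca = [(p, w, o, OUTCOME_FAMILY[o])
           for p in pca_labels for w in windows for o in outcomes]
    return dm, pca


def _fit_cell(data, predictor, outcome, family, covariates, window="",
              group="female_id") -> ModelResult:
    try:
        if family == "gaussian_lmm":
            return fit_gaussian_lmm(data, outcome, predictor, covariates,
                                    group=group, window=window)
        if family == "poisson_glmm":
            return fit_poisson_glmm(data, outcome, predictor, covariates,
                                    group=group, window=window)
        return fit_logistic(data, outcome, predictor, window=window)
    except (ValueError, np.linalg.LinAlgError) as err:
        return ModelResult(predictor=predictor, outcome=outcome, window=window,
                           family=family, degenerate=True,
                           note=f"fit failed: {err}")


def run_univariate_grid(
    absolute: pd.DataFrame,
    delta: pd.DataFrame,
    outcomes=None,
    alpha: float = 0.05,
    group: str = "female_id",
    mass_covariate: str = "body_mass",
) -> tuple[list, GridSummary, list, GridSummary]:
    """Fit the absolute (13 x 12) and delta (14 x 12) univariate grids.

    ``absolute`` holds one chick-rearing row per female-year with biomarker
    and outcome columns; ``delta`` holds the stage-change predictors.  Body
    mass enters Gaussian absolute fits as a covariate (stage-specific
    analyses); failures are flagged and counted, never silently dropped.
    """
    outcomes = UNIVARIATE_OUTCOMES if outcomes is None else list(outcomes)
    if not outcomes:
        raise ValueError("empty outcome set")

    abs_plan = univariate_grid_plan(outcomes=outcomes)
    delta_plan = univariate_grid_plan(outcomes=outcomes, delta=True)

    def covs(table, family, predictor):
        base = ["year"] if table["year"].nunique() > 1 else []
        if (family == "gaussian_lmm" and table is absolute
                and mass_covariate in table.columns
                and predictor != mass_covariate):
            base.append(mass_covariate)
        return tuple(base) if family != "logistic" else ()

    abs_results = [
        _fit_cell(absolute, p, o, fam, covs(absolute, fam, p),
                  window=CHICK_REARING, group=group)
        for p, o, fam in abs_plan
    ]
    delta_results = [
        _fit_cell(delta, p, o, fam, covs(delta, fam, p),
                  window="delta", group=group)
        for p, o, fam in delta_plan
    ]
    return (abs_results, summarize_grid(abs_results, alpha)[0],
            delta_results, summarize_grid(delta_results, alpha)[0])


def run_multivariate_grid(
    window_scores: dict,
    outcomes_table: pd.DataFrame,
    dm_labels,
    pca_labels,
    outcomes=None,
    alpha: float = 0.05,
    group: str = "female_id",
    survival_outcome: str = "returned_year2",
    survival_window: str = CHICK_REARING,
    survival_labels=None,
):
    """Fit the DM and PCA association grids plus the survival logistic block.

    ``window_scores`` maps each window (incubation / chick_rearing /
    annual_mean) to a per-(female, year) table of score columns; outcome
    columns are joined from ``outcomes_table`` on (female_id, year).
    Returns (dm_results, dm_summary, pca_results, pca_summary,
    survival_results).
    """
    outcomes = MULTIVARIATE_OUTCOMES if outcomes is None else list(outcomes)
    dm_plan, pca_plan = multivariate_grid_plan(dm_labels, pca_labels,
                                               outcomes=outcomes)
    merged = {
        w: tbl.merge(outcomes_table, on=["female_id", "year"], how="left")
        for w, tbl in window_scores.items()
    }

    def run(plan):
        results = []
        for predictor, window, outcome, family in plan:
            data = merged[window]
            if predictor not in data.columns:
                results.append(ModelResult(predictor, outcome, window, family,
                                           degenerate=True,
                                           note="score column absent"))
                continue
            results.append(_fit_cell(data, predictor, outcome, family, (),
                                     window=window, group=group))
        return results

    dm_results = run(dm_plan)
    pca_results = run(pca_plan)

    if survival_labels is None:
        survival_labels = [lbl for lbl in dm_labels
                           if lbl.endswith("no_retics")] or list(dm_labels)
    survival_results = [
        _fit_cell(merged[survival_window], lbl, survival_outcome, "logistic",
                  (), window=survival_window, group=group)
        for lbl in survival_labels
    ]
    return (dm_results, summarize_grid(dm_results, alpha)[0],
            pca_results, summarize_grid(pca_results, alpha)[0],
            survival_results)


def summarize_grid(results, alpha: float = 0.05) -> tuple[GridSummary, pd.DataFrame]:
    """Counts/proportions of significant tests plus the effect-matrix export."""
    if not results:
        raise ValueError("no results to summarize")
    n_sig = sum(r.significant(alpha) for r in results)
    per_window: dict = {}
    per_family: dict = {}
    for r in results:
        for key, store in ((r.window, per_window), (r.family, per_family)):
            tot, sig = store.get(key, (0, 0))
            store[key] = (tot + 1, sig + int(r.significant(alpha)))
    summary = GridSummary(len(results), n_sig, alpha,
                          per_window=per_window, per_family=per_family)
    return summary, effect_matrix(results, alpha)


def effect_matrix(results, alpha: float = 0.05) -> pd.DataFrame:
    """Signed-effect matrix (rows = predictor/window, cols = outcomes).

    Cell value is the signed estimate; the companion ``*_sig`` flag marks
    cells significant at ``alpha`` -- the table behind the heat-map figures.
    """
    rows = {}
    for r in results:
        key = f"{r.predictor}@{r.window}" if r.window else r.predictor
        rows.setdefault(key, {})[r.outcome] = r.estimate
        rows.setdefault(key, {})[f"{r.outcome}_sig"] = int(r.significant(alpha))
    return pd.DataFrame(rows).T.sort_index()


def results_frame(results) -> pd.DataFrame:
    """One row per ModelResult, ready for CSV export."""
    return pd.DataFrame([{
        "predictor": r.predictor, "outcome": r.outcome, "window": r.window,
        "family": r.family, "estimate": r.estimate, "se": r.se,
        "statistic": r.statistic, "df": r.df, "p": r.p, "n": r.n,
        "odds_ratio": r.odds_ratio, "or_low": r.or_low, "or_high": r.or_high,
        "degenerate": r.degenerate, "note": r.note,
    } for r in results])
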