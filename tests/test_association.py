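"""Model fitters (cross-checked against statsmodels), repeatability,
FDR adjustment, correlation screen, stage/year contrasts and grid accounting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from physiodys.association import (OUTCOME_FAMILY, UNIVARIATE_OUTCOMES,
                                   correlation_screen, fdr_adjust,
                                   fit_gaussian_lmm, fit_logistic,
                                   fit_poisson_glmm, multivariate_grid_plan,
                                   repeatability, stage_year_contrasts,
                                   summarize_grid, univariate_grid_plan)
from physiodys.cohort import CHICK_REARING, INCUBATION
from physiodys.lmm import fit_glm, fit_random_intercept_lmm


def _clustered_gaussian(rng, n_groups=40, reps=2, beta=0.7, sd_b=1.0, sd_e=1.0):
    g = np.repeat(np.arange(n_groups), reps)
    x = rng.standard_normal(g.size)
    b = rng.normal(0, sd_b, n_groups)
    y = 1.0 + beta * x + b[g] + rng.normal(0, sd_e, g.size)
    return pd.DataFrame({"female_id": g, "y": y, "x": x})


class TestGaussianLMM:
    def test_matches_statsmodels_mixedlm(self, rng):
        df = _clustered_gaussian(rng)
        ours = fit_random_intercept_lmm(
            df["y"].to_numpy(),
            np.column_stack([np.ones(len(df)), df["x"].to_numpy()]),
            df["female_id"].to_numpy(),
        )
        ref = sm.MixedLM.from_formula("y ~ x", groups="female_id",
                                      data=df).fit(reml=True)
        assert ours.beta[1] == pytest.approx(ref.params["x"], rel=1e-4)
        assert ours.se[1] == pytest.approx(ref.bse["x"], rel=1e-3)
        assert ours.sigma2_e == pytest.approx(ref.scale, rel=1e-3)
        assert ours.sigma2_b == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-2, abs=1e-3)

    def test_result_shape_and_f_statistic(self, rng):
        df = _clustered_gaussian(rng)
        res = fit_gaussian_lmm(df, "y", "x")
        assert res.family == "gaussian_lmm"
        assert res.statistic == pytest.approx((res.estimate / res.se) ** 2)
        assert 0 <= res.p <= 1 and res.n == len(df)

    def test_singleton_groups_drop_random_term_with_note(self, rng):
        df = _clustered_gaussian(rng, n_groups=30, reps=1)
        res = fit_gaussian_lmm(df, "y", "x")
        assert "singleton" in res.note

    def test_constant_predictor_named(self, rng):
        df = _clustered_gaussian(rng)
        df["x"] = 1.0
        with pytest.raises(ValueError, match="'x'"):
            fit_gaussian_lmm(df, "y", "x")


class TestGLMs:
    def test_poisson_matches_statsmodels(self, rng):
        n = 120
        x = rng.standard_normal(n)
        y = rng.poisson(np.exp(1.2 + 0.4 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        ours = fit_glm(y, X, "poisson")
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.allclose(ours.beta, ref.params, rtol=1e-6)
        assert np.allclose(ours.se, ref.bse, rtol=1e-5)

    def test_quasipoisson_dispersion_matches_pearson_chi2(self, rng):
        n = 150
        x = rng.standard_normal(n)
        y = (rng.poisson(np.exp(1.0 + 0.2 * x)) * rng.integers(1, 3, n)).astype(float)
        X = np.column_stack([np.ones(n), x])
        ours = fit_glm(y, X, "poisson", quasi=True)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert ours.dispersion == pytest.approx(
            float(ref.pearson_chi2) / ref.df_resid, rel=1e-6)

    def test_logistic_matches_statsmodels(self, rng):
        n = 200
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        y = (rng.random(n) < p).astype(float)
        X = np.column_stack([np.ones(n), x])
        ours = fit_glm(y, X, "binomial")
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(ours.beta, ref.params, rtol=1e-6)
        assert np.allclose(ours.se, ref.bse, rtol=1e-5)

    def test_contingency_table_odds_ratio(self, fixtures):
        df = fixtures["logistic_2x2"]
        res = fit_logistic(df, "event", "exposed")
        assert res.odds_ratio == pytest.approx(4.0, rel=1e-6)
        assert res.or_low < 4.0 < res.or_high

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"y": [1.0] * 10, "x": np.arange(10.0),
                           "female_id": range(10)})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(df, "y", "x")

    def test_complete_separation_flagged_unbounded_ci(self):
        df = pd.DataFrame({"y": [0.0] * 10 + [1.0] * 10,
                           "x": np.r_[np.arange(10.0), 20 + np.arange(10.0)],
                           "female_id": range(20)})
        res = fit_logistic(df, "y", "x")
        assert res.degenerate and res.or_high == np.inf and res.or_low == 0.0

    def test_poisson_preconditions(self, rng):
        df = pd.DataFrame({"y": [-1.0, 2.0, 3.0, 1.0, 2.0, 0.0],
                           "x": rng.standard_normal(6),
                           "female_id": range(6)})
        with pytest.raises(ValueError, match="negative"):
            fit_poisson_glmm(df, "y", "x")
        df["y"] = 0.0
        with pytest.raises(ValueError, match="all zero"):
            fit_poisson_glmm(df, "y", "x")


class TestRepeatability:
    def test_recovers_planted_variance_ratio(self, rng):
        # sigma2_between = sigma2_within -> r = 0.5
        n_groups = 100
        g = np.repeat(np.arange(n_groups), 2)
        y = rng.normal(0, 1, n_groups)[g] + rng.normal(0, 1, g.size)
        df = pd.DataFrame({"female_id": g, "v": y})
        res = repeatability(df, "v")
        assert abs(res.r - 0.5) < 0.1
        assert res.p < 0.01

    def test_zero_between_variance(self, rng):
        g = np.repeat(np.arange(60), 2)
        df = pd.DataFrame({"female_id": g, "v": rng.standard_normal(g.size)})
        res = repeatability(df, "v")
        assert res.r < 0.15
        assert res.p > 0.05

    def test_pooled_year_shift_inflates_apparent_repeatability(self, rng):
        # females nested in years with a large year mean difference: pooling
        # manufactures repeatability that vanishes within years
        n_per_year = 60
        rows = []
        for year, shift in ((2013, 0.0), (2014, 3.0)):
            for i in range(n_per_year):
                fid = f"{year}_{i}"
                for _ in range(2):
                    rows.append({"female_id": fid, "year": year,
                                 "v": shift + rng.normal(0, 1)})
        df = pd.DataFrame(rows)
        res = repeatability(df, "v", year_column="year")
        within = [r for r, _ in res.per_year.values()]
        assert res.r > max(within) + 0.2
        assert all(r < 0.2 for r in within)

    def test_too_few_repeated_groups_rejected(self, rng):
        df = pd.DataFrame({"female_id": range(20),
                           "v": rng.standard_normal(20)})
        with pytest.raises(ValueError, match="5 groups"):
            repeatability(df, "v")


def _bh_oracle(p):
    """Independent step-up oracle: adjusted p = smallest level at which the
    hypothesis is rejected, scanning every candidate level in exact rational
    arithmetic (floats convert to Fractions losslessly)."""
    from fractions import Fraction

    pf = [Fraction(x) for x in p]
    m = len(pf)
    order = sorted(range(m), key=lambda i: pf[i])

    def rejected(alpha):
        k = 0
        for j in range(1, m + 1):
            if pf[order[j - 1]] <= Fraction(j, m) * alpha:
                k = j
        return order[:k]

    candidates = sorted({min(Fraction(1), pi * m / j) for pi in pf
                         for j in range(1, m + 1)} | {Fraction(1)})
    adj = [Fraction(1)] * m
    for alpha in candidates:
        for i in rejected(alpha):
            adj[i] = min(adj[i], alpha)
    return np.array([float(a) for a in adj])


class TestFDR:
    def test_textbook_vector(self, fixtures):
        fx = fixtures["bh_vector"]
        assert np.allclose(fdr_adjust(fx["p"]), fx["adjusted"])

    def test_degenerate_vectors(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=8))
    def test_matches_exhaustive_oracle(self, p):
        got = fdr_adjust(p)
        want = _bh_oracle(p)
        assert np.allclose(got, want, atol=1e-12)
        assert (got >= np.asarray(p) - 1e-12).all()


class TestCorrelationScreen:
    def test_thirteen_variables_give_78_pairs(self, rng):
        cols = {f"v{i}": rng.standard_normal(30) for i in range(13)}
        out = correlation_screen(pd.DataFrame(cols), list(cols))
        assert len(out) == 78

    def test_duplicated_column_perfect_correlation(self, rng):
        x = rng.standard_normal(40)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(40)})
        out = correlation_screen(df, ["a", "b", "c"]).set_index(["var_a", "var_b"])
        assert out.loc[("a", "b"), "r"] == pytest.approx(1.0)
        assert out.loc[("a", "b"), "p"] < 1e-10

    def test_adjusted_never_below_raw(self, rng):
        df = pd.DataFrame(rng.standard_normal((25, 5)),
                          columns=list("abcde"))
        out = correlation_screen(df, list("abcde"))
        assert (out["p_fdr"] >= out["p"] - 1e-12).all()


class TestStageYearContrasts:
    def _oxy_fixture(self):
        rows = []
        means = {(2014, INCUBATION): 167.6, (2014, CHICK_REARING): 232.9,
                 (2013, INCUBATION): 254.4, (2013, CHICK_REARING): 271.1}
        i = 0
        for (year, stage), m in means.items():
            for _ in range(4):
                rows.append({"female_id": f"F{i}", "year": year,
                             "stage": stage, "oxy": m})
                i += 1
        return pd.DataFrame(rows)

    def test_printed_oxy_percent_changes(self):
        out = stage_year_contrasts(self._oxy_fixture(), ["oxy"])
        by_year = out.set_index("year")["percent_change"]
        assert by_year[2014] == 39.0
        assert by_year[2013] == 6.6

    def test_equal_means_zero_change(self, rng):
        df = pd.DataFrame({
            "female_id": [f"F{i}" for i in range(40)],
            "year": [2013] * 40,
            "stage": [INCUBATION, CHICK_REARING] * 20,
            "v": np.tile([5.0, 5.0], 20) + 0.0,
        })
        out = stage_year_contrasts(df, ["v"])
        assert out["percent_change"].iloc[0] == 0.0

    def test_single_stage_rejected(self, rng):
        df = pd.DataFrame({"female_id": ["a", "b"], "year": [2013, 2013],
                           "stage": [INCUBATION] * 2, "v": [1.0, 2.0]})
        with pytest.raises(ValueError, match="stage"):
            stage_year_contrasts(df, ["v"])

    def test_planted_interaction_detected(self, rng):
        rows = []
        for i in range(80):
            year = 2013 if i < 40 else 2014
            inter = 3.0 if year == 2014 else 0.0
            for stage, s in ((INCUBATION, 0.0), (CHICK_REARING, 1.0)):
                rows.append({"female_id": f"F{i}", "year": year, "stage": stage,
                             "v": 10 + s * (1.0 + inter) + rng.normal(0, 0.8)})
        out = stage_year_contrasts(pd.DataFrame(rows), ["v"])
        assert (out["interaction_p"] < 0.01).all()


class TestGridAccounting:
    def test_default_plans_enumerate_exact_sizes(self):
        assert len(univariate_grid_plan()) == 156
        assert len(univariate_grid_plan(delta=True)) == 168
        dm, pca = multivariate_grid_plan()
        assert len(dm) == 396
        assert len(pca) == 297

    def test_every_univariate_outcome_has_a_family(self):
        assert all(o in OUTCOME_FAMILY for o in UNIVARIATE_OUTCOMES)

    def test_failures_are_counted_not_dropped(self, pipeline_report):
        for name, expected in [("univariate_absolute", 156),
                               ("univariate_delta", 168),
                               ("dm", 396), ("pca", 297)]:
            results = pipeline_report.results[name]
            assert len(results) == expected
            summary = pipeline_report.summaries[name]
            assert summary.total_tests == expected
            assert summary.proportion == summary.n_significant / expected

    def test_summary_alpha_extremes(self, pipeline_report):
        results = pipeline_report.results["univariate_absolute"]
        all_sig, _ = summarize_grid(results, alpha=1.0)
        none_sig, _ = summarize_grid(results, alpha=0.0)
        finite = sum(np.isfinite(r.p) for r in results)
        assert all_sig.n_significant == finite
        assert none_sig.n_significant == 0

    def test_survival_block_is_one_logistic_per_version(self, pipeline_report):
        surv = pipeline_report.results["survival"]
        assert len(surv) == 6
        assert {r.family for r in surv} == {"logistic"}
        assert all(r.outcome == "returned_year2" for r in surv)
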