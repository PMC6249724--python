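"""Pre-treatment: transforms, outlier policy, composites, deltas,
cell standardization, wing loading and visit partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from physiodys.cohort import CHICK_REARING, INCUBATION
from physiodys.preprocess import (compute_delta, exclude_cort_outliers,
                                  immune_composite, normalize_variables,
                                  oxidative_composite, partition_unknown_visits,
                                  standardize_by_cell, wing_loading)


class TestNormalize:
    def test_log_and_sqrt_values(self):
        df = pd.DataFrame({"a": [100.0], "b": [16.0]})
        out, applied = normalize_variables(df, {"a": "log", "b": "sqrt"})
        assert out["a"].iloc[0] == pytest.approx(np.log(100.0))
        assert out["b"].iloc[0] == 4.0
        assert applied == {"a": "log", "b": "sqrt"}

    def test_log_reduces_lognormal_skewness(self, rng):
        x = pd.DataFrame({"a": np.exp(rng.normal(0, 1, 500))})
        before = stats.skew(x["a"])
        out, _ = normalize_variables(x, {"a": "log"})
        assert abs(stats.skew(out["a"])) < abs(before)

    def test_nonpositive_under_log_flagged_with_rows(self):
        df = pd.DataFrame({"a": [1.0, -2.0, 3.0]})
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            normalize_variables(df, {"a": "log"})


class TestCortOutliers:
    def test_strict_inequality_at_threshold(self):
        df = pd.DataFrame({
            "female_id": list("abcd"),
            "corticosterone": [10.0, 79.9, 80.0, 80.1],
        })
        kept, excluded = exclude_cort_outliers(df)
        assert excluded == ["d"]
        assert set(kept["female_id"]) == {"a", "b", "c"}

    def test_empty_input(self):
        df = pd.DataFrame({"female_id": [], "corticosterone": []})
        kept, excluded = exclude_cort_outliers(df)
        assert kept.empty and excluded == []

    def test_planted_outlier_cohort_yields_exactly_seven(self, fixtures):
        kept, excluded = exclude_cort_outliers(fixtures["cort_outliers"])
        assert len(excluded) == 7

    def test_negative_threshold_rejected(self):
        df = pd.DataFrame({"female_id": ["a"], "corticosterone": [1.0]})
        with pytest.raises(ValueError):
            exclude_cort_outliers(df, threshold=-1)


class TestComposites:
    def test_rank_one_pair(self):
        x = pd.Series(np.arange(10.0))
        res = immune_composite(x, x.copy())
        assert res.variance_fraction[0] == pytest.approx(1.0)
        assert np.allclose(res.scores["nab_pc2"], 0.0, atol=1e-10)

    def test_uncorrelated_inputs_split_variance(self, rng):
        # eigenvalues of the 2x2 correlation matrix are (1 +/- r) / 2
        a = pd.Series(rng.normal(0, 1, 4000))
        b = pd.Series(rng.normal(0, 1, 4000))
        res = immune_composite(a, b)
        assert res.variance_fraction[0] == pytest.approx(0.5, abs=0.03)

    def test_exactly_two_axes(self, rng):
        res = oxidative_composite(pd.Series(rng.normal(size=30)),
                                  pd.Series(rng.normal(size=30)))
        assert res.scores.shape[1] == 2
        assert res.loadings.shape == (2, 2)

    def test_activation_orientation(self, rng):
        base = rng.normal(0, 1, 200)
        oxy = pd.Series(10 + base + 0.3 * rng.normal(size=200))
        droms = pd.Series(5 + base + 0.3 * rng.normal(size=200))
        res = oxidative_composite(oxy, droms)
        assert (res.loadings[:, 0] > 0).all()
        # both inputs above their means -> positive activation score
        j = int(np.argmax(oxy.to_numpy() + droms.to_numpy()))
        assert res.scores["ox_pc1"].iloc[j] > 0

    def test_anticorrelated_inputs_contrast_axis(self, rng):
        x = rng.normal(0, 1, 5000)
        y = -0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=5000)
        res = oxidative_composite(pd.Series(x), pd.Series(y))
        # first eigenvalue (1 - rho)/2 with rho = -0.9 -> 0.95
        assert res.variance_fraction[0] == pytest.approx(0.95, abs=0.01)
        assert np.sign(res.loadings[0, 0]) != np.sign(res.loadings[1, 0])

    def test_axes_orthogonal_fractions_sum_to_one(self, rng):
        res = immune_composite(pd.Series(rng.normal(size=50)),
                               pd.Series(rng.normal(size=50)))
        assert abs(res.loadings[:, 0] @ res.loadings[:, 1]) < 1e-8
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            immune_composite(pd.Series([1.0, 1.0, 1.0]),
                             pd.Series([1.0, 2.0, 3.0]))


class TestDelta:
    def test_delta_values_and_omissions(self, fixtures):
        panel = compute_delta(fixtures["paired_stages"], ["value"])
        got = dict(zip(panel.values["female_id"], panel.values["delta_value"]))
        assert got == {"P1": 0.0, "P2": -3.0}
        assert panel.omitted == [("P3", 2013)]

    def test_stage_swap_negates_deltas(self, fixtures):
        df = fixtures["paired_stages"]
        swapped = df.copy()
        swapped["stage"] = swapped["stage"].map(
            {INCUBATION: CHICK_REARING, CHICK_REARING: INCUBATION})
        a = compute_delta(df, ["value"]).values.set_index("female_id")
        b = compute_delta(swapped, ["value"]).values.set_index("female_id")
        assert np.allclose(a["delta_value"], -b.loc[a.index, "delta_value"])

    def test_panel_width_is_predictors_plus_mass(self, cohort):
        from physiodys.association import UNIVARIATE_PREDICTORS
        from physiodys.pipeline import PANEL_VARIABLES
        from physiodys.preprocess import immune_composite
        data = cohort.copy()
        nab = immune_composite(data["agglutination"], data["lysis"])
        data = pd.concat([data, nab.scores], axis=1)
        panel = compute_delta(data, UNIVARIATE_PREDICTORS + ["body_mass"])
        assert len(panel.variables) == 14


class TestStandardize:
    def test_additive_fixture_goes_to_zero(self, fixtures):
        panel = standardize_by_cell(fixtures["additive_cells"], ["value"])
        assert np.allclose(panel.values["value"], 0.0, atol=1e-8)

    def test_idempotent_on_standardized_data(self, rng):
        df = pd.DataFrame({
            "year": np.repeat([2013, 2014], 40),
            "stage": np.tile(np.repeat([INCUBATION, CHICK_REARING], 20), 2),
            "v": rng.normal(0, 1, 80),
        })
        once = standardize_by_cell(df, ["v"])
        twice = standardize_by_cell(df.assign(v=once.values["v"]), ["v"])
        assert np.allclose(once.values["v"], twice.values["v"], atol=1e-8)

    def test_interaction_leaves_computable_residual(self):
        # balanced 2x2 with a pure interaction: additive fit leaves +/- i/4
        # in the off-diagonal pattern (closed-form least squares)
        rows = []
        inter = 2.0
        for year in (2013, 2014):
            for stage in (INCUBATION, CHICK_REARING):
                val = 10.0 + (inter if (year == 2014 and stage == CHICK_REARING) else 0.0)
                rows += [{"year": year, "stage": stage, "v": val}] * 4
        df = pd.DataFrame(rows)
        panel = standardize_by_cell(df, ["v"])
        resid = panel.values["v"] * panel.scale["v"]
        cell_means = (pd.concat([df[["year", "stage"]], resid], axis=1)
                      .groupby(["year", "stage"])["v"].mean())
        expected = inter / 4.0
        assert cell_means[(2014, CHICK_REARING)] == pytest.approx(expected)
        assert cell_means[(2013, INCUBATION)] == pytest.approx(expected)
        assert cell_means[(2013, CHICK_REARING)] == pytest.approx(-expected)

    def test_small_cell_rejected(self):
        df = pd.DataFrame({
            "year": [2013, 2013, 2014],
            "stage": [INCUBATION, CHICK_REARING, INCUBATION],
            "v": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError, match="fewer than 2"):
            standardize_by_cell(df, ["v"])

    def test_marginal_means_zero_on_cohort(self, standardized_panel):
        z = standardized_panel.values
        labels = standardized_panel.cell_labels
        for col in ("glucose", "hematocrit"):
            by_year = z[col].groupby(labels["year"].values).mean()
            by_stage = z[col].groupby(labels["stage"].values).mean()
            assert np.allclose(by_year, 0.0, atol=1e-8)
            assert np.allclose(by_stage, 0.0, atol=1e-8)


class TestWingLoadingAndVisits:
    def test_raw_ratio_and_centering(self):
        wl = wing_loading(pd.Series([75.0, 85.0]), pd.Series([250.0, 250.0]),
                          pd.Series([2013, 2013]))
        raw = np.array([0.30, 0.34])
        assert np.allclose(wl, raw - raw.mean())

    def test_single_bird_centers_to_zero(self):
        wl = wing_loading(pd.Series([75.0]), pd.Series([250.0]),
                          pd.Series([2013]))
        assert wl.iloc[0] == 0.0

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            wing_loading(pd.Series([75.0]), pd.Series([0.0]), pd.Series([2013]))

    def test_proportional_allocation(self):
        f, m = partition_unknown_visits([30, 5, 1], [10, 5, 1], [8, 0, 1])
        assert np.allclose(f, [36.0, 5.0, 1.5])
        assert np.allclose(m, [12.0, 5.0, 1.5])

    def test_zero_known_with_unknown_rejected(self):
        with pytest.raises(ValueError):
            partition_unknown_visits([0], [0], [3])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(f=st.integers(0, 100), m=st.integers(0, 100), u=st.integers(0, 50))
    def test_partition_conserves_totals(self, f, m, u):
        if f + m == 0:
            u = 0
        ft, mt = partition_unknown_visits([f], [m], [u])
        assert ft[0] + mt[0] == pytest.approx(f + m + u)
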