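import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import stdtr

from queendx import (
    benjamini_hochberg,
    fit_linear_model,
    run_pairwise_de,
    student_t_test,
    SimulationConfig,
    generate_dataset,
    log2_transform,
)


def bh_step_up_oracle(p):
    """Brute-force BH from the step-up definition: the adjusted value of the
    r-th smallest p is min over j >= r of min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    s = np.sort(p)
    raw = m * s / np.arange(1, m + 1)
    tail = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    return np.array([tail[np.searchsorted(s, pi)] for pi in p])


class TestStudentT:
    def test_identical_samples_give_t_zero_p_one(self):
        res = student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_df_for_seven_vs_six(self):
        rng = np.random.default_rng(0)
        res = student_t_test(rng.normal(size=7), rng.normal(size=6))
        assert res.df == 11

    def test_closed_form_oracle_on_small_samples(self):
        # pooled t by direct formula evaluation on {1,2,3} vs {4,5,6}
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        sp2 = (2 * 1.0 + 2 * 1.0) / 4  # both sample variances are 1
        t_expect = (2.0 - 5.0) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_expect = 2 * (1 - stdtr(4, abs(t_expect)))
        res = student_t_test(x, y)
        assert res.t_stat == pytest.approx(t_expect, rel=1e-12)
        assert res.df == 4
        assert res.p_value == pytest.approx(p_expect, rel=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.floats(-50, 50), min_size=3, max_size=9),
        y=st.lists(st.floats(-50, 50), min_size=3, max_size=9),
    )
    def test_antisymmetric_in_group_order(self, x, y):
        a = student_t_test(x, y)
        b = student_t_test(y, x)
        assert a.t_stat == pytest.approx(-b.t_stat, abs=1e-10)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.df == b.df

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            student_t_test([1.0], [1.0, 2.0, 3.0])

    def test_welch_df_differs_under_unequal_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5, size=7)
        y = rng.normal(0, 0.1, size=7)
        student = student_t_test(x, y)
        welch = student_t_test(x, y, equal_var=False)
        assert student.df == 12
        assert welch.df < 12


class TestBenjaminiHochberg:
    def test_uniform_grid_collapses_to_largest(self):
        # step-up on {0.01, 0.02, 0.03, 0.04}: m*p/rank = 0.04 for every rank
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.0001], [np.nan, 0.5]])
    def test_values_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            benjamini_hochberg(bad)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.lists(
            st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=60
        )
    )
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(
            benjamini_hochberg(p), bh_step_up_oracle(p), rtol=1e-12
        )

    def test_order_preserving_and_monotone_in_sorted_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1, size=40)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPairwiseDe:
    def test_injected_marker_has_smallest_adjusted_p(self, heat_config):
        matrix, truth = generate_dataset(heat_config)
        de = run_pairwise_de(log2_transform(matrix), "heatshock", "control")
        assert de.iloc[0]["accession"] == "XP_001120006.2"
        assert de.iloc[0]["significant"]
        assert de.iloc[0]["direction"] == "up"

    def test_duplicate_group_split_yields_no_discoveries(self, heat_config):
        # same-distribution split: relabel control samples into two halves
        from dataclasses import replace

        cfg = replace(
            heat_config, marker_effects={}, groups=(("a", 7), ("b", 7)), seed=11
        )
        matrix, _ = generate_dataset(cfg)
        de = run_pairwise_de(log2_transform(matrix), "a", "b")
        assert int(de["significant"].sum()) == 0

    def test_significant_set_nested_across_fdr_levels(self, heat_config):
        matrix, _ = generate_dataset(heat_config)
        lm = log2_transform(matrix)
        at5 = run_pairwise_de(lm, "heatshock", "control", fdr=0.05)
        at10 = run_pairwise_de(lm, "heatshock", "control", fdr=0.10)
        sig5 = set(at5[at5["significant"]]["accession"])
        sig10 = set(at10[at10["significant"]]["accession"])
        assert sig5 <= sig10

    def test_unknown_group_label_raises(self, heat_config):
        matrix, _ = generate_dataset(heat_config)
        with pytest.raises(KeyError, match="queenless"):
            run_pairwise_de(log2_transform(matrix), "queenless", "control")

    def test_sparse_rows_reported_untested_not_raised(self, heat_config):
        matrix, _ = generate_dataset(heat_config)
        lm = log2_transform(matrix)
        acc = lm.accessions[5]
        cols = lm.samples_in_group("heatshock")[1:]
        lm.intensities.loc[acc, cols] = np.nan  # one present value in group A
        de = run_pairwise_de(lm, "heatshock", "control")
        assert acc not in set(de["accession"])
        assert de.attrs["n_untested"] == 1


class TestLinearModel:
    def test_perfectly_linear_response_has_r2_one(self):
        x = np.arange(6, dtype=float)
        design = pd.DataFrame({"duration_h": x})
        res = fit_linear_model(3.0 + 2.0 * x, design)
        assert res.r_squared == pytest.approx(1.0)
        assert res.coefficients["duration_h"] == pytest.approx(2.0)
        assert res.residual_df == 4

    def test_constant_response_gives_zero_slope_zero_f(self):
        design = pd.DataFrame({"duration_h": np.arange(6, dtype=float)})
        res = fit_linear_model(np.full(6, 5.0), design)
        assert res.coefficients["duration_h"] == pytest.approx(0.0, abs=1e-12)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_matches_normal_equations_on_six_point_fixture(self):
        x1 = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        x2 = np.array([1.0, 0.0, 2.0, 1.0, 3.0, 2.0])
        y = np.array([2.0, 1.5, 4.0, 3.0, 6.5, 5.0])
        X = np.column_stack([np.ones(6), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # normal equations by hand
        res = fit_linear_model(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert res.coefficients["const"] == pytest.approx(beta[0], abs=1e-10)
        assert res.coefficients["x1"] == pytest.approx(beta[1], abs=1e-10)
        assert res.coefficients["x2"] == pytest.approx(beta[2], abs=1e-10)

    def test_rank_deficient_design_names_collinear_terms(self):
        x = np.arange(8, dtype=float)
        design = pd.DataFrame({"dose": x, "dose_twice": 2 * x})
        with pytest.raises(ValueError, match="dose"):
            fit_linear_model(x + 1, design)
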