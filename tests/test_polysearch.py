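"""Design construction, grid enumeration, LOO evaluation and model search."""

import numpy as np
import pandas as pd
import pytest

import curvegrade as cg
from curvegrade.data import TEST_VARIABLES
from curvegrade.errors import ConfigError, DomainError
from curvegrade.polysearch import DegreeGrid, PolynomialModelSpec


def spec_for(degrees):
    return PolynomialModelSpec("grade_math", TEST_VARIABLES, degrees)


class TestBuildDesign:
    def test_all_linear_has_four_columns(self, small_table):
        z = cg.build_design(small_table.loc[:, list(TEST_VARIABLES)], spec_for((1, 1, 1)))
        assert z.shape == (len(small_table), 4)
        np.testing.assert_array_equal(z[:, 0], 1.0)

    def test_selected_math_shape_has_six_columns(self, small_table):
        # degrees (2, 2, 1): intercept + 3 linear + 2 power columns
        z = cg.build_design(small_table.loc[:, list(TEST_VARIABLES)], spec_for((2, 2, 1)))
        assert z.shape == (len(small_table), 6)

    def test_degree_zero_collapses_to_linear(self, small_table):
        x = small_table.loc[:, list(TEST_VARIABLES)]
        np.testing.assert_array_equal(
            cg.build_design(x, spec_for((0, 1, 1))),
            cg.build_design(x, spec_for((1, 1, 1))),
        )

    def test_square_root_column(self):
        z = cg.build_design(
            pd.DataFrame({"x": [4.0, 9.0]}),
            PolynomialModelSpec("y", ("x",), (0.5,)),
        )
        np.testing.assert_allclose(z[:, 2], [2.0, 3.0])

    def test_fractional_power_of_nonpositive_base_rejected(self):
        with pytest.raises(DomainError, match="fractional"):
            cg.build_design(
                pd.DataFrame({"x": [4.0, -1.0]}),
                PolynomialModelSpec("y", ("x",), (2.5,)),
            )


class TestEnumerateGrid:
    def test_default_grid_cardinalities(self):
        grid = DegreeGrid()
        assert len(grid.values) == 11
        assert len(cg.enumerate_grid(grid, "y", ("g",))) == 11
        assert len(cg.enumerate_grid(grid, "y", TEST_VARIABLES)) == 11**3 == 1331

    def test_quarter_step_grid_without_linear_reaches_8000(self):
        grid = DegreeGrid.regular(step=0.25, max_degree=5.0, include_linear=False)
        assert len(grid.values) == 20
        assert len(cg.enumerate_grid(grid, "y", TEST_VARIABLES)) == 8000

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            DegreeGrid(())


class TestLooEvaluate:
    def test_exact_linear_data_interpolates(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.uniform(1, 5, size=(30, 3)), columns=TEST_VARIABLES)
        y = 1.0 + x.to_numpy() @ np.array([0.5, -0.2, 0.3])
        ev = cg.loo_evaluate(y, x, spec_for((1, 1, 1)))
        assert ev.median_abs_dev == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(ev.abs_deviations, 0.0, atol=1e-10)

    @pytest.mark.parametrize(
        "degrees", [(1, 1, 1), (2, 2, 1), (0.5, 3, 1.5), (5, 0.5, 4.5)]
    )
    def test_hat_matrix_shortcut_equals_brute_force(self, small_table, degrees):
        x = small_table.loc[:, list(TEST_VARIABLES)]
        y = small_table["grade_math"].to_numpy()
        fast = cg.loo_evaluate(y, x, spec_for(degrees))
        slow = cg.loo_evaluate(y, x, spec_for(degrees), brute_force=True)
        np.testing.assert_allclose(
            fast.abs_deviations, slow.abs_deviations, atol=1e-8
        )
        assert fast.median_abs_dev == pytest.approx(slow.median_abs_dev, abs=1e-8)

    def test_criterion_band_on_study_scale_cohorts(self):
        """Study-like cohorts produce criteria in a plausible 0.5-0.8 band."""
        meds = []
        for seed in range(5):
            df = cg.generate_cohort(cg.default_generative_spec(seed=30 + seed))
            scaled, _ = cg.scale_predictors(
                df, TEST_VARIABLES, "fit", on_nonpositive="clamp"
            )
            ev = cg.loo_evaluate(
                df["grade_german"].to_numpy(),
                scaled.loc[:, list(TEST_VARIABLES)],
                spec_for((1, 1, 1)),
            )
            meds.append(ev.median_abs_dev)
        assert 0.4 < np.median(meds) < 0.9


class TestSearch:
    def test_search_is_deterministic(self, small_table):
        r1 = cg.FractionalPolySearch(small_table, "grade_math", TEST_VARIABLES).fit()
        r2 = cg.FractionalPolySearch(small_table, "grade_math", TEST_VARIABLES).fit()
        assert [s.degrees for s, _ in r1.ranking] == [s.degrees for s, _ in r2.ranking]
        assert r1.best_criterion == r2.best_criterion

    def test_best_is_minimum_and_linear_reference_consistent(self, small_table):
        res = cg.FractionalPolySearch(small_table, "grade_math", TEST_VARIABLES).fit()
        crits = [c for _, c in res.ranking]
        assert res.best_criterion == min(crits)
        assert res.ranking[res.linear_rank - 1][0].is_all_linear
        assert res.ranking[res.linear_rank - 1][1] == res.linear_criterion

    def test_tie_break_prefers_fewer_polynomial_terms(self):
        # degree-2 term duplicated by construction: x**2 column of a constant-1
        # predictor is constant, so specs (1,1) and tied criteria arise from
        # the duplicate linear states 0 and 1 -> the canonical report is 1
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.uniform(1, 5, size=(40, 2)), columns=["a", "b"])
        y = 2.0 + 0.5 * x["a"].to_numpy() + rng.normal(0, 0.3, 40)
        res = cg.search(y, x, DegreeGrid((0.0, 1.0, 2.0)))
        # grid has 9 specs but only 4 distinct models; ties between the
        # 0/1 encodings must resolve to the canonical all-linear report
        assert len(res.ranking) == 4
        for spec, _ in res.ranking:
            assert 0.0 not in spec.canonical_degrees

    def test_full_sample_r2_monotone_in_nesting(self, small_table):
        """Adding a power term never lowers full-sample R2."""
        x = small_table.loc[:, list(TEST_VARIABLES)]
        y = small_table["grade_math"].to_numpy()
        base = cg.fit_poly(y, x, spec_for((1, 1, 1)))
        for degrees in [(2, 1, 1), (2, 2, 1), (2, 2, 3.5)]:
            bigger = cg.fit_poly(y, x, spec_for(degrees))
            assert bigger.r2 >= base.r2 - 1e-12

    def test_g_only_best_model_k_at_most_two(self, study_cohort):
        df, _ = cg.attach_g_scores(study_cohort, on_nonpositive="clamp")
        res = cg.FractionalPolySearch(df, "grade_math", ("g_scaled",)).fit()
        assert res.best.k in (1, 2)
        assert res.n_grid == 11

    def test_quadratic_effect_detected_single_cohort(self, test_moments):
        """A strong quadratic Analogies effect is selected as curvilinear."""
        effect = cg.GradeEffect(
            1.05, (0.146, 0.202, 0.203), (0.0, 0.1, 0.0), (1.0, 2.0, 1.0), 0.8
        )
        spec = cg.GenerativeSpec(
            test_moments, {"grade_math": effect}, n=2000, seed=0, discretize=False
        )
        df = cg.generate_cohort(spec)
        scaled, _ = cg.scale_predictors(
            df, TEST_VARIABLES, "fit", on_nonpositive="clamp"
        )
        res = cg.FractionalPolySearch(
            scaled.assign(grade_math=df["grade_math"]), "grade_math", TEST_VARIABLES
        ).fit()
        assert res.best.spec.canonical_degrees[1] != 1.0


class TestCompareModels:
    def test_self_comparison_is_zero(self, study_cohort):
        df, _ = cg.attach_g_scores(study_cohort, on_nonpositive="clamp")
        res = cg.FractionalPolySearch(df, "grade_math", ("g_scaled",)).fit()
        comp = cg.compare_models(res, res)
        assert comp.criterion_diff == 0.0
        assert comp.adj_r2_diff == 0.0

    def test_outcome_mismatch_rejected(self, study_cohort):
        df, _ = cg.attach_g_scores(study_cohort, on_nonpositive="clamp")
        a = cg.FractionalPolySearch(df, "grade_math", ("g_scaled",)).fit()
        b = cg.FractionalPolySearch(df, "grade_german", ("g_scaled",)).fit()
        with pytest.raises(Exception, match="mismatch"):
            cg.compare_models(a, b)

    def test_curvilinear_specific_beats_linear_g(self, test_moments):
        """When the truth has a specific-ability curve and g is linear, the
        specific-ability search reaches the higher adjusted R2."""
        effect = cg.GradeEffect(
            1.05, (0.146, 0.202, 0.203), (0.0, 0.12, 0.0), (1.0, 2.0, 1.0), 0.8
        )
        spec = cg.GenerativeSpec(
            test_moments, {"grade_math": effect}, n=2000, seed=4, discretize=False
        )
        df = cg.generate_cohort(spec)
        df, _ = cg.attach_g_scores(df, on_nonpositive="clamp")
        scaled, _ = cg.scale_predictors(
            df, TEST_VARIABLES, "fit", on_nonpositive="clamp"
        )
        scaled["g_scaled"] = df["g_scaled"]
        g_res = cg.FractionalPolySearch(
            scaled.assign(grade_math=df["grade_math"]), "grade_math", ("g_scaled",)
        ).fit()
        sp_res = cg.FractionalPolySearch(
            scaled.assign(grade_math=df["grade_math"]), "grade_math", TEST_VARIABLES
        ).fit()
        comp = cg.compare_models(g_res, sp_res)
        assert comp.adj_r2_diff > 0
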