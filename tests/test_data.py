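"""Cohort I/O, moment computation, scaling and the variance-sum utility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import curvegrade as cg
from curvegrade.data import TEST_VARIABLES
from curvegrade.errors import (
    DataError,
    DegenerateIntervalError,
    DegenerateVarianceError,
    DomainError,
    SchemaError,
)


class TestCohortIO:
    def test_round_trip_preserves_cells(self, study_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        cg.write_cohort(study_cohort, path)
        back = cg.read_cohort(path)
        for col in TEST_VARIABLES + ("grade_math",):
            np.testing.assert_array_equal(
                back[col].to_numpy(), study_cohort[col].to_numpy()
            )

    def test_round_trip_preserves_moments(self, study_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        cg.write_cohort(study_cohort, path)
        m1 = cg.compute_moments(study_cohort, TEST_VARIABLES)
        m2 = cg.compute_moments(cg.read_cohort(path), TEST_VARIABLES)
        np.testing.assert_allclose(m1.corr, m2.corr, atol=1e-12)
        np.testing.assert_allclose(m1.means, m2.means, atol=1e-12)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"unfolding": [1, 2, 3], "number_series": [2, 3, 4]}).to_csv(
            path, index=False
        )
        with pytest.raises(SchemaError, match="analogies"):
            cg.read_cohort(path)

    def test_missing_value_is_data_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "unfolding": [1.0, None, 3.0],
                "analogies": [1.0, 2.0, 3.0],
                "number_series": [2.0, 3.0, 4.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(DataError, match="unfolding"):
            cg.read_cohort(path)


class TestMoments:
    @pytest.mark.parametrize(
        "y, expected_r",
        [([1.0, 2.0, 3.0], 1.0), ([3.0, 2.0, 1.0], -1.0)],
    )
    def test_collinear_pairs(self, y, expected_r):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": y})
        m = cg.compute_moments(df, ("a", "b"))
        assert m.corr[0, 1] == pytest.approx(expected_r)
        np.testing.assert_allclose(m.means, [2.0, 2.0])
        np.testing.assert_allclose(m.sds, [1.0, 1.0])

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(DegenerateVarianceError):
            cg.compute_moments(df, ("a", "b"))

    def test_large_cohort_recovers_target_correlations(self, test_moments):
        df = cg.sample_predictors(test_moments, n=100_000, seed=1)
        m = cg.compute_moments(df, TEST_VARIABLES)
        np.testing.assert_allclose(m.corr, test_moments.corr, atol=0.02)


class TestFisherCI:
    def test_published_interval_german_g(self):
        # r = .28 between the German grade and the g score at n = 219
        lo, hi = cg.fisher_ci(0.28, 219)
        assert (round(lo, 2), round(hi, 2)) == (0.15, 0.40)

    def test_published_interval_german_english(self):
        lo, hi = cg.fisher_ci(0.54, 219)
        assert (round(lo, 2), round(hi, 2)) == (0.44, 0.63)

    def test_symmetric_about_zero(self):
        lo, hi = cg.fisher_ci(0.0, 219)
        assert lo == pytest.approx(-hi)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(DegenerateIntervalError):
            cg.fisher_ci(1.0, 219)

    @given(r=st.floats(-0.95, 0.95), n=st.integers(5, 5000))
    @settings(max_examples=50, deadline=None)
    def test_width_strictly_decreasing_in_n(self, r, n):
        lo1, hi1 = cg.fisher_ci(r, n)
        lo2, hi2 = cg.fisher_ci(r, n + 50)
        assert hi2 - lo2 < hi1 - lo1


class TestScaling:
    def test_fit_hits_target_center_and_sd(self, study_cohort):
        scaled, params = cg.scale_predictors(
            study_cohort, TEST_VARIABLES, "fit", on_nonpositive="ignore"
        )
        x = scaled.loc[:, TEST_VARIABLES].to_numpy()
        np.testing.assert_allclose(x.mean(axis=0), 3.0, atol=1e-10)
        np.testing.assert_allclose(x.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_correlations_invariant_under_scaling(self, study_cohort):
        before = cg.compute_moments(study_cohort, TEST_VARIABLES).corr
        scaled, _ = cg.scale_predictors(
            study_cohort, TEST_VARIABLES, "fit", on_nonpositive="ignore"
        )
        after = cg.compute_moments(scaled, TEST_VARIABLES).corr
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_stored_params_map_known_value(self):
        params = cg.ScalingParams(("x",), [9.31], [4.26])
        assert params.transform_array(np.array([9.31]))[0] == pytest.approx(3.0)
        # one SD above the mean lands one target-SD above the center
        assert params.transform_array(np.array([9.31 + 4.26]))[0] == pytest.approx(4.0)

    def test_refitting_is_not_idempotent_but_reapplying_is(self, study_cohort):
        once, params = cg.scale_predictors(
            study_cohort, TEST_VARIABLES, "fit", on_nonpositive="ignore"
        )
        again, _ = cg.scale_predictors(
            once, TEST_VARIABLES, params, on_nonpositive="ignore"
        )
        # applying the *stored* params to already-scaled data shifts it again
        assert not np.allclose(
            again["unfolding"].to_numpy(), once["unfolding"].to_numpy()
        )

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        with pytest.raises(DegenerateVarianceError):
            cg.scale_predictors(df, ("x",), "fit")

    def test_nonpositive_scaled_value_is_domain_error(self):
        # one extreme low outlier among many similar values scales below zero
        # (a sample z-score below -3 needs n >= 11)
        df = pd.DataFrame(
            {"x": [10.0, 10.1, 9.9, 10.05, 9.95, 10.2, 9.8, 10.15, 9.85, 10.0,
                   10.1, -50.0]}
        )
        with pytest.raises(DomainError):
            cg.scale_predictors(df, ("x",), "fit")
        scaled, _ = cg.scale_predictors(df, ("x",), "fit", on_nonpositive="clamp")
        assert (scaled["x"] > 0).all()


class TestVarianceOfSum:
    @pytest.mark.parametrize(
        "sd_x, sd_y, rho, sign, expected",
        [
            (1.0, 1.0, 0.0, 1, 2.0),
            (1.0, 1.0, 1.0, 1, 4.0),
            (2.0, 3.0, 0.5, -1, 7.0),
        ],
    )
    def test_known_values(self, sd_x, sd_y, rho, sign, expected):
        assert cg.variance_of_sum(sd_x, sd_y, rho, sign) == pytest.approx(expected)

    @given(sd_x=st.floats(0, 10), sd_y=st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_independence_conserves_variance(self, sd_x, sd_y):
        assert cg.variance_of_sum(sd_x, sd_y, 0.0) == pytest.approx(
            sd_x**2 + sd_y**2
        )
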