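import numpy as np
import pandas as pd
import pytest

import curvegrade as cg
from curvegrade import datasets

TESTS = ("unfolding", "analogies", "number_series")


@pytest.fixture(scope="session")
def test_moments():
    """Published moments of the three ability tests (n = 219)."""
    return datasets.test_score_moments()


@pytest.fixture(scope="session")
def study_cohort():
    """One synthetic study-condition cohort (n = 219, discretized grades)."""
    return cg.generate_cohort(cg.default_generative_spec(seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """Large continuous cohort for asymptotic checks (n = 5000)."""
    return cg.generate_cohort(
        cg.default_generative_spec(n=5000, seed=5, discretize=False)
    )


@pytest.fixture()
def small_table():
    rng = np.random.default_rng(7)
    n = 25
    x = rng.normal(3.0, 1.0, size=(n, 3)).clip(0.2)
    y = 3.0 + 0.3 * x[:, 0] + 0.1 * x[:, 1] ** 2 + rng.normal(0, 0.5, n)
    return pd.DataFrame(
        {
            "unfolding": x[:, 0],
            "analogies": x[:, 1],
            "number_series": x[:, 2],
            "grade_math": y,
        }
    )
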