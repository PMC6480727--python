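"""Published summary statistics of the reference cohort.

The reference study is a cross-sectional sample of n = 219 secondary-school
students (mean age 16.03 years) with scores on three ability tests from the
Wilde Intelligence Test battery — Unfolding (figural/spatial), Analogies
(verbal) and Number Series (numerical reasoning) — and school grades in
math, German, English and sports coded 1 (insufficient) to 6 (very good).
The raw per-subject data were never deposited; only the moment summary
below was published, which is exactly what the moment-based code paths and
the synthetic-cohort generator consume.

Zero-order validities of the math grade (its correlations with the tests
and the g score) were published in the regression tables rather than in
the descriptive table, so the math grade is not part of the full
correlation matrix; its validities are available via
:func:`grade_validities`.
"""

from __future__ import annotations

import numpy as np

from .data import MomentSummary

N_SUBJECTS = 219

_COHORT_VARS = (
    "age",
    "unfolding",
    "analogies",
    "number_series",
    "g",
    "grade_german",
    "grade_english",
    "grade_sports",
)

_MEANS = (16.03, 9.31, 8.21, 8.26, -0.00, 3.91, 3.74, 5.05)
_SDS = (1.49, 4.26, 3.80, 4.01, 0.81, 0.94, 0.94, 0.72)

# lower triangle, row by row, in _COHORT_VARS order
_CORR_LOWER = (
    (0.12,),
    (0.31, 0.33),
    (0.21, 0.39, 0.39),
    (0.28, 0.71, 0.72, 0.85),
    (0.23, 0.22, 0.24, 0.19, 0.28),
    (0.19, 0.13, 0.27, 0.22, 0.27, 0.54),
    (-0.01, -0.01, 0.10, 0.03, 0.05, 0.16, 0.11),
)


def _full_corr() -> np.ndarray:
    p = len(_COHORT_VARS)
    r = np.eye(p)
    for i, row in enumerate(_CORR_LOWER, start=1):
        r[i, : len(row)] = row
        r[: len(row), i] = row
    return r


def cohort_moments() -> MomentSummary:
    """Published moments of age, the three tests, the g score and three grades."""
    return MomentSummary(_COHORT_VARS, _MEANS, _SDS, _full_corr(), N_SUBJECTS)


def test_score_moments() -> MomentSummary:
    """Published moments of the three ability tests only (the generator default)."""
    return cohort_moments().subset(("unfolding", "analogies", "number_series"))


def grade_validities() -> dict[str, dict[str, float]]:
    """Published zero-order correlations of each grade with the tests and g."""
    return {
        "grade_math": {
            "unfolding": 0.31,
            "analogies": 0.35,
            "number_series": 0.36,
            "g": 0.44,
        },
        "grade_german": {
            "unfolding": 0.22,
            "analogies": 0.24,
            "number_series": 0.19,
            "g": 0.28,
        },
        "grade_english": {
            "unfolding": 0.13,
            "analogies": 0.27,
            "number_series": 0.22,
            "g": 0.27,
        },
        "grade_sports": {
            "unfolding": -0.01,
            "analogies": 0.10,
            "number_series": 0.03,
            "g": 0.05,
        },
    }


def grade_moments() -> dict[str, dict[str, float]]:
    """Published mean/SD of each grade.

    The math grade's descriptives were not published; the values adopted
    here (mean 3.80, SD 0.94) mirror the two published academic grades and
    are flagged ``assumed`` so downstream reports can say so.
    """
    return {
        "grade_math": {"mean": 3.80, "sd": 0.94, "assumed": True},
        "grade_german": {"mean": 3.91, "sd": 0.94, "assumed": False},
        "grade_english": {"mean": 3.74, "sd": 0.94, "assumed": False},
        "grade_sports": {"mean": 5.05, "sd": 0.72, "assumed": False},
    }


def linear_r2() -> dict[str, float]:
    """Published R-squared of the three-test linear regression per grade."""
    return {
        "grade_math": 0.200,
        "grade_german": 0.083,
        "grade_english": 0.089,
        "grade_sports": 0.011,
    }
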