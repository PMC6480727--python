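"""Core data containers, cohort I/O, moment computation and predictor scaling.

A *cohort* is a per-subject :class:`pandas.DataFrame` with one row per
student: an identifier, optionally age, three ability test scores
(``unfolding``, ``analogies``, ``number_series``) and school grades on a
1-6 point coding (``grade_math``, ``grade_german``, ``grade_english``,
``grade_sports``).  A :class:`MomentSummary` is the complete sufficient
summary used throughout the moment-based code paths: variable names,
means, standard deviations (n-1 denominator), the Pearson correlation
matrix and the subject count.

Predictors are rescaled to a center of 3 and an SD of 1 before any
polynomial modelling.  The center of 3 keeps every scaled score positive
in practice, which matters because fractional powers (x**0.5 and friends)
are undefined for non-positive bases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DataError,
    DegenerateIntervalError,
    DegenerateVarianceError,
    DomainError,
    MatrixError,
    SchemaError,
)

#: canonical cohort column order
COHORT_COLUMNS = (
    "subject_id",
    "age",
    "unfolding",
    "analogies",
    "number_series",
    "grade_math",
    "grade_german",
    "grade_english",
    "grade_sports",
)

TEST_VARIABLES = ("unfolding", "analogies", "number_series")
GRADE_VARIABLES = ("grade_math", "grade_german", "grade_english", "grade_sports")


# ---------------------------------------------------------------------------
# moment summary


@dataclass
class MomentSummary:
    """Means, SDs, correlation matrix and n for a set of variables.

    Parameters
    ----------
    variable_names
        Ordered variable labels.
    means, sds
        Per-variable mean and standard deviation (n-1 denominator).
    corr
        Symmetric correlation matrix with a unit diagonal, ordered like
        ``variable_names``.
    n
        Number of subjects the moments were computed from.
    """

    variable_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.variable_names = tuple(self.variable_names)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        p = len(self.variable_names)
        if self.means.shape != (p,) or self.sds.shape != (p,):
            raise MatrixError("means/sds length does not match variable names")
        if self.corr.shape != (p, p):
            raise MatrixError("correlation matrix shape does not match variables")
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise MatrixError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-12):
            raise MatrixError("correlation matrix diagonal is not 1")
        off = self.corr[~np.eye(p, dtype=bool)]
        if off.size and (np.abs(off) > 1 + 1e-12).any():
            raise MatrixError("off-diagonal correlation outside [-1, 1]")
        if (self.sds <= 0).any():
            raise DegenerateVarianceError("all SDs must be strictly positive")
        if self.n < 3:
            raise DataError("a moment summary requires n >= 3")

    # -- convenience -------------------------------------------------------

    def index_of(self, names: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.variable_names.index(v) for v in names])
        except ValueError as exc:
            raise SchemaError(f"variable not in moment summary: {exc}") from exc

    def subset(self, names: Sequence[str]) -> "MomentSummary":
        """Moment summary restricted to ``names`` (in the given order)."""
        idx = self.index_of(names)
        return MomentSummary(
            tuple(names),
            self.means[idx],
            self.sds[idx],
            self.corr[np.ix_(idx, idx)],
            self.n,
        )

    def covariance(self) -> np.ndarray:
        d = np.diag(self.sds)
        return d @ self.corr @ d

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variable_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "corr": self.corr.tolist(),
            "n": int(self.n),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MomentSummary":
        corr = np.asarray(d["corr"], dtype=float)
        p = len(d["variables"])
        if corr.ndim == 1:  # row-major flat layout
            corr = corr.reshape(p, p)
        return cls(tuple(d["variables"]), d["means"], d["sds"], corr, int(d["n"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "MomentSummary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScalingParams:
    """Affine rescaling x -> (x - source_mean) / source_sd * target_sd + target_center.

    Fitted once on a cohort and reusable verbatim on new data, so that
    generation-time and analysis-time variable spaces coincide.
    """

    variables: tuple[str, ...]
    source_mean: np.ndarray
    source_sd: np.ndarray
    target_center: float = 3.0
    target_sd: float = 1.0

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.source_mean = np.asarray(self.source_mean, dtype=float)
        self.source_sd = np.asarray(self.source_sd, dtype=float)
        if (self.source_sd <= 0).any():
            raise DegenerateVarianceError("source SDs must be positive")
        if self.target_sd <= 0:
            raise DegenerateVarianceError("target SD must be positive")

    def transform_array(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.source_mean) / self.source_sd * self.target_sd + self.target_center

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "source_mean": self.source_mean.tolist(),
            "source_sd": self.source_sd.tolist(),
            "target_center": self.target_center,
            "target_sd": self.target_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScalingParams":
        return cls(
            tuple(d["variables"]),
            d["source_mean"],
            d["source_sd"],
            float(d.get("target_center", 3.0)),
            float(d.get("target_sd", 1.0)),
        )


# ---------------------------------------------------------------------------
# cohort I/O


def validate_cohort(
    df: pd.DataFrame,
    required: Sequence[str] = TEST_VARIABLES,
    discrete_grades: bool = False,
) -> pd.DataFrame:
    """Validate a cohort table; returns the (unchanged) frame.

    Missing values in any required column are a hard error — moments from
    silently imputed or dropped rows would no longer describe the cohort.
    """
    if len(df) < 1:
        raise DataError("cohort is empty")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column missing: {col!r}")
        series = df[col]
        if not np.issubdtype(series.dtype, np.number):
            bad = series[pd.to_numeric(series, errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise DataError(f"non-numeric value in column {col!r} (row {row})")
        if series.isna().any():
            row = series.index[series.isna()][0]
            raise DataError(f"missing value in column {col!r} (row {row})")
    if discrete_grades:
        for col in GRADE_VARIABLES:
            if col not in df.columns:
                continue
            v = df[col].to_numpy(dtype=float)
            if not np.all((v == np.round(v)) & (v >= 1) & (v <= 6)):
                raise DataError(f"column {col!r} is not integer-coded in [1, 6]")
    return df


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    required: Sequence[str] = TEST_VARIABLES,
) -> pd.DataFrame:
    """Read a cohort CSV (comma-separated, header row, UTF-8).

    ``schema`` optionally maps canonical column names to the names used in
    the file, e.g. ``{"unfolding": "UF_raw"}``.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"cohort file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise SchemaError(f"mapped columns not in file: {missing}")
        df = df.rename(columns={src: dst for dst, src in schema.items()})
    return validate_cohort(df, required=required)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV with full float precision (round-trip safe).

    Floats are written as their shortest round-trip representation;
    :func:`read_cohort` parses with correctly-rounded conversion, so every
    numeric cell survives a write/read cycle bit-exactly.
    """
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations


def compute_moments(table: pd.DataFrame, variables: Sequence[str]) -> MomentSummary:
    """Means, n-1 SDs and Pearson correlations for the selected columns."""
    variables = tuple(variables)
    validate_cohort(table, required=variables)
    if len(table) < 3:
        raise DataError("moment computation requires n >= 3")
    x = table.loc[:, variables].to_numpy(dtype=float)
    sds = x.std(axis=0, ddof=1)
    if (sds <= 0).any():
        bad = [v for v, s in zip(variables, sds) if s <= 0]
        raise DegenerateVarianceError(f"zero-variance column(s): {bad}")
    corr = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return MomentSummary(variables, x.mean(axis=0), sds, corr, len(table))


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation.

    Symmetric on the z scale: tanh(atanh(r) +/- z_crit / sqrt(n - 3)).
    """
    if abs(r) >= 1:
        raise DegenerateIntervalError("Fisher CI undefined for |r| >= 1")
    if n < 4:
        raise DataError("Fisher CI requires n >= 4")
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def scale_predictors(
    table: pd.DataFrame,
    variables: Sequence[str],
    params: ScalingParams | str = "fit",
    target_center: float = 3.0,
    target_sd: float = 1.0,
    on_nonpositive: str = "error",
) -> tuple[pd.DataFrame, ScalingParams]:
    """Affinely rescale predictor columns to ``target_center`` / ``target_sd``.

    With ``params="fit"`` the source moments are estimated from ``table``
    (scaled columns then have exactly the target mean and SD); a fitted
    :class:`ScalingParams` can be passed back in to apply the identical
    transform to new data.

    ``on_nonpositive`` controls what happens when a scaled value is <= 0
    (which would make fractional powers undefined downstream): ``"error"``
    lists the offending subjects, ``"clamp"`` raises them to 1e-6,
    ``"ignore"`` leaves them.
    """
    variables = tuple(variables)
    validate_cohort(table, required=variables)
    if params == "fit":
        x = table.loc[:, variables].to_numpy(dtype=float)
        sds = x.std(axis=0, ddof=1)
        if (sds <= 0).any():
            bad = [v for v, s in zip(variables, sds) if s <= 0]
            raise DegenerateVarianceError(f"zero-variance column(s): {bad}")
        params = ScalingParams(variables, x.mean(axis=0), sds, target_center, target_sd)
    elif not isinstance(params, ScalingParams):
        raise SchemaError('params must be a ScalingParams or the string "fit"')
    elif params.variables != variables:
        params = replace(
            params,
            variables=variables,
            source_mean=params.source_mean[[params.variables.index(v) for v in variables]],
            source_sd=params.source_sd[[params.variables.index(v) for v in variables]],
        )

    out = table.copy()
    scaled = params.transform_array(out.loc[:, variables].to_numpy(dtype=float))
    nonpos = scaled <= 0
    if nonpos.any():
        if on_nonpositive == "error":
            rows, cols = np.nonzero(nonpos)
            offenders = [
                (table.index[i], variables[j]) for i, j in zip(rows[:10], cols[:10])
            ]
            raise DomainError(
                "scaled predictor values <= 0 (undefined under fractional powers); "
                f"first offenders (row, variable): {offenders}"
            )
        if on_nonpositive == "clamp":
            scaled = np.where(nonpos, 1e-6, scaled)
        elif on_nonpositive != "ignore":
            raise SchemaError(f"unknown on_nonpositive policy: {on_nonpositive!r}")
    out.loc[:, variables] = scaled
    return out, params


def variance_of_sum(sd_x: float, sd_y: float, rho: float, sign: int = 1) -> float:
    """Variance of x + y (sign=+1) or x - y (sign=-1) from SDs and their correlation.

    var = sd_x**2 + sd_y**2 +/- 2 * rho * sd_x * sd_y
    """
    if sd_x < 0 or sd_y < 0:
        raise DataError("standard deviations must be non-negative")
    if abs(rho) > 1:
        raise DataError("|rho| must be <= 1")
    if sign not in (1, -1):
        raise SchemaError("sign must be +1 or -1")
    return float(sd_x**2 + sd_y**2 + sign * 2.0 * rho * sd_x * sd_y)
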