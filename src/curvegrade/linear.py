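"""Linear regression baselines, from raw data or from a moment summary.

Two equivalent routes produce the same :class:`RegressionResult`:

* :func:`fit_ols` — ordinary least squares on a per-subject table (via
  :mod:`statsmodels`), the route the original analysis took;
* :func:`fit_from_moments` — the normal-equation solution computed purely
  from means, SDs, correlations and n, which makes the published tables
  reproducible from the printed moment summary alone.

Both report unstandardized weights b, standardized weights beta, squared
semi-partial correlations, zero-order validities, R^2, adjusted R^2, and
t-based 95% CIs.  On matched inputs the two routes agree to machine
precision — a core oracle property of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import MomentSummary, compute_moments, validate_cohort
from .errors import CollinearityError, DataError
import warnings

__all__ = [
    "RegressionResult",
    "LinearBaseline",
    "fit_ols",
    "fit_from_moments",
    "adjusted_r2",
    "r2_ci",
]


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1); may be negative."""
    if n <= k + 1:
        raise DataError(f"adjusted R^2 undefined for n={n}, k={k}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass
class RegressionResult:
    """OLS fit summary for one outcome.

    ``b`` are raw-unit weights, ``beta`` standardized weights (SD-ratio
    scaled), ``sr2`` the squared semi-partial correlations (unique
    variance each predictor adds over the others), ``zero_order`` the
    validities r_q.  ``k`` counts non-intercept terms.
    """

    outcome: str
    predictors: tuple[str, ...]
    b: np.ndarray
    b_ci: np.ndarray
    beta: np.ndarray
    beta_ci: np.ndarray
    sr2: np.ndarray
    zero_order: np.ndarray
    r2: float
    adj_r2: float
    n: int
    k: int
    intercept: float
    pvalues: np.ndarray
    r2_pvalue: float
    r2_ci: tuple[float, float] | None = None
    from_moments: bool = False

    def stars(self) -> list[str]:
        """Two-sided significance stars at alpha = .05 / .01 (uncorrected)."""
        return ["**" if p < 0.01 else "*" if p < 0.05 else "" for p in self.pvalues]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "b": self.b,
                "b_ll": self.b_ci[:, 0],
                "b_ul": self.b_ci[:, 1],
                "beta": self.beta,
                "beta_ll": self.beta_ci[:, 0],
                "beta_ul": self.beta_ci[:, 1],
                "sr2": self.sr2,
                "r": self.zero_order,
                "sig": self.stars(),
            },
            index=list(self.predictors),
        )

    def summary(self) -> str:
        lines = [
            f"OLS baseline: {self.outcome} ~ {' + '.join(self.predictors)}"
            + ("  [from moments]" if self.from_moments else ""),
            self.to_frame().round(3).to_string(),
            f"R2 = {self.r2:.3f}   adj R2 = {self.adj_r2:.3f}   "
            f"n = {self.n}   k = {self.k}",
        ]
        if self.r2_ci is not None:
            lines.append(f"R2 95% CI [{self.r2_ci[0]:.3f}, {self.r2_ci[1]:.3f}]")
        return "\n".join(lines)


def _derived_stats(
    r_xx: np.ndarray,
    r_xy: np.ndarray,
    sd_x: np.ndarray,
    sd_y: float,
    n: int,
    level: float = 0.95,
):
    """Standardized solution and inferential stats from correlations alone."""
    k = len(r_xy)
    cond = np.linalg.cond(r_xx)
    if cond > 1e10:
        raise CollinearityError(
            f"predictor correlation matrix is near-singular (cond={cond:.2e})"
        )
    rinv = np.linalg.inv(r_xx)
    beta = rinv @ r_xy
    r2 = float(r_xy @ beta)
    df_resid = n - k - 1
    se_beta = np.sqrt((1.0 - r2) * np.diag(rinv) / df_resid)
    tcrit = stats.t.ppf(0.5 + level / 2, df_resid)
    tvals = np.divide(beta, se_beta, out=np.zeros_like(beta), where=se_beta > 0)
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    b = beta * sd_y / sd_x
    se_b = se_beta * sd_y / sd_x
    sr2 = beta**2 / np.diag(rinv)
    if r2 >= 1.0:
        f_p = 0.0
    else:
        f_stat = (r2 / k) / ((1 - r2) / df_resid)
        f_p = float(stats.f.sf(f_stat, k, df_resid))
    return {
        "beta": beta,
        "beta_ci": np.column_stack([beta - tcrit * se_beta, beta + tcrit * se_beta]),
        "b": b,
        "b_ci": np.column_stack([b - tcrit * se_b, b + tcrit * se_b]),
        "sr2": sr2,
        "r2": r2,
        "adj_r2": adjusted_r2(r2, n, k),
        "pvalues": pvals,
        "r2_pvalue": f_p,
    }


def fit_from_moments(
    moments: MomentSummary, outcome: str, predictors: Sequence[str]
) -> RegressionResult:
    """Reconstruct the OLS solution from a moment summary.

    beta = R_xx^-1 r_xy, R^2 = r_xy' beta, b_q = beta_q sd_y / sd_xq;
    t-based CIs use the n recorded in the moments.
    """
    predictors = tuple(predictors)
    sub = moments.subset((outcome, *predictors))
    r_xy = sub.corr[0, 1:]
    r_xx = sub.corr[1:, 1:]
    d = _derived_stats(r_xx, r_xy, sub.sds[1:], sub.sds[0], moments.n)
    intercept = float(
        sub.means[0] - d["b"] @ sub.means[1:]
    )
    return RegressionResult(
        outcome=outcome,
        predictors=predictors,
        b=d["b"],
        b_ci=d["b_ci"],
        beta=d["beta"],
        beta_ci=d["beta_ci"],
        sr2=d["sr2"],
        zero_order=r_xy,
        r2=d["r2"],
        adj_r2=d["adj_r2"],
        n=moments.n,
        k=len(predictors),
        intercept=intercept,
        pvalues=d["pvalues"],
        r2_pvalue=d["r2_pvalue"],
        from_moments=True,
    )


def fit_ols(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    r2_ci_reps: int = 0,
    seed: int = 0,
) -> RegressionResult:
    """OLS on raw data (statsmodels backend) with standardized statistics.

    With ``r2_ci_reps`` > 0 a nonparametric bootstrap percentile interval
    for R^2 is attached (see :func:`r2_ci`).
    """
    predictors = tuple(predictors)
    validate_cohort(data, required=(outcome, *predictors))
    n = len(data)
    k = len(predictors)
    if n <= k + 1:
        raise DataError(f"need n > k+1 (n={n}, k={k})")
    y = data[outcome].to_numpy(dtype=float)
    x = data.loc[:, predictors].to_numpy(dtype=float)
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(
            f"design is rank deficient for predictors {predictors}"
        )
    fit = sm.OLS(y, design).fit()
    sd_x = x.std(axis=0, ddof=1)
    sd_y = y.std(ddof=1)
    b = fit.params[1:]
    b_ci = fit.conf_int()[1:]
    beta = b * sd_x / sd_y
    beta_ci = b_ci * (sd_x / sd_y)[:, None]
    r_xx = np.corrcoef(x, rowvar=False) if k > 1 else np.ones((1, 1))
    rinv = np.linalg.inv(r_xx)
    sr2 = beta**2 / np.diag(rinv)
    zero_order = np.array([stats.pearsonr(x[:, j], y)[0] for j in range(k)])
    result = RegressionResult(
        outcome=outcome,
        predictors=predictors,
        b=b,
        b_ci=b_ci,
        beta=beta,
        beta_ci=beta_ci,
        sr2=sr2,
        zero_order=zero_order,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=n,
        k=k,
        intercept=float(fit.params[0]),
        pvalues=fit.pvalues[1:],
        r2_pvalue=float(fit.f_pvalue),
        from_moments=False,
    )
    if r2_ci_reps:
        result.r2_ci = r2_ci(data, outcome, predictors, reps=r2_ci_reps, seed=seed)
    return result


def r2_ci(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    level: float = 0.95,
    reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Nonparametric bootstrap percentile CI for R^2 (case resampling).

    Deterministic given ``seed``.  The original tables' CI method was not
    described; the bootstrap is used here as a transparent, testable
    substitute and is not expected to match those printed intervals.
    """
    if reps < 200:
        warnings.warn(f"r2_ci with reps={reps} < 200 is imprecise", stacklevel=2)
    predictors = tuple(predictors)
    y = data[outcome].to_numpy(dtype=float)
    x = data.loc[:, predictors].to_numpy(dtype=float)
    n = len(y)
    design = sm.add_constant(x, has_constant="add")
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        db = design[idx]
        coef, _, rank, _ = np.linalg.lstsq(db, yb, rcond=None)
        resid = yb - db @ coef
        tss = ((yb - yb.mean()) ** 2).sum()
        vals[r] = 1.0 - resid @ resid / tss if tss > 0 else 1.0
    alpha = 1 - level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


class LinearBaseline:
    """Model-object wrapper around the two fitting routes.

    ``LinearBaseline.from_dataframe(df, outcome, predictors).fit()`` uses
    least squares on the rows; ``LinearBaseline.from_moments(...)`` uses
    the printed-summary route.  Both return :class:`RegressionResult`.
    """

    def __init__(self, outcome: str, predictors: Sequence[str]) -> None:
        self.outcome = outcome
        self.predictors = tuple(predictors)
        self._data: pd.DataFrame | None = None
        self._moments: MomentSummary | None = None

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str, predictors: Sequence[str]
    ) -> "LinearBaseline":
        m = cls(outcome, predictors)
        m._data = data
        return m

    @classmethod
    def from_moments(
        cls, moments: MomentSummary, outcome: str, predictors: Sequence[str]
    ) -> "LinearBaseline":
        m = cls(outcome, predictors)
        m._moments = moments
        return m

    def fit(self, r2_ci_reps: int = 0, seed: int = 0) -> RegressionResult:
        if self._data is not None:
            return fit_ols(
                self._data, self.outcome, self.predictors, r2_ci_reps, seed
            )
        if self._moments is not None:
            return fit_from_moments(self._moments, self.outcome, self.predictors)
        raise DataError("no data source; use from_dataframe or from_moments")
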