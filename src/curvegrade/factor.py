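"""One-factor principal axis factoring and regression factor scores.

The g score used throughout the pipeline is the first unrotated factor of
the three ability tests, extracted by iterated principal axis factoring
(PAF): starting from squared multiple correlations as communality
estimates, the correlation-matrix diagonal is repeatedly replaced by the
current communalities and the leading eigenpair re-extracted until the
communalities stabilise.  Factor scores are regression (Thurstone)
estimates, w = R^-1 lambda applied to z-scored tests; their model-implied
SD is sqrt(lambda' R^-1 lambda), which is below 1 because regression
scores shrink toward the mean.

For exactly three indicators the one-factor model is exactly identified
and converged PAF loadings coincide with the closed-form triad solution
lambda_1 = sqrt(r12 * r13 / r23) (and permutations) whenever all three
correlations are positive — the independent oracle used by the tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MomentSummary
from .errors import MatrixError, NumericError

__all__ = [
    "FactorResults",
    "PrincipalAxisFactor",
    "paf_one_factor",
    "factor_scores",
    "triad_loadings",
]


@dataclass
class FactorResults:
    """Converged one-factor PAF solution.

    Attributes
    ----------
    loadings : per-test lambda_q on the first unrotated factor
    communalities : h2_q = lambda_q**2
    eigenvalue : sum of squared loadings
    variance_proportion : eigenvalue / number of tests
    score_weights : regression-score weights w = R^-1 lambda
    score_sd : model-implied SD of the regression scores, sqrt(lambda' w)
    """

    variable_names: tuple[str, ...]
    loadings: np.ndarray
    communalities: np.ndarray
    eigenvalue: float
    variance_proportion: float
    score_weights: np.ndarray
    score_sd: float
    iterations: int
    converged: bool
    heywood: bool
    corr: np.ndarray

    def scores(self, tests: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Regression factor scores for a table of raw test scores."""
        return factor_scores(self, tests, self.corr)

    def implied_test_correlations(self) -> np.ndarray:
        """Model-implied correlation of the factor score with each test."""
        return self.loadings / self.score_sd

    def summary(self) -> str:
        rows = pd.DataFrame(
            {
                "loading": self.loadings,
                "communality": self.communalities,
                "score_weight": self.score_weights,
            },
            index=list(self.variable_names),
        )
        lines = [
            "One-factor principal axis solution",
            rows.round(4).to_string(),
            f"eigenvalue            {self.eigenvalue:.4f}",
            f"variance proportion   {self.variance_proportion:.4f}",
            f"implied score SD      {self.score_sd:.4f}",
            f"iterations            {self.iterations} "
            f"({'converged' if self.converged else 'NOT converged'})",
        ]
        if self.heywood:
            lines.append("warning: Heywood case, communality clamped at 1")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variable_names),
            "loadings": self.loadings.tolist(),
            "communalities": self.communalities.tolist(),
            "eigenvalue": self.eigenvalue,
            "variance_proportion": self.variance_proportion,
            "score_weights": self.score_weights.tolist(),
            "score_sd": self.score_sd,
            "iterations": self.iterations,
            "converged": self.converged,
            "heywood": self.heywood,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


class PrincipalAxisFactor:
    """One-factor PAF model for a correlation matrix.

    Parameters
    ----------
    corr
        Either a :class:`MomentSummary` or a plain correlation matrix.
    variable_names
        Labels when ``corr`` is a plain matrix.
    """

    def __init__(
        self,
        corr: MomentSummary | np.ndarray,
        variable_names: Sequence[str] | None = None,
    ) -> None:
        if isinstance(corr, MomentSummary):
            self.corr = np.asarray(corr.corr, dtype=float)
            self.variable_names = corr.variable_names
        else:
            self.corr = np.asarray(corr, dtype=float)
            p = self.corr.shape[0]
            self.variable_names = (
                tuple(variable_names)
                if variable_names is not None
                else tuple(f"x{i + 1}" for i in range(p))
            )
        p = self.corr.shape[0]
        if self.corr.shape != (p, p) or p < 3:
            raise MatrixError("PAF requires a square correlation matrix, >= 3 variables")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise MatrixError("correlation matrix must be symmetric")

    def fit(self, tol: float = 1e-10, max_iter: int = 10000) -> FactorResults:
        """Iterated PAF: communalities start at squared multiple correlations.

        The tight default tolerance (max communality change < 1e-10) makes
        converged 3-variable loadings agree with the exact triad solution
        to well under 1e-6.  Convergence is linear and can be slow for weak
        correlation structures, hence the generous iteration cap; each
        iteration is a single small eigendecomposition.
        """
        r = self.corr.copy()
        p = r.shape[0]
        try:
            rinv = np.linalg.inv(r)
        except np.linalg.LinAlgError as exc:
            raise MatrixError("correlation matrix is singular") from exc
        h2 = 1.0 - 1.0 / np.diag(rinv)  # SMC start
        heywood = False
        converged = False
        loadings = np.zeros(p)
        it = 0
        for it in range(1, max_iter + 1):
            work = r.copy()
            np.fill_diagonal(work, h2)
            w, v = np.linalg.eigh(work)
            if not np.isfinite(w).all():
                raise NumericError(f"eigendecomposition failed at iteration {it}")
            lead = w[-1]
            vec = v[:, -1]
            if lead < 0:
                lead = 0.0
            loadings = np.sqrt(lead) * vec
            if loadings.sum() < 0:  # sign fixed so the factor is positively keyed
                loadings = -loadings
            h2_new = loadings**2
            if (h2_new > 1).any():
                heywood = True
                h2_new = np.minimum(h2_new, 1.0)
            delta = np.abs(h2_new - h2).max()
            h2 = h2_new
            if delta < tol:
                converged = True
                break
        if heywood:
            warnings.warn("Heywood case: communality clamped at 1", stacklevel=2)
        eigenvalue = float((loadings**2).sum())
        weights = np.linalg.solve(r, loadings)
        score_var = float(loadings @ weights)
        if score_var < 0:
            raise NumericError("negative implied score variance")
        return FactorResults(
            variable_names=self.variable_names,
            loadings=loadings,
            communalities=h2,
            eigenvalue=eigenvalue,
            variance_proportion=eigenvalue / p,
            score_weights=weights,
            score_sd=float(np.sqrt(score_var)),
            iterations=it,
            converged=converged,
            heywood=heywood,
            corr=r,
        )


def paf_one_factor(
    corr: MomentSummary | np.ndarray,
    variable_names: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> FactorResults:
    """Functional shorthand for ``PrincipalAxisFactor(corr).fit()``."""
    return PrincipalAxisFactor(corr, variable_names).fit(tol=tol, max_iter=max_iter)


def factor_scores(
    solution: FactorResults,
    tests: pd.DataFrame | np.ndarray,
    corr: np.ndarray | None = None,
) -> np.ndarray:
    """Regression (Thurstone) factor scores.

    Tests are z-scored internally (sample mean, n-1 SD), so the scores are
    invariant to any affine rescaling of the raw tests and have mean 0 by
    construction.
    """
    if isinstance(tests, pd.DataFrame):
        x = tests.loc[:, list(solution.variable_names)].to_numpy(dtype=float)
    else:
        x = np.asarray(tests, dtype=float)
    r = solution.corr if corr is None else np.asarray(corr, dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise MatrixError("zero-variance test column; cannot standardize")
    z = (x - x.mean(axis=0)) / sd
    try:
        w = np.linalg.solve(r, solution.loadings)
    except np.linalg.LinAlgError as exc:
        raise MatrixError("singular correlation matrix in score weights") from exc
    return z @ w


def triad_loadings(corr: np.ndarray) -> np.ndarray:
    """Closed-form one-factor loadings for exactly three variables.

    lambda_1 = sqrt(r12 * r13 / r23) and permutations; defined when all
    three pairwise correlations are positive.  Exact for the
    exactly-identified 3-variable case; used as an independent oracle.
    """
    r = np.asarray(corr, dtype=float)
    if r.shape != (3, 3):
        raise MatrixError("triad formula requires a 3x3 matrix")
    r12, r13, r23 = r[0, 1], r[0, 2], r[1, 2]
    if min(r12, r13, r23) <= 0:
        raise NumericError("triad formula requires all positive correlations")
    return np.array(
        [
            np.sqrt(r12 * r13 / r23),
            np.sqrt(r12 * r23 / r13),
            np.sqrt(r13 * r23 / r12),
        ]
    )
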