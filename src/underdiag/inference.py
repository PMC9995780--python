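"""Single-variant logistic regression and the Wald test that defines power.

The association model refit to each simulated replicate is the same logistic
model the data were generated from, ``logit(Pr(Y=1)) = b0 + g*b1``, estimated
by maximum likelihood (delegated to statsmodels). Power is the fraction of
replicates whose two-sided Wald p-value for the slope falls strictly below the
significance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (
    DegenerateOutcomeError,
    DegeneratePredictorError,
    InvalidInputError,
)

__all__ = ["FitResult", "fit_logistic", "wald_test"]


@dataclass(frozen=True)
class FitResult:
    """Estimates from one logistic fit of outcome on allele count.

    When ``converged`` is False the point estimates are unusable (NaN) and the
    fit counts as non-significant in any power calculation.
    """

    beta0_hat: float
    betag_hat: float
    se_betag: float
    pvalue: float
    converged: bool
    n_cases: int


def fit_logistic(genotype: np.ndarray, outcome: np.ndarray) -> FitResult:
    """ML fit of ``outcome ~ 1 + genotype`` with a Wald p-value for the slope.

    Raises
    ------
    DegenerateOutcomeError
        If the outcome is constant (all 0 or all 1) — no likelihood to fit.
    DegeneratePredictorError
        If the genotype vector is constant — the slope is unidentifiable.
    """
    genotype = np.asarray(genotype, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if genotype.shape != outcome.shape:
        raise InvalidInputError("genotype and outcome must have equal length")
    n_cases = int(outcome.sum())
    if n_cases == 0 or n_cases == len(outcome):
        raise DegenerateOutcomeError(
            "outcome must contain at least one case and one control"
        )
    if np.all(genotype == genotype[0]):
        raise DegeneratePredictorError("constant genotype: slope unidentifiable")

    X = sm.add_constant(genotype)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings handled via flag
            res = sm.Logit(outcome, X).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        converged = False
        res = None

    if not converged or res is None or not np.isfinite(res.bse[1]):
        return FitResult(np.nan, np.nan, np.nan, np.nan, False, n_cases)
    return FitResult(
        beta0_hat=float(res.params[0]),
        betag_hat=float(res.params[1]),
        se_betag=float(res.bse[1]),
        pvalue=float(res.pvalues[1]),
        converged=True,
        n_cases=n_cases,
    )


def wald_test(
    betag_hat: float, se_betag: float, alpha: float = 0.05
) -> tuple[bool, float]:
    """Two-sided Wald test of the slope; significant iff ``pvalue < alpha``.

    Returns ``(significant, pvalue)`` with ``pvalue = 2*(1 - Phi(|z|))`` for
    ``z = betag_hat / se_betag``. The level boundary is resolved by the strict
    inequality.
    """
    if not se_betag > 0:
        raise InvalidInputError(f"se_betag must be > 0, got {se_betag}")
    z = betag_hat / se_betag
    pvalue = 2.0 * norm.sf(abs(z))
    return bool(pvalue < alpha), float(pvalue)
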