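"""Deterministic counterparts of the simulation.

Three small pieces of closed-form algebra plus one numeric oracle:

* ``expected_prevalence`` — the marginal disease prevalence implied by the
  logistic penetrance model, averaging over the three genotype strata.
* ``observed_prevalence`` / ``misclassification_rate`` — the one-sided
  thinning identity ``observed = (1 - pi) * true`` and its inverse
  ``pi = 1 - observed/true``, which is how an underdiagnosis rate is read off
  a biobank's recorded prevalence given an assumed population prevalence.
* ``attenuated_coefficients`` — the large-sample limit of the logistic MLE
  fitted to the *misclassified* outcome: the unique maximizer of the expected
  (population-averaged) log-likelihood over the genotype strata. This is the
  deterministic surface against which the stochastic simulation means are
  checked; it quantifies attenuation toward the null without Monte Carlo.

The expected log-likelihood being maximized is

    L(b0, b1) = sum_g P(g) [ q_g log p_g(b) + (1 - q_g) log(1 - p_g(b)) ],

with ``P(g)`` the Binomial(2, maf) genotype pmf, ``q_g = (1-pi) *
expit(beta0 + betag*g)`` the probability of an *observed* case in stratum g,
and ``p_g(b) = expit(b0 + b1*g)`` the working model. Its maximizer solves the
two expected score equations; we solve them by Newton iteration with the
analytic gradient and Hessian (the Hessian is the negative of a weighted
logistic information matrix, so it is negative definite whenever 0 < q_g < 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import binom

from .cohort import Scenario
from .errors import (
    InconsistentPrevalenceError,
    InvalidParameterError,
    UndefinedRateError,
)

__all__ = [
    "PrevalencePair",
    "AttenuationResult",
    "expected_prevalence",
    "expected_logistic_fit",
    "misclassification_rate",
    "observed_prevalence",
    "attenuated_coefficients",
]

_GENOTYPES = np.array([0.0, 1.0, 2.0])


@dataclass(frozen=True)
class PrevalencePair:
    """True and observed (recorded) disease prevalence in a population."""

    true_prevalence: float
    observed_prevalence: float

    def __post_init__(self) -> None:
        t, o = self.true_prevalence, self.observed_prevalence
        if not (0.0 <= t <= 1.0 and 0.0 <= o <= 1.0):
            raise InvalidParameterError("prevalences must lie in [0, 1]")


@dataclass(frozen=True)
class AttenuationResult:
    """Large-sample limit of the misclassified-data logistic MLE.

    ``degenerate`` is True when pi = 1 (no observed cases remain): the slope
    limit is then undefined and both starred values are NaN.
    """

    beta0_star: float
    betag_star: float
    degenerate: bool = False


def _genotype_pmf(maf: float) -> np.ndarray:
    if not 0.0 <= maf <= 1.0:
        raise InvalidParameterError(f"maf must be in [0, 1], got {maf}")
    return binom.pmf(_GENOTYPES, 2, maf)


def expected_prevalence(beta0: float, betag: float, maf: float) -> float:
    """Marginal prevalence: E_g[ expit(beta0 + betag*g) ], g ~ Binomial(2, maf)."""
    w = _genotype_pmf(maf)
    return float(np.sum(w * expit(beta0 + betag * _GENOTYPES)))


def misclassification_rate(pair: PrevalencePair) -> float:
    """Implied underdiagnosis rate ``1 - observed/true`` for a prevalence pair."""
    if pair.true_prevalence == 0.0:
        raise UndefinedRateError("misclassification rate undefined at zero prevalence")
    if pair.observed_prevalence > pair.true_prevalence:
        raise InconsistentPrevalenceError(
            "observed prevalence exceeds true prevalence: inconsistent with "
            "case-only misclassification"
        )
    return 1.0 - pair.observed_prevalence / pair.true_prevalence

def observed_prevalence(true_prevalence: float, pi: float) -> float:
    """Recorded prevalence after thinning cases at rate ``pi``."""
    if not (0.0 <= true_prevalence <= 1.0 and 0.0 <= pi <= 1.0):
        raise InvalidParameterError("inputs must lie in [0, 1]")
    return true_prevalence * (1.0 - pi)


def expected_logistic_fit(
    x: np.ndarray,
    weights: np.ndarray,
    q: np.ndarray,
    start: tuple[float, float],
    tol: float = 1e-12,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Maximizer of a weighted expected Bernoulli log-likelihood.

    Solves the expected score equations ``sum_j w_j (q_j - expit(b0+b1 x_j))
    (1, x_j) = 0`` by Newton iteration with the analytic Hessian. This is the
    population (infinite-sample) analogue of a logistic fit to grouped data
    with stratum frequencies ``weights`` and per-stratum success
    probabilities ``q``.
    """
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    w = np.asarray(weights, dtype=float)
    q = np.asarray(q, dtype=float)
    b = np.array(start, dtype=float)
    for _ in range(max_iter):
        p = expit(X @ b)
        grad = X.T @ (w * (q - p))
        if np.linalg.norm(grad) < tol:
            break
        H = -(X.T * (w * p * (1.0 - p))) @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            # singular Hessian (degenerate strata): damped gradient fallback
            step = -grad
        b = b - step
    else:
        if np.linalg.norm(X.T @ (w * (q - expit(X @ b)))) >= 1e-10:
            raise RuntimeError("expected-score Newton solver did not converge")
    return float(b[0]), float(b[1])


def attenuated_coefficients(scenario: Scenario) -> AttenuationResult:
    """Asymptotic (b0*, b1*) of the logistic fit to the misclassified outcome.

    Newton iterations on the expected log-likelihood, started at the true
    parameters, run until the gradient norm falls below 1e-12 (well under the
    1e-10 the package guarantees). At pi = 0 the model is correctly specified
    and (beta0, betag) are recovered; for pi in (0, 1) the slope is strictly
    attenuated toward, never past, the null.
    """
    if scenario.pi == 1.0:
        return AttenuationResult(np.nan, np.nan, degenerate=True)
    w = _genotype_pmf(scenario.maf)
    q = (1.0 - scenario.pi) * expit(scenario.beta0 + scenario.betag * _GENOTYPES)
    b0, b1 = expected_logistic_fit(
        _GENOTYPES, w, q, start=(scenario.beta0, scenario.betag)
    )
    return AttenuationResult(b0, b1, degenerate=False)
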