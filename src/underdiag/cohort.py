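"""Synthetic single-variant cohorts with underdiagnosis-style misclassification.

The generative model is the one the simulation study assumes throughout:

* genotype dosage ``g ~ Binomial(2, maf)`` (Hardy-Weinberg, biallelic variant);
* true disease status ``D ~ Bernoulli(expit(beta0 + g * betag))`` — a logistic
  penetrance model in allele count;
* observed status: each true case is *retained* as an observed case with
  probability ``1 - pi`` and otherwise recorded as a control; true controls are
  never mislabelled. ``pi`` is the misclassification (underdiagnosis) rate.

Misclassification is therefore one-sided binomial thinning of the cases: the
observed-status vector is elementwise <= the true-status vector, and false
positives are structurally impossible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "Scenario",
    "Cohort",
    "MisclassTable",
    "simulate_genotypes",
    "disease_probability",
    "simulate_true_status",
    "apply_misclassification",
    "simulate_cohort",
    "tabulate",
]


@dataclass(frozen=True)
class Scenario:
    """One point of the simulation grid.

    Parameters
    ----------
    beta0 : float
        Log-odds intercept of the penetrance model. Governs baseline disease
        prevalence (e.g. -1.5 / -1.0 / -0.5 give ~19% / 28% / 39% prevalence
        at ``betag=0.1, maf=0.3``).
    betag : float
        Per-allele log odds ratio of the variant.
    maf : float
        Allele frequency in [0, 1]; genotype is Binomial(2, maf).
    pi : float
        Misclassification rate in [0, 1]: the probability that a true case is
        recorded as a control.
    n : int
        Cohort size per replicate.
    reps : int
        Number of simulation replicates.
    seed : int
        Root RNG seed; per-replicate streams are spawned from it.
    """

    beta0: float
    betag: float
    maf: float
    pi: float
    n: int = 20_000
    reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise InvalidParameterError(f"maf must be in [0, 1], got {self.maf}")
        if not 0.0 <= self.pi <= 1.0:
            raise InvalidParameterError(f"pi must be in [0, 1], got {self.pi}")
        if self.n < 1:
            raise InvalidParameterError(f"n must be >= 1, got {self.n}")
        if self.reps < 1:
            raise InvalidParameterError(f"reps must be >= 1, got {self.reps}")

    def replicate_rngs(self) -> list[np.random.Generator]:
        """Independent per-replicate generators spawned from the root seed.

        Spawning makes replicates statistically independent and the study
        reproducible regardless of execution order.
        """
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(child) for child in ss.spawn(self.reps)]


@dataclass(frozen=True)
class Cohort:
    """Genotype plus true/observed status for one simulated replicate."""

    genotype: np.ndarray
    true_status: np.ndarray
    observed_status: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genotype)
        if len(self.true_status) != n or len(self.observed_status) != n:
            raise InvalidInputError("cohort vectors must have equal length")
        if np.any(self.observed_status > self.true_status):
            raise InvalidInputError(
                "observed_status must be <= true_status elementwise "
                "(case-only misclassification)"
            )

    def __len__(self) -> int:
        return len(self.genotype)

    def to_frame(self) -> pd.DataFrame:
        """Three-column table (genotype, true_status, observed_status)."""
        return pd.DataFrame(
            {
                "genotype": self.genotype,
                "true_status": self.true_status,
                "observed_status": self.observed_status,
            }
        )


@dataclass(frozen=True)
class MisclassTable:
    """2x2 cross-tabulation of true vs observed status.

    ``n11``: true cases observed as cases; ``n10``: true cases observed as
    controls (the underdiagnosed); ``n01``: false positives (structurally zero
    under the thinning mechanism, carried for generality); ``n00``: true
    controls observed as controls.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    @property
    def n1s(self) -> int:
        """Number of true cases (row margin)."""
        return self.n11 + self.n10

    @property
    def n0s(self) -> int:
        """Number of true controls (row margin)."""
        return self.n01 + self.n00

    @property
    def n(self) -> int:
        return self.n1s + self.n0s

    @property
    def pi_hat(self) -> float:
        """Empirical misclassification rate n10 / n1s (requires n1s > 0)."""
        if self.n1s == 0:
            from .errors import UndefinedRateError

            raise UndefinedRateError("no true cases: pi_hat is undefined")
        return self.n10 / self.n1s


def simulate_genotypes(
    n: int, maf: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. allele counts from Binomial(2, maf)."""
    if not 0.0 <= maf <= 1.0:
        raise InvalidParameterError(f"maf must be in [0, 1], got {maf}")
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    return rng.binomial(2, maf, size=n).astype(np.int64)


def disease_probability(
    genotype: np.ndarray, beta0: float, betag: float
) -> np.ndarray:
    """Penetrance ``expit(beta0 + genotype * betag)`` per individual."""
    genotype = np.asarray(genotype)
    if not np.isin(genotype, (0, 1, 2)).all():
        raise InvalidInputError("genotype entries must be in {0, 1, 2}")
    return expit(beta0 + genotype * betag)


def simulate_true_status(
    prob: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli draws of true disease status."""
    prob = np.asarray(prob, dtype=float)
    if np.any(prob < 0.0) or np.any(prob > 1.0):
        raise InvalidParameterError("probabilities must lie in [0, 1]")
    return (rng.random(prob.shape) < prob).astype(np.int64)


def apply_misclassification(
    true_status: np.ndarray, pi: float, rng: np.random.Generator
) -> np.ndarray:
    """Thin the cases: each true case stays an observed case w.p. ``1 - pi``.

    One uniform draw is made per individual and a case is retained iff its
    draw is >= ``pi``. Holding the RNG stream fixed, raising ``pi`` can only
    drop further cases, never resurrect one — a monotone coupling across
    misclassification rates.
    """
    if not 0.0 <= pi <= 1.0:
        raise InvalidParameterError(f"pi must be in [0, 1], got {pi}")
    true_status = np.asarray(true_status)
    u = rng.random(true_status.shape)
    return (true_status * (u >= pi)).astype(np.int64)


def simulate_cohort(scenario: Scenario, rng: np.random.Generator) -> Cohort:
    """Generate one full replicate under ``scenario`` using ``rng``."""
    g = simulate_genotypes(scenario.n, scenario.maf, rng)
    p = disease_probability(g, scenario.beta0, scenario.betag)
    d = simulate_true_status(p, rng)
    obs = apply_misclassification(d, scenario.pi, rng)
    return Cohort(genotype=g, true_status=d, observed_status=obs)


def tabulate(true_status: np.ndarray, observed_status: np.ndarray) -> MisclassTable:
    """Exact 2x2 cross-tabulation of true against observed status."""
    true_status = np.asarray(true_status)
    observed_status = np.asarray(observed_status)
    if true_status.shape != observed_status.shape:
        raise InvalidInputError("status vectors must have equal length")
    t = true_status.astype(bool)
    o = observed_status.astype(bool)
    return MisclassTable(
        n11=int(np.sum(t & o)),
        n10=int(np.sum(t & ~o)),
        n01=int(np.sum(~t & o)),
        n00=int(np.sum(~t & ~o)),
    )
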