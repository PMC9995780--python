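"""Synthetic-cohort generator: genotype law, penetrance, case-only thinning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from underdiag import (
    Cohort,
    Scenario,
    apply_misclassification,
    disease_probability,
    simulate_cohort,
    simulate_genotypes,
    simulate_true_status,
    tabulate,
)
from underdiag.errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedRateError,
)


class TestSimulateGenotypes:
    def test_zero_maf_gives_all_zero(self, rng):
        assert not simulate_genotypes(2000, 0.0, rng).any()

    def test_allele_count_distribution_matches_binomial(self, rng):
        # Binomial(2, 0.3) pmf: (0.49, 0.42, 0.09); mean dosage 0.6
        g = simulate_genotypes(100_000, 0.3, rng)
        props = np.bincount(g, minlength=3) / len(g)
        expected = np.array([0.49, 0.42, 0.09])
        se = np.sqrt(expected * (1 - expected) / len(g))
        assert np.all(np.abs(props - expected) < 3 * se)
        assert abs(g.mean() - 0.6) < 3 * np.sqrt(2 * 0.3 * 0.7 / len(g))

    @pytest.mark.parametrize("maf", [-0.01, 1.5])
    def test_invalid_maf_rejected(self, rng, maf):
        with pytest.raises(InvalidParameterError):
            simulate_genotypes(10, maf, rng)


class TestDiseaseProbability:
    @pytest.mark.parametrize(
        ("g", "beta0", "betag", "expected"),
        [
            # 1 / (1 + e^1.5)
            (0, -1.5, 0.1, 0.18242552380635635),
            # 1 / (1 + e), slope zero so genotype-independent
            (2, -1.0, 0.0, 0.2689414213699951),
            (1, 0.0, 0.0, 0.5),
        ],
    )
    def test_pointwise_values(self, g, beta0, betag, expected):
        p = disease_probability(np.array([g]), beta0, betag)
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_values_strictly_inside_unit_interval(self):
        g = np.array([0, 1, 2])
        p = disease_probability(g, -30.0, 0.1)
        assert np.all((p > 0) & (p < 1))

    def test_rejects_non_dosage_genotype(self):
        with pytest.raises(InvalidInputError):
            disease_probability(np.array([0, 3]), -1.0, 0.1)


class TestSimulateTrueStatus:
    def test_degenerate_probabilities(self, rng):
        assert not simulate_true_status(np.zeros(500), rng).any()
        assert simulate_true_status(np.ones(500), rng).all()

    def test_case_fraction_matches_marginal_prevalence(self, rng):
        # sum_g P(g) expit(-1.5 + 0.1 g) = 0.191746...
        n = 100_000
        g = simulate_genotypes(n, 0.3, rng)
        d = simulate_true_status(disease_probability(g, -1.5, 0.1), rng)
        prev = 0.19174612499668
        assert abs(d.mean() - prev) < 3 * np.sqrt(prev * (1 - prev) / n)

    def test_rejects_invalid_probability(self, rng):
        with pytest.raises(InvalidParameterError):
            simulate_true_status(np.array([0.5, 1.2]), rng)


class TestApplyMisclassification:
    def test_pi_zero_is_identity(self, rng):
        d = (rng.random(1000) < 0.3).astype(np.int64)
        assert np.array_equal(apply_misclassification(d, 0.0, rng), d)

    def test_pi_one_removes_every_case(self, rng):
        d = np.ones(1000, dtype=np.int64)
        assert not apply_misclassification(d, 1.0, rng).any()

    def test_controls_never_become_cases(self, rng):
        d = (rng.random(5000) < 0.4).astype(np.int64)
        obs = apply_misclassification(d, 0.6, rng)
        assert np.all(obs <= d)

    def test_observed_prevalence_finngen_example(self, rng):
        # true prevalence 25%, pi = 0.68 -> recorded prevalence about 8%
        n = 200_000
        d = (rng.random(n) < 0.25).astype(np.int64)
        obs = apply_misclassification(d, 0.68, rng)
        assert abs(obs.mean() - 0.08) < 3 * np.sqrt(0.08 * 0.92 / n)

    def test_monotone_coupling_in_pi(self):
        # same stream: raising pi can drop observed cases but never add any
        d = np.ones(20_000, dtype=np.int64)
        observed = {
            pi: apply_misclassification(d, pi, np.random.default_rng(7))
            for pi in (0.2, 0.4, 0.6, 0.8)
        }
        for lo, hi in [(0.2, 0.4), (0.4, 0.6), (0.6, 0.8)]:
            assert np.all(observed[hi] <= observed[lo])

    def test_rejects_invalid_rate(self, rng):
        with pytest.raises(InvalidParameterError):
            apply_misclassification(np.array([1, 0]), 1.5, rng)


class TestTabulate:
    def test_direct_counts(self):
        t = tabulate(np.array([1, 1, 0, 0]), np.array([1, 0, 0, 0]))
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 1, 0, 2)
        assert (t.n1s, t.n0s, t.n) == (2, 2, 4)
        assert t.pi_hat == 0.5

    def test_identical_vectors_have_no_discordance(self):
        d = np.array([1, 0, 1, 1, 0])
        t = tabulate(d, d)
        assert t.n10 == t.n01 == 0
        assert t.pi_hat == 0.0

    def test_empirical_rate_recovers_pi(self, rng):
        d = np.ones(1_000_000, dtype=np.int64)
        obs = apply_misclassification(d, 0.4, rng)
        t = tabulate(d, obs)
        assert t.n11 + t.n10 == len(d)  # thinning conserves true cases
        assert abs(t.pi_hat - 0.4) < 3 * np.sqrt(0.4 * 0.6 / len(d))

    def test_rejects_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            tabulate(np.array([1, 0]), np.array([1]))

    def test_rate_undefined_without_true_cases(self):
        with pytest.raises(UndefinedRateError):
            _ = tabulate(np.zeros(4), np.zeros(4)).pi_hat


class TestCohort:
    def test_simulation_is_bit_reproducible(self):
        sc = Scenario(beta0=-1.0, betag=0.1, maf=0.3, pi=0.6, n=3000, reps=2, seed=11)
        a = simulate_cohort(sc, sc.replicate_rngs()[0])
        b = simulate_cohort(sc, sc.replicate_rngs()[0])
        assert np.array_equal(a.genotype, b.genotype)
        assert np.array_equal(a.true_status, b.true_status)
        assert np.array_equal(a.observed_status, b.observed_status)

    def test_replicate_streams_differ(self):
        sc = Scenario(beta0=-1.0, betag=0.1, maf=0.3, pi=0.6, n=3000, reps=2, seed=11)
        rngs = sc.replicate_rngs()
        a = simulate_cohort(sc, rngs[0])
        b = simulate_cohort(sc, rngs[1])
        assert not np.array_equal(a.true_status, b.true_status)

    def test_rejects_false_positives(self):
        with pytest.raises(InvalidInputError):
            Cohort(np.array([0, 1]), np.array([0, 1]), np.array([1, 1]))

    def test_frame_export_round_trips(self, rng, tmp_path):
        sc = Scenario(beta0=-1.0, betag=0.1, maf=0.3, pi=0.6, n=500, reps=1, seed=3)
        cohort = simulate_cohort(sc, rng)
        path = tmp_path / "cohort.csv"
        cohort.to_frame().to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns) == ["genotype", "true_status", "observed_status"]
        assert np.array_equal(back["observed_status"].to_numpy(), cohort.observed_status)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf": 1.2}, {"pi": -0.1}, {"n": 0}, {"reps": 0},
        ],
    )
    def test_scenario_validation(self, kwargs):
        base = dict(beta0=-1.0, betag=0.1, maf=0.3, pi=0.5, n=100, reps=10, seed=0)
        with pytest.raises(InvalidParameterError):
            Scenario(**{**base, **kwargs})


@settings(derandomize=True, max_examples=30)
@given(
    pi=st.floats(0.0, 1.0),
    maf=st.floats(0.0, 1.0),
    seed=st.integers(0, 2**31 - 1),
)
def test_thinning_invariants_hold_for_any_parameters(pi, maf, seed):
    """One-sided thinning: observed <= true and true-case count is conserved."""
    rng = np.random.default_rng(seed)
    g = simulate_genotypes(300, maf, rng)
    d = simulate_true_status(disease_probability(g, -1.0, 0.1), rng)
    obs = apply_misclassification(d, pi, rng)
    assert np.all(obs <= d)
    t = tabulate(d, obs)
    assert t.n11 + t.n10 == int(d.sum())
    assert t.n01 == 0
    assert t.n == 300
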