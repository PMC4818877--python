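"""The beta-binomial error model and cross-sample log-likelihood score."""

import math

import numpy as np
import pytest
from scipy.stats import betabinom as scipy_betabinom
from scipy.stats import binom as scipy_binom

from barclean import (
    CleanupParams,
    betabinom_log_density,
    expected_daughter_reads,
    loglik_score,
    score_threshold,
    shape_from_mu_rho,
)
from barclean.model import LOG_DENSITY_FLOOR


class TestShapeParameterization:
    @pytest.mark.parametrize(
        "mu, rho, alpha, beta",
        [
            (0.5, 1 / 3, 1.0, 1.0),
            (0.001, 0.0001, 9.999, 9989.001),
            (0.05, 0.005, 9.95, 189.05),
        ],
    )
    def test_closed_form_inversion(self, mu, rho, alpha, beta):
        shape = shape_from_mu_rho(mu, rho)
        assert shape.alpha == pytest.approx(alpha, rel=1e-12)
        assert shape.beta == pytest.approx(beta, rel=1e-12)
        assert shape.alpha + shape.beta == pytest.approx(1 / rho - 1, rel=1e-12)

    def test_round_trips_on_grid(self):
        for mu in np.linspace(0.01, 0.99, 9):
            for rho in np.logspace(-5, -0.1, 8):
                shape = shape_from_mu_rho(mu, rho)
                assert shape.mu == pytest.approx(mu, rel=1e-10)
                assert shape.rho == pytest.approx(rho, rel=1e-10)

    @pytest.mark.parametrize("mu, rho", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)])
    def test_rejects_degenerate_parameters(self, mu, rho):
        with pytest.raises(ValueError):
            shape_from_mu_rho(mu, rho)


class TestLogDensity:
    def test_empty_trial_has_probability_one(self):
        shape = shape_from_mu_rho(0.3, 0.1)
        assert betabinom_log_density(0, 0, shape) == pytest.approx(0.0)

    def test_uniform_prior_makes_outcomes_equiprobable(self):
        # alpha = beta = 1 is a flat prior on the success probability, so all
        # n+1 outcomes have mass 1/(n+1)
        shape = shape_from_mu_rho(0.5, 1 / 3)  # alpha = beta = 1
        assert betabinom_log_density(1, 2, shape) == pytest.approx(math.log(1 / 3))

    def test_direct_summation_normalizes(self):
        shape = shape_from_mu_rho(2 / 7, 1 / 8)  # alpha=2, beta=5
        mass = np.exp(betabinom_log_density(np.arange(11), 10, shape)).sum()
        assert mass == pytest.approx(1.0, abs=1e-12)

    def test_normalizes_across_shapes_and_large_n(self):
        for n in (10, 1000, 10_000):
            for mu in (0.001, 0.05, 0.5, 0.9):
                for rho in (1e-4, 0.01, 0.3):
                    shape = shape_from_mu_rho(mu, rho)
                    mass = np.exp(
                        betabinom_log_density(np.arange(n + 1), n, shape)
                    ).sum()
                    assert abs(mass - 1.0) < 1e-9

    def test_small_rho_limit_is_binomial(self):
        n = 500
        for mu in (0.01, 0.2, 0.7):
            shape = shape_from_mu_rho(mu, 1e-8)
            ours = np.exp(betabinom_log_density(np.arange(n + 1), n, shape))
            ref = scipy_binom.pmf(np.arange(n + 1), n, mu)
            assert np.max(np.abs(ours - ref)) < 1e-6

    def test_impossible_outcome_is_floored(self):
        shape = shape_from_mu_rho(0.1, 0.01)
        assert betabinom_log_density(5, 2, shape) == LOG_DENSITY_FLOOR

    def test_matches_scipy_reference(self):
        shape = shape_from_mu_rho(0.02, 0.002)
        c = np.array([0, 3, 40, 700])
        ref = scipy_betabinom.logpmf(c, 1000, shape.alpha, shape.beta)
        ours = betabinom_log_density(c, 1000, shape)
        np.testing.assert_allclose(ours, ref, rtol=1e-9)


class TestExpectedReadsAndThreshold:
    @pytest.mark.parametrize(
        "ratio, mother, expected",
        [(0.001, 100_000, 100.0), (0.001, 0, 0.0), (0.05, 200, 10.0)],
    )
    def test_expected_daughter_reads(self, ratio, mother, expected):
        assert expected_daughter_reads(ratio, mother) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "total, a, b, expected",
        [(100, -2, -1, -5.0), (1000, -2, -1, -7.0), (12345, 0, 0, 0.0)],
    )
    def test_threshold_line(self, total, a, b, expected):
        params = CleanupParams(slope_a=a, offset_b=b)
        assert score_threshold(total, params) == pytest.approx(expected)

    def test_threshold_requires_positive_total(self):
        with pytest.raises(ValueError):
            score_threshold(0, CleanupParams())


def oracle_score(daughter, mother, params):
    """Independent route: scipy's beta-binomial pmf plus explicit bookkeeping."""
    daughter = np.asarray(daughter)
    mother = np.asarray(mother)
    r = daughter.sum() / mother.sum()
    ab = params.rho_divisor / r - 1.0
    alpha, beta = r * ab, (1 - r) * ab
    qual = (mother >= params.min_sample_reads) | (daughter >= params.min_sample_reads)
    if not qual.any() or not (0 < r < 1):
        return r, None
    vals = scipy_betabinom.logpmf(daughter[qual], mother[qual], alpha, beta)
    vals = np.maximum(np.nan_to_num(vals, nan=-np.inf), LOG_DENSITY_FLOOR)
    return r, float(np.mean(vals))


class TestLoglikScore:
    def test_worked_pair(self):
        params = CleanupParams()
        score = loglik_score([100, 200], [100_000, 200_000], params)
        assert score.ratio == pytest.approx(0.001)
        assert score.n_qualifying == 2
        _, expected = oracle_score(np.array([100, 200]),
                                   np.array([100_000, 200_000]), params)
        assert score.loglik == pytest.approx(expected, rel=1e-9)
        assert score.threshold == pytest.approx(-2 * math.log10(300) - 1)

    def test_no_qualifying_samples_leaves_score_undefined(self):
        score = loglik_score([1, 2], [150, 180], CleanupParams())
        assert score.n_qualifying == 0
        assert score.loglik is None

    def test_zero_daughter_total_is_degenerate(self):
        score = loglik_score([0, 0], [1000, 1000], CleanupParams())
        assert score.ratio == 0.0
        assert score.loglik is None
        assert score.threshold is None

    def test_zero_mother_total_is_an_error(self):
        with pytest.raises(ValueError):
            loglik_score([1, 2], [0, 0], CleanupParams())

    def test_matches_independent_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        params = CleanupParams()
        for _ in range(100):
            mother = rng.integers(0, 500_000, size=8)
            if mother.sum() == 0:
                mother[0] = 1000
            rate = rng.uniform(1e-4, 0.04)
            daughter = rng.binomial(mother, rate)
            score = loglik_score(daughter, mother, params)
            r, expected = oracle_score(daughter, mother, params)
            assert score.ratio == pytest.approx(r, rel=1e-12)
            if expected is None:
                assert score.loglik is None
            else:
                assert score.loglik == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_joint_sample_permutation(self):
        rng = np.random.default_rng(3)
        mother = rng.integers(100, 100_000, size=10)
        daughter = rng.binomial(mother, 0.002)
        base = loglik_score(daughter, mother)
        for _ in range(5):
            perm = rng.permutation(10)
            other = loglik_score(daughter[perm], mother[perm])
            assert other.loglik == pytest.approx(base.loglik, rel=1e-12)
            assert other.ratio == base.ratio

    def test_proportional_counts_score_higher_than_uneven(self):
        mother = np.array([100_000, 100_000, 100_000])
        proportional = loglik_score([100, 100, 100], mother)
        uneven = loglik_score([300, 0, 0], mother)
        assert proportional.loglik > uneven.loglik
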