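"""Zero-inflated removal observation model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from openremoval import observation as obs


class TestDailyCaptureProb:
    @pytest.mark.parametrize("theta,traps,expected", [
        (0.0, 100, 0.0),
        (1.0, 1, 1.0),
        (0.001, 100, 0.09521),  # complement of 100 per-trap misses
        (0.5, 0, 0.0),
    ])
    def test_values(self, theta, traps, expected):
        assert obs.daily_capture_prob(theta, traps) == pytest.approx(
            expected, abs=1e-5)

    def test_matches_independent_miss_product(self):
        # oracle: explicit product of per-trap miss probabilities
        theta, traps = 0.003, 57
        assert obs.daily_capture_prob(theta, traps) == pytest.approx(
            1.0 - np.prod(np.full(traps, 1.0 - theta)), rel=1e-12)

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            obs.daily_capture_prob(1.5, 10)

    @given(theta=st.floats(0, 1), traps=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, theta, traps):
        p = obs.daily_capture_prob(theta, traps)
        assert 0.0 <= p <= 1.0
        assert p <= obs.daily_capture_prob(theta, traps + 1) + 1e-15
        assert p <= obs.daily_capture_prob(min(theta + 0.01, 1.0), traps) + 1e-12


class TestRemovalCellProbs:
    @pytest.mark.parametrize("p,n,expected", [
        (0.5, 3, [0.5, 0.25, 0.125]),
        (0.0, 4, [0, 0, 0, 0]),
        (1.0, 3, [1, 0, 0]),
    ])
    def test_values(self, p, n, expected):
        assert obs.removal_cell_probs(p, n) == pytest.approx(expected)

    @given(p=st.floats(0, 1), n=st.integers(1, 60))
    @settings(max_examples=200, deadline=None)
    def test_conservation(self, p, n):
        # cells plus the never-removed mass partition the available animal
        pi = obs.removal_cell_probs(p, n)
        assert pi.sum() + (1 - p) ** n == pytest.approx(1.0, abs=1e-12)


class TestExpectedDailyRemovals:
    def test_arithmetic(self):
        assert obs.expected_daily_removals(100, 0.5, 0.09, 1) == pytest.approx(4.5)

    @pytest.mark.parametrize("phi,z", [(0.0, 1.0), (0.7, 0.0)])
    def test_zero_factors(self, phi, z):
        assert obs.expected_daily_removals(500, phi, 0.1, z) == 0


class TestZipLoglik:
    def test_pure_poisson_zero(self):
        assert obs.zip_loglik(0, 2.0, 1.0) == pytest.approx(-2.0)

    def test_always_unsuitable(self):
        assert obs.zip_loglik(0, 5.0, 0.0) == pytest.approx(0.0)

    def test_poisson_pmf_oracle(self):
        assert obs.zip_loglik(3, 2.0, 1.0) == pytest.approx(
            stats.poisson.logpmf(3, 2.0))

    def test_impossible_observation_flagged(self):
        assert obs.zip_loglik(3, 0.0, 0.5) == -math.inf

    @given(y=st.integers(0, 40), mu=st.floats(1e-6, 50))
    @settings(max_examples=150, deadline=None)
    def test_zprob_one_is_plain_poisson(self, y, mu):
        assert obs.zip_loglik(y, mu, 1.0) == pytest.approx(
            stats.poisson.logpmf(y, mu), rel=1e-9)

    @given(y=st.integers(0, 20), mu=st.floats(1e-3, 20),
           zp=st.floats(0.01, 0.99))
    @settings(max_examples=150, deadline=None)
    def test_matches_mixture_density(self, y, mu, zp):
        direct = (1 - zp) * (y == 0) + zp * stats.poisson.pmf(y, mu)
        assert obs.zip_loglik(y, mu, zp) == pytest.approx(
            math.log(direct), rel=1e-9)


class TestEffectiveProbs:
    @pytest.mark.parametrize("p,zp,phi,n,expected", [
        (0.1, 1.0, 0.0, 10, 0.0),
        (0.1, 1.0, 1.0, 10, 0.6513),
        (0.1, 0.5, 0.5, 14, 0.29844),  # 1 - 0.975**14
    ])
    def test_period_values(self, p, zp, phi, n, expected):
        assert obs.period_effective_prob(p, zp, phi, n) == pytest.approx(
            expected, abs=1e-4)

    @pytest.mark.parametrize("psets,expected", [
        ([0.5, 0.5], 0.75),
        ([0.0, 0.0, 0.0], 0.0),
        ([0.6513, 0.29844], 0.75534),
        ([], 0.0),
    ])
    def test_annual_values(self, psets, expected):
        assert obs.annual_effective_prob(psets) == pytest.approx(
            expected, abs=2e-4)

    def test_annual_dominates_each_period(self):
        psets = [0.1, 0.35, 0.2]
        assert obs.annual_effective_prob(psets) >= max(psets)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.integers(1, 40))
    @settings(max_examples=200, deadline=None)
    def test_period_monotone(self, p, zp, phi, n):
        v = obs.period_effective_prob(p, zp, phi, n)
        assert 0.0 <= v <= 1.0
        assert v <= obs.period_effective_prob(p, zp, phi, n + 1) + 1e-12
        assert v <= obs.period_effective_prob(min(p + 0.01, 1), zp, phi, n) + 1e-12


class TestSequentialRemovalOracle:
    def test_expected_period_removals_match_simulation(self, rng):
        """Cell probabilities reproduce Monte-Carlo sequential removal
        without replacement within 3 MC standard errors."""
        p, n_days, n_avail, reps = 0.22, 6, 40, 40_000
        totals = np.zeros(reps)
        for r in range(reps):
            remaining = n_avail
            for _ in range(n_days):
                c = rng.binomial(remaining, p)
                remaining -= c
                totals[r] += c
        expected = n_avail * obs.removal_cell_probs(p, n_days).sum()
        se = totals.std(ddof=1) / math.sqrt(reps)
        assert abs(totals.mean() - expected) < 3 * se
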