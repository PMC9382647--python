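"""MCMC layer: configs, sampling correctness, diagnostics, summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from openremoval import inference
from openremoval.inference import (MCMCConfig, PAPER_MCMC, fit, hpd_interval,
                                   rhat, summarize)


class ConjugateToy:
    """Poisson counts with a Gamma(shape, rate) prior on the rate --
    the posterior is Gamma(shape + sum(y), rate + n) in closed form."""

    shape, rate = 3.0, 1.0
    y = np.array([4, 7, 5, 6, 3, 8, 5, 4])
    n_params = 1
    param_names = ["lam"]

    def logpost(self, theta):
        lam = theta[0]
        if lam <= 0:
            return -np.inf
        lp = (self.shape - 1) * math.log(lam) - self.rate * lam
        return lp + float(np.sum(self.y * math.log(lam) - lam))

    def initial_point(self, rng):
        return np.array([rng.gamma(self.shape, 1.0 / self.rate) + 0.1])

    def initial_scales(self):
        return np.array([1.0])

    @property
    def post_shape(self):
        return self.shape + self.y.sum()

    @property
    def post_rate(self):
        return self.rate + len(self.y)


class TestMCMCConfig:
    def test_full_profile_retains_sixty_thousand(self):
        assert PAPER_MCMC.retained_draws == 60_000

    def test_generic_retained_contract(self):
        cfg = MCMCConfig(n_iter=200_000, thin=10, n_chains=3)
        assert cfg.retained_draws == 60_000

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=0)


class TestFit:
    cfg = MCMCConfig(n_adapt=500, n_burn=500, n_iter=2000, thin=1,
                     n_chains=3, seed=11)

    def test_conjugate_posterior_recovered(self):
        toy = ConjugateToy()
        res = fit(toy, self.cfg)
        draws = res.stacked()[:, 0]
        target_mean = toy.post_shape / toy.post_rate
        mc_se = draws.std(ddof=1) / math.sqrt(len(draws) / 20)  # crude ESS
        assert abs(draws.mean() - target_mean) < 3 * mc_se
        # compare full distribution against the closed form
        qs = np.quantile(draws, [0.1, 0.5, 0.9])
        ref = stats.gamma(toy.post_shape, scale=1 / toy.post_rate).ppf(
            [0.1, 0.5, 0.9])
        assert np.allclose(qs, ref, rtol=0.05)

    def test_reproducible_given_seed(self):
        toy = ConjugateToy()
        r1 = fit(toy, self.cfg)
        r2 = fit(toy, self.cfg)
        assert np.array_equal(r1.draws, r2.draws)

    def test_retained_draw_count(self):
        res = fit(ConjugateToy(), self.cfg)
        assert res.n_draws == self.cfg.retained_draws

    def test_hopeless_initialization_rejected(self):
        class Hopeless(ConjugateToy):
            def logpost(self, theta):
                return -np.inf

        with pytest.raises(RuntimeError, match="starting point"):
            fit(Hopeless(), self.cfg, max_init_attempts=5)


class TestRhat:
    def test_iid_chains_near_one(self, rng):
        chains = rng.normal(size=(3, 2000))
        assert rhat(chains) < 1.01

    def test_separated_chains_flagged(self, rng):
        chains = rng.normal(size=(3, 500)) + np.array([[0.0], [3.0], [6.0]])
        assert rhat(chains) > 1.5

    def test_constant_parameter_defined(self):
        assert rhat(np.zeros((3, 100))) == 1.0


class TestHpdInterval:
    def test_integer_ladder(self):
        lo, hi = hpd_interval(np.arange(1, 101), mass=0.5)
        assert hi - lo == 49  # fifty consecutive values

    def test_degenerate_draws(self):
        assert hpd_interval(np.full(50, 7.0)) == (7.0, 7.0)

    def test_symmetric_matches_quantiles(self, rng):
        x = rng.normal(size=40_000)
        lo, hi = hpd_interval(x, 0.95)
        qlo, qhi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(qlo, abs=0.1)
        assert hi == pytest.approx(qhi, abs=0.1)

    def test_shorter_than_quantile_interval_when_skewed(self, rng):
        x = rng.gamma(2.0, size=40_000)
        lo, hi = hpd_interval(x, 0.95)
        qlo, qhi = np.quantile(x, [0.025, 0.975])
        assert (hi - lo) <= (qhi - qlo)

    def test_exhaustive_window_oracle(self, rng):
        x = np.sort(rng.normal(size=200))
        k = math.ceil(0.9 * len(x))
        widths = [x[i + k - 1] - x[i] for i in range(len(x) - k + 1)]
        lo, hi = hpd_interval(x, 0.9)
        assert hi - lo == pytest.approx(min(widths))

    def test_invalid(self):
        with pytest.raises(ValueError):
            hpd_interval([1.0], 0.95)
        with pytest.raises(ValueError):
            hpd_interval([1.0, 2.0], 1.5)


class TestSummarize:
    def test_interval_kinds_and_tail_probs(self, rng):
        toy = ConjugateToy()
        res = fit(toy, TestFit.cfg)
        extra = {"net": rng.normal(2.0, 1.0, res.n_draws)}
        table = summarize(res, abundance_names={"lam"}, extra_draws=extra,
                          tail_probs={"net": 0.0})
        assert set(table["parameter"]) == {"lam", "net"}
        assert table.set_index("parameter").loc["lam", "interval"] == "hpd"
        assert table.set_index("parameter").loc["net", "interval"] == "quantile"
        pr = table.set_index("parameter").loc["net", "pr_gt_0"]
        assert pr == pytest.approx(np.mean(extra["net"] > 0))

    def test_tail_prob_all_positive(self, rng):
        toy = ConjugateToy()
        res = fit(toy, TestFit.cfg)
        table = summarize(res, tail_probs={"lam": 0.0})
        assert table["pr_gt_0"].iloc[0] == 1.0

    def test_median_below_mean_for_right_skew(self, rng):
        x = rng.lognormal(size=10_000)
        assert np.median(x) < x.mean()
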