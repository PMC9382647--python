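"""Synthetic-data generator and the post-validation study plumbing."""

import dataclasses
import math

import numpy as np
import pytest

from openremoval import (SimulationTruth, inference, make_preset,
                         run_simulation_study, simulate_series)
from openremoval import observation
from openremoval.simulate import seasonal_phi


class TestPresets:
    @pytest.mark.parametrize("name", ["core-like", "edge-like", "sparse",
                                      "infopm-core"])
    def test_presets_valid(self, name):
        truth = make_preset(name, seed=3)
        assert truth.build_design().max_period == 26

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_preset("nope")

    def test_truth_round_trips_through_dict(self):
        truth = make_preset("core-like", seed=5)
        again = SimulationTruth.from_dict(truth.to_dict())
        assert again.to_dict() == truth.to_dict()

    def test_malformed_truth_rejected(self):
        with pytest.raises(ValueError):
            SimulationTruth.from_dict({"model_kind": "rw", "years": [2016]})

    def test_missing_dynamics_named(self):
        with pytest.raises(ValueError, match="lam0"):
            SimulationTruth(
                model_kind="rw", years=(2016,), sampled_periods=(6, 7),
                n_days=14, effort=50, theta=(1e-3,), zprob=(0.9,),
                phi=seasonal_phi((6, 7)))


class TestGenerator:
    def test_deterministic_given_seed(self, rw_truth):
        s1, l1 = simulate_series(rw_truth, seed=9)
        s2, l2 = simulate_series(rw_truth, seed=9)
        assert np.array_equal(s1.removals, s2.removals)
        assert np.array_equal(l1["M"], l2["M"])

    def test_zero_suitability_no_removals(self, rw_truth):
        truth = dataclasses.replace(rw_truth, zprob=(0.0,) * 3)
        series, latent = simulate_series(truth, seed=2)
        assert series.period_totals.sum() == 0
        assert latent["M"].sum() > 0  # the population still evolves

    def test_zero_efficiency_no_removals(self, rw_truth):
        truth = dataclasses.replace(rw_truth, theta=(0.0,) * 3)
        series, latent = simulate_series(truth, seed=2)
        assert series.period_totals.sum() == 0
        assert (latent["lam"] > 0).all()

    def test_mean_period_removals_match_effective_rate(self, rw_truth):
        """Replicated periods: mean removals agree with M * pset within
        3 MC standard errors (closed-form effective-rate oracle)."""
        one = dataclasses.replace(
            rw_truth, years=(2016,), sampled_periods=(10,),
            theta=(rw_truth.theta[0],), zprob=(rw_truth.zprob[0],),
            phi=np.array([[0.5]]), mu_trend=(0.0,), sd_trend=(1.0,),
            lam0=600.0)
        totals = []
        for rep in range(2000):
            series, _ = simulate_series(one, seed=rep)
            totals.append(series.period_totals.sum())
        totals = np.array(totals, dtype=float)
        p = observation.daily_capture_prob(one.theta[0], one.effort)
        pset = observation.period_effective_prob(
            p, one.zprob[0], 0.5, one.n_days)
        expected = one.lam0 * pset
        se = totals.std(ddof=1) / math.sqrt(len(totals))
        assert abs(totals.mean() - expected) < 3 * se

    def test_infopm_latents_consistent(self, small_infopm_truth):
        series, latent = simulate_series(small_infopm_truth, seed=4)
        assert np.all(latent["lam_star"] >= latent["lam"] - 1e-9)
        assert np.all(latent["phi_juv"] >= 0)
        assert np.all(latent["phi_juv"] <= 1)
        assert series.period_totals.sum() == latent["R"].sum()

    def test_series_is_ingestable_round_trip(self, rw_series):
        series, _ = rw_series
        # generator output went through the real ingestion path
        assert series.design.sampled_mask.sum() == 48
        assert (series.design.n_days[series.design.sampled_mask] == 14).all()


class TestSimulationStudy:
    def test_no_converged_fits_gives_empty_report(self, rw_truth):
        truth = dataclasses.replace(rw_truth, years=(2016,),
                                    theta=(rw_truth.theta[0],),
                                    zprob=(rw_truth.zprob[0],),
                                    phi=rw_truth.phi[:1],
                                    mu_trend=(rw_truth.mu_trend[0],),
                                    sd_trend=(rw_truth.sd_trend[0],))
        # a 2-sweep chain cannot converge: the report must stay empty
        cfg = inference.MCMCConfig(n_adapt=1, n_burn=1, n_iter=2, thin=1,
                                   n_chains=3, seed=0)
        report = run_simulation_study(truth, 1, cfg, master_seed=0)
        assert report.n_converged == 0
        assert math.isnan(report.median_bias)
        assert report.frac_within_threshold == {}

    def test_invalid_reps(self, rw_truth):
        with pytest.raises(ValueError):
            run_simulation_study(rw_truth, 0, inference.DEFAULT_TEST_MCMC)
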