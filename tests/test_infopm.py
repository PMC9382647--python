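"""2-age-class informed population model."""

import numpy as np
import pytest
from scipy import stats

from openremoval import observation
from openremoval.infopm import (InfoPMModel, adult_transition,
                                allocate_removals, birth_transition,
                                catchable_fraction, combined_expected_removals,
                                corrected_rates, juvenile_abundance,
                                juvenile_availability, project_no_removal,
                                scalarize_survival)
from openremoval.priors import Prior, VitalRatePriors, default_priors, load_priors


class TestScalarizeSurvival:
    def test_identity_and_root(self):
        assert scalarize_survival(1.0, 26) == 1.0
        assert scalarize_survival(0.5, 26) == pytest.approx(0.5 ** (1 / 26))

    def test_round_trip(self):
        s = scalarize_survival(0.37, 26)
        assert s ** 26 == pytest.approx(0.37, rel=1e-12)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            scalarize_survival(0.0, 26)


class TestEmergenceCurve:
    def test_half_at_location(self):
        assert juvenile_availability(180.0, 180.0, 30.0) == pytest.approx(0.5)

    def test_tails(self):
        assert juvenile_availability(0.0, 180.0, 30.0) == pytest.approx(0.0, abs=1e-8)
        assert juvenile_availability(180 + 1.96 * 30, 180, 30) == pytest.approx(
            0.975, abs=1e-3)

    def test_monotone_in_age(self):
        days = np.linspace(0, 365, 50)
        vals = juvenile_availability(days, 180.0, 30.0)
        assert np.all(np.diff(vals) >= 0)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            juvenile_availability(100, 180, 0.0)


class TestJuvenileAbundance:
    def test_limits(self):
        # at the pulse: the full cohort before first-year mortality
        assert juvenile_abundance(100, 0.25, 0, 0, 26) == pytest.approx(400.0)
        # after a whole cycle: only the survivors that recruit
        assert juvenile_abundance(100, 0.25, 26, 0, 26) == pytest.approx(100.0)

    def test_mid_cohort_with_removals(self):
        assert juvenile_abundance(100, 0.25, 13, 10, 26) == pytest.approx(190.0)

    def test_floor_at_zero(self):
        assert juvenile_abundance(10, 0.5, 26, 50, 26) == 0.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            juvenile_abundance(10, 0.0, 5, 0, 26)
        with pytest.raises(ValueError):
            juvenile_abundance(10, 0.5, 30, 0, 26)


class TestCatchableAndAllocation:
    @pytest.mark.parametrize("ad,juv,pj,expected", [
        (50, 150, 1.0, 1.0),
        (80, 0, 0.3, 1.0),
        (50, 150, 0.2, 0.4),
        (0, 0, 0.5, 1.0),  # degenerate: defined as no correction
    ])
    def test_catchable_fraction(self, ad, juv, pj, expected):
        assert catchable_fraction(ad, juv, pj) == pytest.approx(expected)

    def test_allocation_example(self):
        r_ad, r_juv = allocate_removals(50, 150, 0.2, 16)
        assert (r_ad, r_juv) == pytest.approx((10.0, 6.0))

    def test_allocation_conserves_total_exactly(self, rng):
        for _ in range(200):
            ad, juv = rng.uniform(0, 1000, 2)
            pj = rng.uniform(0, 1)
            r = rng.integers(0, 500)
            r_ad, r_juv = allocate_removals(ad + 1e-9, juv, pj, r)
            assert r_ad + r_juv == pytest.approx(float(r), abs=1e-9)
            assert r_ad >= 0 and r_juv >= 0

    def test_unavailable_juveniles_all_adult(self):
        r_ad, r_juv = allocate_removals(40, 500, 0.0, 12)
        assert (r_ad, r_juv) == (12.0, 0.0)

    def test_zero_catchable_with_removals_rejected(self):
        with pytest.raises(ValueError):
            allocate_removals(0.0, 100.0, 0.0, 5)


class TestTransitions:
    def test_adult_identity(self):
        assert adult_transition(123.0, 1.0, 0.0, 0.0, 0.0) == 123.0

    def test_adult_arithmetic(self):
        assert adult_transition(100, 0.97368, 5, 10, 0) == pytest.approx(92.368)
        assert adult_transition(100, 0.9, 0, 0, 140) == pytest.approx(230.0)

    def test_birth_transition(self):
        assert birth_transition(0.8, 200, 20, True) == pytest.approx(140.0)
        assert birth_transition(0.8, 200, 20, False) == 0.0
        assert birth_transition(0.1, 10, 50, True) == 0.0  # floored


class TestCombinedLikelihood:
    def test_reduces_to_single_class(self):
        # with full juvenile availability the combined expectation is the
        # one-class expectation at lam = lam_ad + lam_juv
        lam_ad, lam_juv = 320.0, 180.0
        combined = combined_expected_removals(lam_ad, lam_juv, 1.0, 0.5, 0.1, 1)
        single = observation.expected_daily_removals(
            lam_ad + lam_juv, 0.5, 0.1, 1)
        assert combined == pytest.approx(single)

    def test_arithmetic(self):
        assert combined_expected_removals(50, 150, 0.2, 0.5, 0.1, 1) == \
            pytest.approx(4.0)

    def test_corrected_rates(self):
        pset_star, pyear_star = corrected_rates(
            np.array([0.4]), np.array([0.1]), 1.0, np.array([1.0]),
            np.array([10]))
        assert pset_star[0] == pytest.approx(1 - 0.96 ** 10, abs=1e-6)
        ps_full, py_full = corrected_rates(
            np.ones(3), np.full(3, 0.1), 0.9, np.full(3, 0.6), np.full(3, 14))
        uncorrected = observation.period_effective_prob(0.1, 0.9, 0.6, 14)
        assert ps_full == pytest.approx(np.full(3, uncorrected))
        assert np.all(pset_star <= 1.0)


class TestPriorsConfig:
    def test_missing_component_named(self):
        with pytest.raises(ValueError, match="s_juv"):
            load_priors({"b": {"dist": "normal", "params": [0.7, 0.1]},
                         "s_ad_year": {"dist": "beta", "params": [2, 2]}}, 3)

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        pri = default_priors(2)
        path = tmp_path / "priors.yaml"
        path.write_text(yaml.safe_dump(pri.to_dict()))
        again = load_priors(str(path), 2)
        assert again.to_dict() == pri.to_dict()

    def test_survival_support_validated(self):
        with pytest.raises(ValueError, match="support"):
            VitalRatePriors(
                b=tuple([Prior("normal", (0.7, 0.1))] * 3),
                s_ad_year=Prior("normal", (0.7, 0.1)),  # unbounded support
                s_juv=Prior("beta", (2, 6)),
                mu_emerge=tuple([Prior("uniform", (150, 210))] * 2),
                sd_emerge=tuple([Prior("truncnormal", (60, 14.14))] * 2),
            ).validate(2)

    def test_emergence_prior_mean(self):
        assert Prior("uniform", (150, 210)).mean() == pytest.approx(180.0)


class TestJointModel:
    def test_kernel_matches_reference_density(self, small_infopm_model, rng):
        model, _ = small_infopm_model
        for _ in range(5):
            vec = model.initial_point(rng)
            assert model.logpost(vec) == pytest.approx(
                model.logpost_py(vec), rel=1e-10)

    def test_net_migration_parameter_counts(self, small_infopm_model):
        model, _ = small_infopm_model
        assert model.n_iegroup == 2  # yearly variant, two years

    def test_matches_rw_when_juveniles_fully_available(self, small_infopm_model,
                                                       rng):
        """Forcing the emergence curve to 1 reduces the pointwise
        log-likelihood to the one-class form at the matched total."""
        model, _ = small_infopm_model
        vec = model.initial_point(rng)
        p = model.unpack(vec)
        p["mu_emerge"] = np.full_like(p["mu_emerge"], -1e4)  # phi_juv -> 1
        vec2 = model.pack(**p)
        traj = model.trajectories(vec2)
        assert np.allclose(traj["phi_juv"], 1.0)
        assert np.allclose(traj["lam_catch"], traj["lam_star"])
        # one-class oracle at the same totals
        mu, zp = model.daily_means(vec2)
        ll = observation.zip_loglik(model.layout.y_obs, mu, zp)
        assert np.allclose(model.pointwise_loglik(vec2), ll)

    def test_degenerate_priors_give_finite_density(self, small_infopm_truth):
        from openremoval.simulate import centered_priors, simulate_series
        series, _ = simulate_series(small_infopm_truth, seed=7)
        pri = centered_priors(small_infopm_truth, rel_sd=0.001)
        model = InfoPMModel(series, None, pri)
        vec = model.initial_point(np.random.default_rng(3))
        assert np.isfinite(model.logpost(vec))

    def test_missing_prior_component_rejected(self, small_infopm_truth):
        from openremoval.simulate import simulate_series
        series, _ = simulate_series(small_infopm_truth, seed=7)
        with pytest.raises(ValueError, match="b"):
            bad = default_priors(2)
            object.__setattr__(bad, "b", bad.b[:1])
            InfoPMModel(series, None, bad)


class TestCounterfactual:
    def test_zero_removals_identical(self, small_infopm_truth):
        """With no observed removals the no-removal projection equals the
        estimated trajectory draw by draw."""
        import dataclasses
        import pandas as pd
        from openremoval import build_design, ingest_records
        truth = small_infopm_truth
        d = build_design(truth.years)
        rows = []
        for yr in truth.years:
            for t in truth.sampled_periods:
                for j in range(truth.n_days):
                    doy = (t - 1) * 14 + j + 1
                    from openremoval.simulate import _date_from_doy_365
                    rows.append({"date": _date_from_doy_365(yr, doy).isoformat(),
                                 "removals": 0, "traps": truth.effort})
        series = ingest_records(pd.DataFrame(rows), d)
        from openremoval.simulate import centered_priors
        model = InfoPMModel(series, None, centered_priors(truth))
        rng = np.random.default_rng(0)
        draws = np.stack([model.initial_point(rng) for _ in range(8)])
        proj = project_no_removal(model, draws, np.random.default_rng(1))
        for q in ("lam", "lam_star", "lam_ad", "lam_juv", "M", "M_star"):
            assert np.array_equal(proj["estimated"][q], proj["no_removal"][q])

    def test_positive_removals_dominated(self, small_infopm_model):
        """With removals the counterfactual dominates the estimated
        trajectory at every period in every draw."""
        model, _ = small_infopm_model
        rng = np.random.default_rng(4)
        draws = np.stack([model.initial_point(rng) for _ in range(10)])
        proj = project_no_removal(model, draws, np.random.default_rng(2))
        for q in ("lam", "lam_star", "M", "M_star"):
            assert np.all(proj["no_removal"][q] >= proj["estimated"][q] - 1e-9)

    def test_two_period_hand_recursion(self):
        """A hand-computed two-period recursion matches the projection."""
        import pandas as pd
        from openremoval import build_design, ingest_records
        from openremoval.simulate import _date_from_doy_365
        d = build_design([2016])
        rows = []
        for t, r in ((10, 5), (11, 3)):  # two post-pulse periods
            for j in range(14):
                doy = (t - 1) * 14 + j + 1
                rows.append({"date": _date_from_doy_365(2016, doy).isoformat(),
                             "removals": r if j == 0 else 0, "traps": 40})
        series = ingest_records(pd.DataFrame(rows), d)
        pri = default_priors(1)
        model = InfoPMModel(series, None, pri)
        rng = np.random.default_rng(9)
        vec = model.initial_point(rng)
        p = model.unpack(vec)
        traj = model.trajectories(vec)
        sad_p = scalarize_survival(float(p["s_ad_year"][0]), 26)
        # period 10: the chain starts after the pulse, so the live
        # cohort is seeded from the pre-study adult scale
        B1 = float(p["b"][1]) * float(p["lam_ad_prepulse"][0])
        lam_juv0 = B1 * float(p["s_juv"][0]) ** ((1 - 26) / 26)
        assert traj["lam_juv"][0] == pytest.approx(lam_juv0)
        phij0 = stats.norm.cdf((14 * 1 - p["mu_emerge"][0]) / p["sd_emerge"][0])
        r_ad0, r_juv0 = allocate_removals(
            float(p["lam_ad"][0]), lam_juv0, float(phij0), 5.0)
        ie0 = float(p["lam_ad"][1]) - (float(p["lam_ad"][0]) * sad_p - r_ad0)
        assert traj["ie"][0] == pytest.approx(ie0)
        # counterfactual: same ie, no removals
        cf1 = adult_transition(float(p["lam_ad"][0]), sad_p, ie0, 0.0, 0.0)
        proj = project_no_removal(model, vec[None, :])
        assert proj["no_removal"]["lam_ad"][0, 1] == pytest.approx(cf1)
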