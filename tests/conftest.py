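import numpy as np
import pytest

from openremoval import (RWModel, build_design, ingest_records, make_preset,
                         simulate_series)
from openremoval.infopm import InfoPMModel
from openremoval.simulate import SimulationTruth, centered_priors, seasonal_phi


@pytest.fixture(scope="session")
def rw_truth():
    return make_preset("core-like", seed=1)


@pytest.fixture(scope="session")
def rw_series(rw_truth):
    """One simulated high-signal removal series with its latent truth."""
    return simulate_series(rw_truth, seed=100)


@pytest.fixture(scope="session")
def rw_model(rw_series):
    return RWModel(rw_series[0])


@pytest.fixture(scope="session")
def small_infopm_truth():
    """A two-year age-structured scenario (kept small for fast fits)."""
    periods = tuple(range(6, 22))
    return SimulationTruth(
        model_kind="infopm", years=(2016, 2017), sampled_periods=periods,
        n_days=14, effort=120, theta=(1.2e-4,) * 2, zprob=(0.85,) * 2,
        phi=seasonal_phi(periods), lam_ad0=500.0, lam_ad_prepulse=600.0,
        b=(0.7,) * 3, s_ad_year=0.7, s_juv=0.25, mu_emerge=180.0,
        sd_emerge=30.0, mu_ie=(60.0,) * 2, sd_ie=(20.0,) * 2, seed=1)


@pytest.fixture(scope="session")
def small_infopm_model(small_infopm_truth):
    series, latent = simulate_series(small_infopm_truth, seed=42)
    model = InfoPMModel(series, None, centered_priors(small_infopm_truth))
    return model, latent


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


#: scaled-down MCMC profile used by the heavy study fixtures
STUDY_MCMC = dict(n_adapt=2000, n_burn=4000, n_iter=4000, thin=2, n_chains=3)


@pytest.fixture(scope="session")
def study_report():
    """Estimator post-validation study: 20 replicate series from the
    un-approximated multinomial removal process at the high-signal
    scenario, each refit at the reduced MCMC profile."""
    import dataclasses
    from openremoval import inference, run_simulation_study
    truth = dataclasses.replace(make_preset("core-like", seed=1),
                                mechanism="multinomial")
    cfg = inference.MCMCConfig(seed=0, **STUDY_MCMC)
    return run_simulation_study(truth, 20, cfg, thresholds=(20.0,),
                                compute_ppc=True, master_seed=1)


@pytest.fixture(scope="session")
def ppc_calib():
    """Goodness-of-fit calibration under the true generating model,
    averaged over four simulate-and-refit replicates."""
    from openremoval import inference
    from openremoval.simulate import ppc_calibration
    truth = make_preset("core-like", seed=1)
    cfg = inference.MCMCConfig(seed=0, **STUDY_MCMC)
    return ppc_calibration(truth, 4, cfg, master_seed=1)
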