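import numpy as np
import pytest

from marchrisk.config import CohortConfig, RiskModelParams, RunConfig, TrainingRegimen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cohort_config():
    return CohortConfig(seed=7)


@pytest.fixture
def degenerate_cohort_config():
    """Zero stride-to-stride variability, zero baseline noise, zero SD on the
    waveform-relevant variables: the generated trial is exactly periodic."""
    cfg = CohortConfig(seed=7, stride_cv=0.0, baseline_noise_sd=0.0)
    for variable in ("stance_duration", "normalized_stride_length", "grf_peak"):
        for sex, by_load in cfg.group_params[variable].items():
            for load, (mean, _) in by_load.items():
                by_load[load] = (mean, 0.0)
    return cfg


@pytest.fixture
def regimen():
    return TrainingRegimen()


def miner_params(n_f: float, strain: float = 5000.0, **kwargs) -> RiskModelParams:
    """Risk parameters with the S-N curve pinned so Nf(strain) = n_f,
    scatter and adaptation off, and repair off unless overridden."""
    defaults = dict(
        sn_intercept=np.log10(n_f) + 9.3 * np.log10(strain),
        sn_slope=-9.3,
        sn_scatter_sd=0.0,
        repair_time_constant=np.inf,
        apposition_rate=0.0,
        mc_samples=1,
    )
    defaults.update(kwargs)
    return RiskModelParams(**defaults)


@pytest.fixture(scope="session")
def default_report():
    """One full pipeline run at the study group sizes, shared across tests."""
    from marchrisk.pipeline import run_pipeline

    config = RunConfig(seed=11)
    config.cohort.seed = 11
    return run_pipeline(config)


@pytest.fixture
def small_run_config():
    cfg = RunConfig(seed=3)
    cfg.cohort = CohortConfig(seed=3, n_female=6, n_male=6)
    cfg.risk_model = RiskModelParams(mc_samples=300)
    return cfg
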