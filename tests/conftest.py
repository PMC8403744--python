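import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_params():
    from saccadapt.observer import ObserverParams
    return ObserverParams()


@pytest.fixture(scope="session")
def clean_params():
    """Observer with no oculomotor noise or blinks: every trial should validate."""
    from saccadapt.observer import ObserverParams
    return ObserverParams(landing_error_sd_deg=0.0, fixation_jitter_sd_deg=0.01,
                          blink_prob=0.0)


@pytest.fixture(scope="session")
def exp1_small_records():
    """One simulated participant of the main experiment (480 trials)."""
    from saccadapt.design import experiment_spec
    from saccadapt.observer import ObserverParams, generate_dataset
    return generate_dataset(experiment_spec(1), 1, ObserverParams(), master_seed=99)
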