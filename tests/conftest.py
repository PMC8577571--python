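import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def default_field():
    from fgsablate import PhantomSpec, build_phantom
    return build_phantom(PhantomSpec())


@pytest.fixture
def quiet_model():
    from fgsablate import EmissionModel
    return EmissionModel(noise_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def envelope_report():
    """Shared calibrated-noise experiment: 30 seeds per diameter at the
    reduced 0.5 mm distance-scan resolution."""
    from dataclasses import replace
    from fgsablate import ExperimentConfig, run_experiment
    cfg = replace(ExperimentConfig(), replicates=30, distance_step_mm=0.5)
    return run_experiment(cfg, base_seed=0)
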