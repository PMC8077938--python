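import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mechanocell as mc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Base seed for every stochastic test in the suite.
BASE_SEED = 1234


@pytest.fixture(scope="session")
def base_seed():
    return BASE_SEED


@pytest.fixture(scope="session")
def free_diffusion_ensemble():
    """alpha=0, DT=2 ensemble in free space, reused by MSD and variance tests."""
    cfg = mc.SimulationConfig(
        dt=1e-3, total_time=20.0, boundary="none", n_trajectories=200, seed=BASE_SEED
    )
    params = mc.ScaledParams(alpha=0.0, DT=2.0)
    return mc.run_ensemble(params, cfg)


@pytest.fixture(scope="session")
def reflecting_ensemble():
    """Moderate-coupling reflecting-box ensemble reused across observable tests."""
    cfg = mc.SimulationConfig(
        dt=1e-3,
        total_time=60.0,
        boundary="reflecting",
        n_trajectories=100,
        seed=BASE_SEED,
        record_stride=10,
    )
    params = mc.ScaledParams(alpha=5.0, DT=1.0)
    return mc.run_ensemble(params, cfg)
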