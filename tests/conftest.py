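import numpy as np
import pytest

from chimotor.pipeline import PipelineConfig, analyze_trajectories, simulate_ensemble


@pytest.fixture(scope="session")
def default_pipeline_run():
    """One full 50-trajectory self-consistency run shared across tests.

    Uses the package defaults (150-cycle trajectories, 0.5 ms sampling,
    0.34 nm pause noise, the standard rate scheme) with a fixed fixture
    seed so results are reproducible.
    """
    cfg = PipelineConfig(seed=1)
    trajs = simulate_ensemble(cfg)
    result = analyze_trajectories(trajs, cfg)
    return cfg, trajs, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
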