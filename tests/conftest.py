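import numpy as np
import pytest
from hypothesis import settings

import neuralclock as nc
from neuralclock.engine import train_clock

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


def desk_cfg_for_seed(seed: int) -> nc.SimulationConfig:
    cfg = nc.desk_config()
    cfg.seeds.topology = seed
    cfg.seeds.stimulus = seed * 11 + 1
    cfg.seeds.dynamics = seed * 17 + 5
    return cfg


@pytest.fixture(scope="session")
def desk_clocks():
    """Fully trained desk clocks (both learning phases) for three seeds.

    This is the expensive shared fixture behind the scaled-down end-to-end
    checks: ~10 minutes of biological time per seed.
    """
    out = {}
    for seed in (1, 2, 3):
        cfg = desk_cfg_for_seed(seed)
        out[seed] = train_clock(cfg)
    return out


@pytest.fixture(scope="session")
def tiny_cfg():
    """A minimal, fast configuration for engine-contract tests."""
    cfg = nc.desk_config()
    cfg.network.N_E = 40
    cfg.network.N_I = 20
    cfg.network.N_C = 4
    cfg.network.N_R = 2
    cfg.protocol.phase1_ms = 500.0
    cfg.protocol.phase2_ms = 500.0
    cfg.protocol.readout_ms = 500.0
    cfg.protocol.replay_ms = 500.0
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
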