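import numpy as np
import pytest

from micromet import initialize_world, run_simulation
from micromet.presets import PRESET_LEVELS, preset_config


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def tiny_config(**overrides):
    """A fast, small tissue patch for engine-level tests."""
    from micromet import WorldConfig

    cfg = WorldConfig()
    cfg.domain_size = 240.0
    cfg.dt_diffusion = 0.5
    cfg.dt_mechanics = 0.5
    cfg.initial_cancer = 3
    cfg.initial_macrophages = 4
    cfg.initial_dcs = 2
    for k, v in overrides.items():
        if "." in k:
            block, attr = k.split(".")
            setattr(getattr(cfg, block), attr, v)
        else:
            setattr(cfg, k, v)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def preset_runs():
    """Five replicates of each immune-response preset, run once per session."""
    out = {}
    for level in PRESET_LEVELS:
        runs = []
        for rep in range(5):
            cfg = preset_config(level, seed=1000 + rep)
            world = initialize_world(cfg)
            n_initial = len(world.cells)
            traj = run_simulation(world)
            runs.append((n_initial, traj))
        out[level] = runs
    return out
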