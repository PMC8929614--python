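import numpy as np
import pytest

from lag1.config import ModelParams
from lag1.experiment_harness import (ExperimentConfig, Lag1Model,
                                     build_structure, counterbalance,
                                     run_experiment)
from lag1.visuospatial import sim1_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blair():
    return build_structure("blair")


@pytest.fixture(scope="session")
def five_four():
    return build_structure("five_four")


@pytest.fixture(scope="session")
def sim1_run_short():
    """A short Simulation-1 run at median free parameters, shared across
    tests that only need plausible raw data (30 trials)."""
    cfg = ExperimentConfig(structure="blair", n_trials=30, seed=7)
    return run_experiment(cfg)


def make_model(structure_name="blair", seed=0, **overrides):
    structure = build_structure(structure_name)
    layout = sim1_layout()
    params = ModelParams(**overrides)
    rng_ = np.random.default_rng(seed)
    return Lag1Model(structure, layout, params, rng_), counterbalance(structure, 0)
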