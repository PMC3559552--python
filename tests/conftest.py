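"""Shared fixtures: expensive simulation artifacts are built once per session."""

import numpy as np
import pytest

from endoabm.config import ProductionParams, SimulationConfig
from endoabm.experiments import prepare_homeostatic_world
from endoabm.world import build_world


@pytest.fixture(scope="session")
def default_world():
    """A freshly constructed world at the published defaults."""
    return build_world(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def homeostatic_base():
    """Relaxed circadian snapshot at the published adjusted parameters.

    Shared by every experiment-level test; treat as read-only (experiments
    deep-copy it per replicate).
    """
    return prepare_homeostatic_world()


@pytest.fixture(scope="session")
def tuning_result():
    """Full tuning run from the untuned 70% probabilities."""
    from endoabm.calibration import TuningConfig, tune_homeostasis
    cfg = SimulationConfig(seed=7, params=ProductionParams.initial_guess())
    return tune_homeostasis(cfg, TuningConfig(max_rounds=30))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
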