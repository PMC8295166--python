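import logging

import numpy as np
import pytest

from aneuclip.driver import SimulationConfig, run
from aneuclip.geometry import TriangleMesh, make_tube
from aneuclip.scenarios import pinch_tube_scenario

# stretch-compensation convergence warnings are expected during hard contact
logging.getLogger("aneuclip.massspring").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def straight_tube() -> TriangleMesh:
    """Canonical straight tube: r=1 mm, length 10 mm along z, 400 vertices."""
    line = np.array([[0.0, 0.0, -5.0], [0.0, 0.0, 5.0]])
    return make_tube(line, 1.0, 16, 24)


@pytest.fixture(scope="session")
def pinch():
    """The canonical clip-closing scenario (built once per session)."""
    return pinch_tube_scenario()


@pytest.fixture(scope="session")
def pinch_history(pinch):
    """Full clip-closing run to convergence; shared across end-to-end tests."""
    history = run(pinch.initial_state(), pinch.system, pinch.schedule,
                  pinch.config, clip=pinch.clip)
    return history


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def quick_config() -> SimulationConfig:
    """Small-budget configuration for short driver tests."""
    return SimulationConfig(max_steps=400, convergence_tol=1e-4)
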