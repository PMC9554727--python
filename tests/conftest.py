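import numpy as np
import pytest

from cellswarm.config import PipelineConfig
from cellswarm.library import ForceLibrary
from cellswarm.simulate import SimulationConfig, TrajectoryData, simulate_population


@pytest.fixture(scope="session")
def library():
    return ForceLibrary()


@pytest.fixture(scope="session")
def small_c_population():
    """Small homogeneous alignment+drag population (species C)."""
    cfg = SimulationConfig(n_tot=30, proportions={"C": 1.0}, n_frames=120,
                           dt=0.02, seed=42, ic_speed_std=0.2, ic_radius=0.35)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def tiny_trajectory():
    """Hand-sized random-walk-free trajectory: 3 cells, 5 frames."""
    rng = np.random.default_rng(0)
    pos = np.cumsum(rng.normal(scale=0.05, size=(3, 5, 2)), axis=1) + \
        rng.uniform(-1, 1, size=(3, 1, 2))
    return TrajectoryData(positions=pos, times=0.1 * np.arange(5),
                          labels=np.array(["A", "B", "C"]))


@pytest.fixture()
def config():
    return PipelineConfig()
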