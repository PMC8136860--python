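import numpy as np
import pytest

from buridan import ArenaGeometry, GenotypeEffect, SimulationConfig


@pytest.fixture(scope="session")
def arena() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture
def small_config(arena) -> SimulationConfig:
    """Short sessions keep unit tests fast; full 5-min runs live in the
    acceptance suite."""
    return SimulationConfig(dt=0.05, duration=30.0, seed=7, arena=arena, n_flies_per_group=4)


@pytest.fixture
def wt_effect() -> GenotypeEffect:
    return GenotypeEffect(label="wt")


def random_trajectory(rng: np.random.Generator, n_samples: int, n_segments: int = 1):
    """A random in-disc trajectory for oracle comparisons."""
    from buridan import Trajectory, TrajectorySegment

    segs = []
    t_offset = 0.0
    per_seg = max(n_samples // n_segments, 2)
    for _ in range(n_segments):
        t = t_offset + np.cumsum(rng.uniform(0.04, 0.1, per_seg))
        # random walk with walking-scale steps (speeds mostly 0-50 mm/s)
        x = np.cumsum(rng.normal(0, 0.8, per_seg)) + rng.uniform(-20, 20)
        y = np.cumsum(rng.normal(0, 0.8, per_seg)) + rng.uniform(-20, 20)
        segs.append(TrajectorySegment(t, x, y))
        t_offset = t[-1] + 0.05
    return Trajectory("rand", "g", segs)
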