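import numpy as np
import pytest

from echolag import ExtractionConfig, PairedTrajectory, Trajectory
from echolag.synthetic import SynthSpec, generate


@pytest.fixture
def cfg():
    return ExtractionConfig()


def straight_pair(
    heading_a=0.0,
    heading_b=None,
    speed=5.0,
    n=60,
    dt=0.02,
    offset=(0.0, 1.0),
    pair_id="straight",
):
    """Two constant-velocity tracks; b offset from a (defaults to parallel)."""
    heading_b = heading_a if heading_b is None else heading_b
    t = dt * np.arange(n)
    pa = np.column_stack([speed * t * np.cos(heading_a), speed * t * np.sin(heading_a)])
    pb = np.column_stack(
        [offset[0] + speed * t * np.cos(heading_b), offset[1] + speed * t * np.sin(heading_b)]
    )
    return PairedTrajectory(
        pair_id,
        Trajectory("a", 0.0, dt, pa),
        Trajectory("b", 0.0, dt, pb),
    )


@pytest.fixture
def parallel_pair():
    return straight_pair()


@pytest.fixture
def coordinated_pair():
    pair, truth = generate(SynthSpec(scenario="coordinated", lag=0.2, seed=3, duration=6.0))
    return pair, truth


@pytest.fixture
def chase_pair():
    pair, truth = generate(
        SynthSpec(scenario="chase", lag=0.2, seed=1, noise_sd=0.0, duration=6.0)
    )
    return pair, truth
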