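import numpy as np
import pytest

from dsxchange.model import build_i27_star
from dsxchange.potentials import PotentialParams


@pytest.fixture(scope="session")
def params():
    return PotentialParams()


@pytest.fixture(scope="session")
def fixture_chain():
    """The I27*-like chain with a seed-1 compact start."""
    return build_i27_star(seed=1)


@pytest.fixture(scope="session")
def unfolded_run(params):
    """One 480 pN trajectory long enough to unfold and plateau.

    Shared by several tests; 400k steps take a few seconds.
    """
    from dsxchange.simulator import SimulationConfig, run_force_clamp

    topo, start = build_i27_star(seed=2)
    cfg = SimulationConfig(seed=2, n_steps=400_000, output_stride=1000)
    return run_force_clamp(start, topo, params, cfg), topo, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
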