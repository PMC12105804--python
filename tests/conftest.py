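import numpy as np
import pytest

from tbforge.grid import RadialGrid
from tbforge.structure import from_angstrom
from tbforge.toyparams import generate_toy_parameter_set


@pytest.fixture(scope="session")
def toy_params():
    """Full-pipeline H/O parameter set shared across the engine tests."""
    return generate_toy_parameter_set(("H", "O"), seed=7)


@pytest.fixture(scope="session")
def light_grid():
    return RadialGrid(rmin=1e-8, rmax=40.0, n=500)


@pytest.fixture()
def water():
    return from_angstrom(
        ["O", "H", "H"],
        [[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.2399, 0.9266, 0.0]],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
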