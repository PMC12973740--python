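import numpy as np
import pytest

from mandifrac.synthetic import SynthParams, make_ifs_fractal


@pytest.fixture(scope="session")
def carpet81():
    """Depth-4 Sierpinski carpet on its native 81x81 grid."""
    return make_ifs_fractal(
        SynthParams(seed=0, size=81, model_params={"depth": 4})
    ).pixels


@pytest.fixture(scope="session")
def carpet64():
    """Depth-4 carpet nearest-neighbour rasterized to 64x64."""
    return make_ifs_fractal(
        SynthParams(seed=0, size=64, model_params={"depth": 4})
    ).pixels


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
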