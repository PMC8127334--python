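import numpy as np
import pytest

from mpscat.bench import ToyCrystalSpec, make_toy_crystal


@pytest.fixture(scope="session")
def toy():
    """P2(1)/n planar-amide toy crystal and its synthetic bank."""
    return make_toy_crystal()


@pytest.fixture(scope="session")
def toy_p1():
    return make_toy_crystal(ToyCrystalSpec(symmetry="P1"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
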