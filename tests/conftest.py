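import numpy as np
import pytest
from hypothesis import settings

from symprop import ToyPropellerSpec, make_toy_propeller

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy8():
    """Exact C8 toy propeller (40 residues per blade) plus metadata."""
    spec = ToyPropellerSpec(n_blades=8, residues_per_blade=40, seed=0)
    model, meta = make_toy_propeller(spec)
    return spec, model, meta


@pytest.fixture(scope="session")
def toy4():
    spec = ToyPropellerSpec(n_blades=4, residues_per_blade=24, seed=0)
    model, meta = make_toy_propeller(spec)
    return spec, model, meta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
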