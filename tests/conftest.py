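import numpy as np
import pytest
from hypothesis import settings

from shiftqa import FieldSpec, generate_simt, generate_single_field

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def single_grid():
    """Default single-field scenario: 1 cm target, sigma 2 mm, 1 mm grid."""
    return generate_single_field(FieldSpec(), extent_mm=120.0, spacing_mm=1.0)


@pytest.fixture(scope="session")
def simt_grid():
    """Two 1 cm targets at SI = +-60 mm, 1 mm grid."""
    return generate_simt(extent_mm=240.0, spacing_mm=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
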