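import numpy as np
import pytest

from maffresunet.io_preprocess import preprocess_case, slice_and_filter
from maffresunet.phantom import PhantomSpec, generate_case


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def phantom_case(phantom_spec):
    """One deterministic raw phantom case."""
    return generate_case(phantom_spec, 0)


@pytest.fixture(scope="session")
def preprocessed_case(phantom_case):
    return preprocess_case(phantom_case)


@pytest.fixture(scope="session")
def phantom_slices(preprocessed_case):
    """Tumor-containing 64x64 slices from the preprocessed phantom."""
    return slice_and_filter(preprocessed_case, crop_size=64)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
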