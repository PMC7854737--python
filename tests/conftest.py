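import numpy as np
import pytest

from rdfc.synth import (
    CouplingSpec,
    default_reference_spec,
    generate_epoch,
    generate_reference_set,
)


@pytest.fixture(scope="session")
def ref_spec():
    return default_reference_spec(seed=0)


@pytest.fixture(scope="session")
def ref_set(ref_spec):
    """Reference set built from the six permutations of one synthetic epoch."""
    return generate_reference_set(ref_spec)


@pytest.fixture(scope="session")
def ref_epoch(ref_spec):
    """The epoch the reference set was derived from (300 s at 256 Hz)."""
    return generate_epoch(ref_spec)


@pytest.fixture(scope="session")
def small_epoch():
    """A short three-channel epoch for fast unit tests (20 s at 128 Hz)."""
    spec = CouplingSpec(
        mixing=((1.0, 0.8, 0.0), (1.0, 0.0, 0.6), (0.5, 0.4, 0.4)),
        modulation=(("sin", 0.1, 0.6), "constant", "constant"),
        noise_sd=0.2,
        rate=128.0,
        duration=20.0,
        seed=11,
    )
    return generate_epoch(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
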