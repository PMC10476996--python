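import logging

import numpy as np
import pytest

from oarsort.phantom_factory import PhantomSpec, generate_phantom

logging.getLogger("oarsort").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom():
    """One deterministic default phantom shared across the session."""
    ct, sset, labels = generate_phantom(PhantomSpec(), seed=1, patient_id="fix01")
    return ct, sset, labels


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Reduced phantom for I/O round-trips (fewer slices, fewer organs)."""
    return PhantomSpec(
        shape=(32, 56, 72),
        organs=("bladder", "rectum"),
        nuisance=("ptv",),
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec, seed=3, patient_id="small01")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
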