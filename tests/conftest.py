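import numpy as np
import pytest

from pmdwi import (
    DirectionScheme,
    FIXED_TISSUE,
    SEProtocol,
    SSFPProtocol,
    generate_directions,
)

try:
    from hypothesis import settings

    settings.register_profile("derandomized", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("derandomized")
except ImportError:
    pass


#: implemented high-b DW-SSFP protocol (TE/TR = 28/42 ms, alpha 37, delta 16.7)
@pytest.fixture(scope="session")
def ssfp_hi():
    return SSFPProtocol(TR=42, alpha=37, delta=16.7, G=38)


#: implemented low-b DW-SSFP protocol (spoiler-sized gradient)
@pytest.fixture(scope="session")
def ssfp_lo():
    return SSFPProtocol(TR=27, alpha=37, delta=1.2, G=38)


@pytest.fixture(scope="session")
def se_proto():
    return SEProtocol(TR=530, TE=122, alpha=75, b=4500)


@pytest.fixture(scope="session")
def tissue():
    return FIXED_TISSUE


@pytest.fixture(scope="session")
def dirs54():
    return generate_directions(54, seed=7)


@pytest.fixture(scope="session")
def scheme54_se(dirs54):
    return DirectionScheme(vectors=dirs54.vectors, n_lowb=6)


@pytest.fixture(scope="session")
def scheme54_ssfp(dirs54):
    return DirectionScheme(vectors=dirs54.vectors, n_lowb=30)


#: short-but-adequate chain settings for unit tests (acceptance uses defaults)
@pytest.fixture(scope="session")
def quick_mcmc():
    return dict(burn_in=300, n_samples=500, thin=10)


def unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def angle_deg(a, b):
    return float(np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), -1, 1))))
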