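import numpy as np
import pytest

from handgp import DoseResponseData, GeneratorSpec, HillParams, generate


@pytest.fixture(scope="session")
def greco_like():
    """Noisy mildly synergistic 6x6 checkerboard (classic benchmark design)."""
    data, truth = generate(GeneratorSpec(seed=1))
    return data, truth


@pytest.fixture(scope="session")
def additive_spec():
    return GeneratorSpec(interaction_alpha=0.0, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def hill_inhibitory():
    return HillParams(E0=100.0, Emax=0.0, h=1.5, C=10.0)


def random_dose_data(rng, n=10, dmax=50.0):
    """Random dose set that always includes monotherapy points."""
    d1 = rng.uniform(0, dmax, size=n)
    d2 = rng.uniform(0, dmax, size=n)
    d1[0] = 0.0
    d2[0] = 0.0
    d1[1] = 0.0
    d2[2] = 0.0
    y = rng.normal(50.0, 10.0, size=n)
    return DoseResponseData(d1, d2, y)
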