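import numpy as np
import pytest

import pobds


@pytest.fixture(scope="session")
def p53_dsb0():
    return pobds.load_example_network("p53net_DNAdsb0")


@pytest.fixture(scope="session")
def p53_dsb1():
    return pobds.load_example_network("p53net_DNAdsb1")


@pytest.fixture(scope="session")
def gauss_spec():
    """Well-separated Gaussian observation channel used in the demos."""
    return pobds.GaussianObs(mu0=1.0, sigma0=2.0, mu1=5.0, sigma1=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
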