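import pytest

from lethaltime import datasets as ds


@pytest.fixture(scope="session")
def catfish_coeffs():
    return ds.regression_coeffs(ds.CATFISH)


@pytest.fixture(scope="session")
def tilapia_coeffs():
    return ds.regression_coeffs(ds.TILAPIA)


@pytest.fixture(scope="session")
def atz_chl_catfish():
    """Atrazine-chlorpyrifos mixture spec for catfish (33.95:1)."""
    return ds.mixture_spec(ds.CATFISH, ds.AC)
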