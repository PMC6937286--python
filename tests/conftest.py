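import pytest

from rangeland.fixtures import SyntheticSiteSpec, make_site


@pytest.fixture(scope="session")
def site():
    """Default noise-free synthetic semi-arid site."""
    return make_site(SyntheticSiteSpec())


@pytest.fixture(scope="session")
def clay_site():
    return make_site(SyntheticSiteSpec(soil_preset="clay_loam", seed=7))
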