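import pytest

from irescan import PenaltyConfig, default_registry

# Hand-built perfect canonical core: N7=G, N8=C, upper stem GUUCG/CGAAC,
# loop CAGUGC, N25=C.  Used across the suite as the minimal reference IRE.
PERFECT_CORE = "GCGUUCGCAGUGCCGAACC"


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def cfg():
    return PenaltyConfig()
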