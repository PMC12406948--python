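import pytest
from hypothesis import settings

from mpspec import ExcitationConfig, compute_lod, generate_blanks, get_preset

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cfg():
    """Default acquisition: 25 kHz drive, 25 mT, 64 samples/period, 16 periods."""
    return ExcitationConfig()


@pytest.fixture(scope="session")
def lod():
    return compute_lod(generate_blanks())


@pytest.fixture(scope="session")
def vsop():
    return get_preset("vsop")


@pytest.fixture(scope="session")
def endorem():
    return get_preset("endorem")


@pytest.fixture(scope="session")
def mcp():
    return get_preset("mcp_resovist")


@pytest.fixture(scope="session")
def contaminant():
    return get_preset("contaminant_diet")
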