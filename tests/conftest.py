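import pytest

from tonegap import get_preset


@pytest.fixture(scope="session")
def m1():
    """Hysteresis variant (sustained + inhibitory pathways)."""
    return get_preset("model1")


@pytest.fixture(scope="session")
def m2():
    """Bistable variant (transient pathway only)."""
    return get_preset("model2")


@pytest.fixture(scope="session")
def m3():
    """Combined variant (all pathways)."""
    return get_preset("model3")
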