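import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def null_2arm():
    from platsim import make_fixture

    return make_fixture("null-2arm")


@pytest.fixture
def alt_2arm():
    from platsim import make_fixture

    return make_fixture("alt-2arm")


@pytest.fixture
def platform_3arm():
    from platsim import make_fixture

    return make_fixture("platform-3arm")


@pytest.fixture
def continuous_2arm():
    from platsim import make_fixture

    return make_fixture("continuous-2arm")
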