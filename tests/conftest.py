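import pytest
from hypothesis import HealthCheck, settings

from ggflux import make_toy_model
from ggflux.synthetic_data import ToyModelParams

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_model():
    """Toy photoautotroph with the GG extension, photon bound 100."""
    return make_toy_model()


@pytest.fixture
def base_toy():
    """Toy photoautotroph without the GG extension reactions."""
    return make_toy_model(with_gg_extension=False)


@pytest.fixture
def toy_params():
    return ToyModelParams()
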