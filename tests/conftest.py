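import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150218)  # field campaign date as fixed seed


@pytest.fixture
def faro():
    from benthoflux.synthetic import PRESETS

    return PRESETS["faro_like"]


@pytest.fixture
def chamber_geometry():
    from benthoflux.chamber import ChamberGeometry

    return ChamberGeometry(inner_diameter=19.0, height_readings=(18.0,))
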