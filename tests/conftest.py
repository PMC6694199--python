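import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture
def rng():
    return np.random.default_rng(20170511)


@pytest.fixture(scope="session")
def d7_layout():
    from honeycomb import DesignSpec, generate_layout

    return generate_layout(DesignSpec(7, 6))


@pytest.fixture(scope="session")
def d19_layout():
    from honeycomb import DesignSpec, generate_layout

    return generate_layout(DesignSpec(19, 30, 2.0, 1.8))
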