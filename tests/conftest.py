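import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def acq():
    from flodm.acquisition import AcquisitionSpec

    return AcquisitionSpec()


@pytest.fixture()
def cocaine():
    from flodm import cocaine_preset

    return cocaine_preset()


@pytest.fixture()
def small_phantom():
    """Coarse-voxel phantom small enough for per-test forward renders."""
    from flodm.synthetic import default_phantom

    return default_phantom(shape=(24, 48, 48), voxel_um=6.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
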