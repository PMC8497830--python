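import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mlsfm.optics import SheetModel
from mlsfm.pipeline import default_detection_path

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sheet():
    return SheetModel()


@pytest.fixture(scope="session")
def detection_16x():
    """Detection chain at the signal-detection zoom (1.6x)."""
    return default_detection_path(zoom=1.6, sensor_px=96)


@pytest.fixture(scope="session")
def pipeline_run():
    """One default demo pipeline run shared across tests (seed 0)."""
    from mlsfm.pipeline import run_pipeline

    return run_pipeline(seed=0)
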