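import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fociquant import AnalysisParams, GrayImage

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def gray(arr, name="test.png") -> GrayImage:
    """Wrap an array-like as a GrayImage."""
    return GrayImage(np.asarray(arr, dtype=np.uint8), source_name=name)


def random_gray(rng, shape=(32, 32), name="rand.png") -> GrayImage:
    return gray(rng.integers(0, 256, size=shape, dtype=np.uint8), name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def matched_params():
    """Analysis parameters matched to the synthetic generator's noise-free
    regime: no background floor needed (Otsu separates marker cleanly),
    default nucleus-area window, every focus kept, and a zero adaptive
    offset so perfectly flat background never fires."""
    return AnalysisParams(
        intensity_cutoff=0,
        marker_area_min=1000,
        marker_area_max=2500,
        foci_area_min=1,
        c_offset=0,
    )
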