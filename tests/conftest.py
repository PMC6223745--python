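import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from embryosync import BinnedDistribution, PlateImageSpec, PopulationSpec


@pytest.fixture
def triangular_dist() -> BinnedDistribution:
    """phi = [0, 0.5, 1, 0.5, 0] at centers 0.5 .. 4.5 (delta 1 mm)."""
    return BinnedDistribution(delta=1.0, origin=0.0, counts=[0, 1, 2, 1, 0])


@pytest.fixture
def table1_dispersed_spec() -> PopulationSpec:
    """Bioreactor dispersed population: 3.05 +/- 0.74 mm, n = 1037."""
    return PopulationSpec(mean_length=3.05, sd_length=0.74, n_embryos=1037, label="dispersed")


@pytest.fixture
def small_plate_spec() -> PlateImageSpec:
    return PlateImageSpec(image_height_px=1200, image_width_px=1200, mm_per_px=0.02)
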