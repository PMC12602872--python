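import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chestwall.curve_geometry import Plane, SampledCurve, Side
from chestwall.synthetic_cohort import CohortConfig

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_cohort():
    """A 5-grid-point, 3-vs-2-subject toy cohort with hand-enterable values."""
    grid = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
    left_rows = [
        [0.0, 1.0, 2.0, 3.0, 4.0],
        [0.5, 1.5, 2.5, 3.5, 4.5],
        [1.0, 2.0, 1.0, 2.0, 3.0],
    ]
    right_rows = [
        [0.0, 0.5, 1.0, 1.5, 2.0],
        [1.0, 1.5, 2.0, 2.5, 3.0],
    ]
    left = [
        SampledCurve(f"S{i}", Side.LEFT, Plane.HORIZONTAL, grid, row)
        for i, row in enumerate(left_rows)
    ]
    right = [
        SampledCurve(f"S{i}", Side.RIGHT, Plane.HORIZONTAL, grid, row)
        for i, row in enumerate(right_rows)
    ]
    return grid, left_rows, right_rows, left, right


@pytest.fixture
def grid_only_config():
    """Default study conditions, grid curves only (no dense centerlines)."""
    return CohortConfig(n_subjects=50, include_centerlines=False)
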