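import numpy as np
import pytest

from cspat import (
    FrequencySampling,
    ImageGrid,
    SensorGeometry,
    build_forward_matrix,
)


@pytest.fixture
def small_grid() -> ImageGrid:
    return ImageGrid(nx=4, ny=4, fov_mm=8.0)


@pytest.fixture
def small_operator(small_grid):
    """4x4 grid, 2 sensors, 3 frequencies: dense double-precision build."""
    sensors = SensorGeometry(radius_mm=20.0, span_deg=90.0, count=2)
    freqs = FrequencySampling(grid_size=8, per_angle=3, seed=7)
    return build_forward_matrix(small_grid, sensors, freqs, dtype=np.complex128)


def gaussian_sparse_instance(seed: int, m: int = 40, n: int = 100, k: int = 5):
    """Random Gaussian system with an exactly k-sparse ground truth."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((m, n))
    theta = np.zeros(n)
    theta[rng.choice(n, k, replace=False)] = rng.standard_normal(k)
    return A, theta, A @ theta
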