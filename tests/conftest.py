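import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gifdemons as gd

settings.register_profile(
    "suite",
    max_examples=15,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """Smooth random 12^3 volume with unit spacing."""
    from scipy.ndimage import gaussian_filter

    data = gaussian_filter(rng.random((12, 12, 12)), 1.0, mode="nearest")
    lo, hi = data.min(), data.max()
    return gd.Volume((data - lo) / (hi - lo))


def naive_trilinear(arr, x, y, z):
    """Reference trilinear interpolation with edge clamping."""
    nx, ny, nz = arr.shape
    x = min(max(x, 0.0), nx - 1)
    y = min(max(y, 0.0), ny - 1)
    z = min(max(z, 0.0), nz - 1)
    x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
    x1, y1, z1 = min(x0 + 1, nx - 1), min(y0 + 1, ny - 1), min(z0 + 1, nz - 1)
    fx, fy, fz = x - x0, y - y0, z - z0
    c = 0.0
    for ix, wx in ((x0, 1 - fx), (x1, fx)):
        for iy, wy in ((y0, 1 - fy), (y1, fy)):
            for iz, wz in ((z0, 1 - fz), (z1, fz)):
                c += wx * wy * wz * arr[ix, iy, iz]
    return c
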