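import numpy as np
import pytest

from perfscape import (Domain, GFDesign, QuadraticSurface, flat_surface,
                       saddle_surface, simulate_gf_experiment)


@pytest.fixture
def unit_domain():
    return Domain.unit()


@pytest.fixture
def saddle():
    return saddle_surface()


@pytest.fixture
def flat():
    return flat_surface()


@pytest.fixture
def random_quadratic():
    """Factory for reproducible random quadratic surfaces."""
    def make(seed=0, scale=2.0):
        rng = np.random.default_rng(seed)
        a, b, c, d, e, i = rng.uniform(-scale, scale, 6)
        return QuadraticSurface(a, b, c, d, e, intercept=i)
    return make


@pytest.fixture
def gf_dataset():
    """Simulated GF experiment with known ground truth (mild noise)."""
    design = GFDesign(
        true_surfaces={
            "lifespan": QuadraticSurface(-1.0, -0.5, 1.2, 0.8, 0.6, intercept=2.0),
            "eggs": QuadraticSurface(-0.4, -0.9, 0.5, 1.5, -0.3, intercept=1.0),
        },
        noise_sd=0.1, seed=42)
    return design, simulate_gf_experiment(design)


def finite_difference_patch(height, h=1e-5):
    """Independent numeric partials of a height function by central differences.

    Used as the oracle against the analytic partials stored on a
    SurfacePatch; deliberately knows nothing about the package's
    surface classes.
    """
    def dx(x, y):
        return (height(x + h, y) - height(x - h, y)) / (2 * h)

    def dy(x, y):
        return (height(x, y + h) - height(x, y - h)) / (2 * h)

    def dxx(x, y):
        return (height(x + h, y) - 2 * height(x, y) + height(x - h, y)) / h**2

    def dyy(x, y):
        return (height(x, y + h) - 2 * height(x, y) + height(x, y - h)) / h**2

    def dxy(x, y):
        return (height(x + h, y + h) - height(x + h, y - h)
                - height(x - h, y + h) + height(x - h, y - h)) / (4 * h**2)

    return dx, dy, dxx, dyy, dxy


def brute_force_directed_hausdorff(A, B):
    """O(|A||B|) double-loop directed Hausdorff distance (test oracle)."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    best = 0.0
    for a in A:
        d = np.sqrt(((B - a) ** 2).sum(axis=1)).min()
        best = max(best, d)
    return best
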