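import numpy as np
import pytest

from scarkit import fibers, simulate


@pytest.fixture(scope="session")
def aligned_phantom():
    """Phantom with (numerically) degenerate orientation distribution at 30 deg."""
    spec = simulate.PhantomSpec(kappa=1e6, mean_orientation_deg=30.0, seed=42)
    return simulate.generate_fiber_phantom(spec)


@pytest.fixture(scope="session")
def random_phantom():
    """Phantom with uniform (kappa = 0) axial orientations."""
    spec = simulate.PhantomSpec(kappa=0.0, seed=42)
    return simulate.generate_fiber_phantom(spec)


@pytest.fixture(scope="session")
def small_collagen_map():
    """Irregular 32x32 collagen map for brute-force comparisons."""
    rng = np.random.default_rng(7)
    weight = np.zeros((32, 32))
    # a few short strokes plus salt noise so line-of-sight actually matters
    for _ in range(6):
        y, x = rng.integers(2, 30, size=2)
        dy, dx = rng.integers(-1, 2, size=2)
        for k in range(rng.integers(4, 10)):
            yy, xx = y + k * dy, x + k * dx
            if 0 <= yy < 32 and 0 <= xx < 32:
                weight[yy, xx] = rng.uniform(0.3, 1.0)
    salt = rng.random((32, 32)) < 0.08
    weight[salt] = rng.uniform(0.2, 1.0, size=salt.sum())
    mask = weight > 0
    return fibers.CollagenMap(mask=mask, weight=weight)
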