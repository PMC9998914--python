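import numpy as np
import pytest

from podstar.phantom import PhantomConfig, generate_pod


def voxel_ball(radius: int, pad: int = 3) -> np.ndarray:
    """Boolean voxelized ball centered in its own volume."""
    n = 2 * (radius + pad) + 1
    c = radius + pad
    z, y, x = np.mgrid[:n, :n, :n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius**2


def voxel_ellipsoid(semi_axes, pad: int = 3) -> np.ndarray:
    """Boolean voxelized axis-aligned ellipsoid, semi-axes in (Z,Y,X)."""
    a = np.asarray(semi_axes, dtype=float)
    n = (2 * (a.max() + pad) + 1).astype(int)
    c = (n - 1) / 2.0
    z, y, x = np.mgrid[:n, :n, :n]
    return ((z - c) / a[0]) ** 2 + ((y - c) / a[1]) ** 2 + ((x - c) / a[2]) ** 2 <= 1.0


@pytest.fixture(scope="session")
def small_pod():
    """One deterministic 6-seed pod phantom (image, labels, truth)."""
    cfg = PhantomConfig(n_seeds=6, rng_seed=42)
    return cfg, *generate_pod(cfg)


@pytest.fixture(scope="session")
def ball10():
    return voxel_ball(10)
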