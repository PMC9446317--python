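import numpy as np
import pytest

from lesionmorph import LesionMask, LesionSimConfig, make_lesion_mask


def rasterize_sphere(radius_mm: float, spacing: float, pad_vox: int = 4) -> LesionMask:
    """Voxel-centre rasterization of a sphere, the reference shape for the
    sphericity normalization."""
    n = int(np.ceil(2 * radius_mm / spacing)) + 2 * pad_vox
    centers = (np.arange(n) + 0.5) * spacing
    x, y, z = np.meshgrid(centers, centers, centers, indexing="ij")
    c = n * spacing / 2.0
    data = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_mm**2
    return LesionMask(data, (spacing, spacing, spacing))


def random_blob_mask(seed: int, shape=(14, 14, 14), p: float = 0.2) -> LesionMask:
    """Dense random binary mask for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    return LesionMask(rng.random(shape) < p, (1.0, 1.0, 1.0))


def rotated_cuboid_mask(seed: int, grid: int = 32):
    """Rasterize a solid cuboid rotated about one random coordinate axis.

    Returns (mask, dims_vox, axis, angle_deg); the continuous cuboid volume is
    prod(dims).
    """
    rng = np.random.default_rng(seed)
    dims = rng.integers(5, 15, size=3).astype(float)
    axis = int(rng.integers(3))
    angle = float(rng.uniform(5.0, 85.0))
    a, b = [i for i in range(3) if i != axis]
    rot = np.eye(3)
    c, s = np.cos(np.deg2rad(angle)), np.sin(np.deg2rad(angle))
    rot[a, a], rot[a, b], rot[b, a], rot[b, b] = c, -s, s, c
    centers = np.indices((grid,) * 3).reshape(3, -1).T + 0.5
    local = (centers - grid / 2.0) @ rot  # rotate into the cuboid frame
    inside = np.all(np.abs(local) <= dims / 2.0, axis=1)
    return LesionMask(inside.reshape((grid,) * 3), (1.0, 1.0, 1.0)), dims, axis, angle


@pytest.fixture(scope="session")
def sphere_r10_fine() -> LesionMask:
    """Sphere of radius 10 mm at 0.5 mm isotropic spacing."""
    return rasterize_sphere(10.0, 0.5)


@pytest.fixture()
def simple_lesion():
    mask, truth = make_lesion_mask(LesionSimConfig(n_components=2, seed=7))
    return mask, truth
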