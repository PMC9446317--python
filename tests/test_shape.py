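"""Shape descriptors: closed-form cases, oracle equivalence, invariances."""

import numpy as np
import pytest

import lesionmorph as lm
from lesionmorph.oracles import axis_rotation_obb_volume, flood_fill_count
from lesionmorph.shape import SPHERE_SHAPE_CONSTANT, voxel_corner_points
from scipy.spatial import ConvexHull

from conftest import random_blob_mask, rasterize_sphere, rotated_cuboid_mask


def cube_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return lm.LesionMask(np.ones(shape, dtype=bool), spacing)


class TestComponentLabeling:
    def test_corner_touching_voxels_depend_on_connectivity(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[1, 1, 1] = data[2, 2, 2] = True  # share only a corner
        mask = lm.LesionMask(data, (1.0, 1.0, 1.0))
        assert lm.label_components(mask, connectivity=26).n_components == 1
        assert lm.label_components(mask, connectivity=6).n_components == 2

    def test_two_separated_blobs(self):
        data = np.zeros((12, 12, 12), dtype=bool)
        data[1:4, 1:4, 1:4] = True
        data[7:10, 7:10, 7:10] = True
        mask = lm.LesionMask(data, (1.0, 1.0, 1.0))
        assert lm.label_components(mask).n_components == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        for seed in range(15):
            mask = random_blob_mask(seed)
            got = lm.label_components(mask, connectivity=connectivity).n_components
            assert got == flood_fill_count(mask.data, connectivity)

    def test_volumes_sum_to_total_and_labels_contiguous(self, simple_lesion):
        mask, _ = simple_lesion
        lab = lm.label_components(mask)
        assert np.isclose(lab.component_volumes_mm3.sum(), mask.volume_mm3)
        assert set(np.unique(lab.labels)) == set(range(lab.n_components + 1))
        # deterministic order: label 1 owns the lexicographically first voxel
        first_voxel = tuple(np.argwhere(mask.data)[0])
        assert lab.labels[first_voxel] == 1

    def test_empty_mask_raises(self):
        empty = lm.LesionMask(np.zeros((4, 4, 4), dtype=bool), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="empty"):
            lm.label_components(empty)


class TestVolume:
    def test_unit_conversion(self):
        assert lm.lesion_volume(cube_mask((10, 10, 10))) == pytest.approx(1.0)

    def test_anisotropic_single_voxel(self):
        one = np.zeros((3, 3, 3), dtype=bool)
        one[1, 1, 1] = True
        mask = lm.LesionMask(one, (0.7, 0.7, 3.0))
        assert lm.lesion_volume(mask) == pytest.approx(0.00147)

    def test_axis_permutation_invariance(self, simple_lesion):
        mask, _ = simple_lesion
        v = lm.lesion_volume(mask)
        permuted = lm.LesionMask(np.transpose(mask.data, (2, 0, 1)), mask.spacing_mm)
        assert lm.lesion_volume(permuted) == pytest.approx(v)


class TestSurfaceArea:
    def test_single_voxel_face_count(self):
        one = np.zeros((3, 3, 3), dtype=bool)
        one[1, 1, 1] = True
        mask = lm.LesionMask(one, (1.0, 1.0, 1.0))
        assert lm.surface_area(mask, method="face_count") == pytest.approx(6.0)

    def test_sphere_mesh_within_5_percent(self, sphere_r10_fine):
        true_area = 4 * np.pi * 10.0**2
        area = lm.surface_area(sphere_r10_fine, method="mesh")
        assert abs(area / true_area - 1) < 0.05

    def test_sphere_face_count_digitization_bias(self, sphere_r10_fine):
        # exposed-face counting converges to 3/2 the true area for a sphere
        true_area = 4 * np.pi * 10.0**2
        ratio = lm.surface_area(sphere_r10_fine, method="face_count") / true_area
        assert 1.45 < ratio < 1.55

    def test_unknown_method_rejected(self, simple_lesion):
        with pytest.raises(ValueError, match="method"):
            lm.surface_area(simple_lesion[0], method="voxels")


class TestOrientedBoundingBox:
    def test_axis_aligned_cuboid(self):
        data = np.zeros((14, 9, 6), dtype=bool)
        data[2:12, 2:7, 2:4] = True  # 10 x 5 x 2 voxels
        obb = lm.oriented_bounding_box(lm.LesionMask(data, (1.0, 1.0, 1.0)))
        assert obb.volume_mm3 == pytest.approx(100.0, rel=1e-6)
        assert sorted(obb.extents) == pytest.approx([2.0, 5.0, 10.0], rel=1e-6)

    def test_single_voxel_anisotropic(self):
        one = np.zeros((3, 3, 3), dtype=bool)
        one[1, 1, 1] = True
        obb = lm.oriented_bounding_box(lm.LesionMask(one, (0.7, 0.7, 3.0)))
        assert obb.volume_mm3 == pytest.approx(0.7 * 0.7 * 3.0, rel=1e-6)

    def test_rotated_cuboid_near_oracle(self):
        mask, dims, axis, _ = rotated_cuboid_mask(seed=3)
        obb = lm.oriented_bounding_box(mask)
        pts = voxel_corner_points(mask)
        oracle = axis_rotation_obb_volume(pts, axis, step_deg=1.0)
        assert abs(obb.volume_mm3 / oracle - 1) < 0.01
        # rasterization inflates the box by about one voxel layer per face
        assert obb.volume_mm3 < np.prod(dims + 2.0)

    def test_hull_obb_aabb_sandwich(self):
        for seed in range(8):
            mask, _ = lm.make_lesion_mask(
                lm.LesionSimConfig(grid_shape=(32, 32, 32), n_components=2,
                                   radius_range_mm=(2.0, 4.0), dispersion_mm=8.0,
                                   seed=seed))
            pts = voxel_corner_points(mask)
            hull_vol = ConvexHull(pts).volume
            aabb_vol = np.prod(pts.max(axis=0) - pts.min(axis=0))
            obb_vol = lm.oriented_bounding_box(mask).volume_mm3
            assert hull_vol - 1e-6 <= obb_vol <= aabb_vol + 1e-6

    def test_translation_invariance(self):
        mask, _ = lm.make_lesion_mask(
            lm.LesionSimConfig(grid_shape=(32, 32, 32), radius_range_mm=(3.0, 4.0),
                               dispersion_mm=2.0, seed=5))
        shifted = lm.LesionMask(np.roll(mask.data, (3, -2, 4), axis=(0, 1, 2)),
                                mask.spacing_mm)
        v0 = lm.oriented_bounding_box(mask).volume_mm3
        v1 = lm.oriented_bounding_box(shifted).volume_mm3
        assert v1 == pytest.approx(v0, rel=1e-6)


class TestSphericity:
    def test_continuous_sphere_scores_one(self):
        r = 10.0
        area = 4 * np.pi * r**2
        volume_ml = (4 / 3) * np.pi * r**3 / 1000.0
        assert lm.sphericity(area, volume_ml) == pytest.approx(1.0, abs=1e-9)

    def test_unit_cube_closed_form(self):
        assert lm.sphericity(6.0, 1e-3) == pytest.approx(
            np.sqrt(6.0) / SPHERE_SHAPE_CONSTANT)

    def test_scale_invariance(self):
        s1 = lm.sphericity(123.4, 0.567)
        k = 3.7
        s2 = lm.sphericity(k**2 * 123.4, k**3 * 0.567)
        assert s2 == pytest.approx(s1, rel=1e-12)

    @pytest.mark.parametrize("area,volume", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_non_positive_inputs_rejected(self, area, volume):
        with pytest.raises(ValueError):
            lm.sphericity(area, volume)


class TestShapeDescriptors:
    def test_axis_aligned_cuboid_fills_its_box(self):
        data = np.zeros((12, 10, 8), dtype=bool)
        data[2:10, 2:8, 2:6] = True
        desc = lm.shape_descriptors(lm.LesionMask(data, (1.0, 1.0, 1.0)))
        assert desc.lesion_obb_ratio == pytest.approx(1.0, rel=1e-6)
        assert desc.n_components == 1

    def test_two_distant_voxels_have_tiny_fill_ratio(self):
        data = np.zeros((20, 20, 20), dtype=bool)
        data[2, 2, 2] = data[17, 17, 17] = True
        desc = lm.shape_descriptors(lm.LesionMask(data, (1.0, 1.0, 1.0)))
        assert desc.n_components == 2
        assert desc.lesion_obb_ratio < 0.1
        assert desc.obb_volume_ml > 10 * desc.volume_ml

    def test_fill_ratio_in_unit_interval_over_random_lesions(self):
        rng = np.random.default_rng(42)
        for i in range(40):
            mask, _ = lm.make_lesion_mask(lm.LesionSimConfig(
                grid_shape=(24, 24, 24),
                n_components=int(rng.integers(1, 4)),
                radius_range_mm=(1.5, 3.5),
                dispersion_mm=float(rng.uniform(4, 8)),
                seed=1000 + i))
            desc = lm.shape_descriptors(mask)
            assert 0.0 < desc.lesion_obb_ratio <= 1.0 + 1e-9
            assert desc.obb_volume_ml >= desc.volume_ml * (1 - 1e-9)

    def test_rigid_motion_robustness(self):
        mask, _ = lm.make_lesion_mask(lm.LesionSimConfig(
            grid_shape=(32, 32, 32), n_components=2, radius_range_mm=(2.5, 4.0),
            dispersion_mm=5.0, seed=11))
        base = lm.shape_descriptors(mask)
        rotated = lm.LesionMask(np.rot90(mask.data, k=1, axes=(0, 1)), mask.spacing_mm)
        rot = lm.shape_descriptors(rotated)
        assert rot.n_components == base.n_components
        assert rot.volume_ml == pytest.approx(base.volume_ml)
        assert rot.surface_area_mm2 == pytest.approx(base.surface_area_mm2, rel=1e-3)
        assert rot.obb_volume_ml == pytest.approx(base.obb_volume_ml, rel=1e-3)

    def test_obb_volume_monotone_in_dispersion(self):
        # larger scatter of the same blobs can only need a bigger box
        for seed in (0, 1, 2):
            volumes = []
            for dispersion in (4.0, 10.0, 22.0):
                mask, _ = lm.make_lesion_mask(lm.LesionSimConfig(
                    grid_shape=(96, 96, 96), n_components=3,
                    radius_range_mm=(3.0, 3.0), dispersion_mm=dispersion,
                    seed=seed))
                volumes.append(lm.oriented_bounding_box(mask).volume_mm3)
            assert volumes[0] <= volumes[1] * (1 + 1e-9)
            assert volumes[1] <= volumes[2] * (1 + 1e-9)
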