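import math

import numpy as np
import pytest

from surfdice import (
    BinaryMask,
    GridSpacing,
    ISOTROPIC_1MM,
    LabeledRegion,
    SparseCase,
    make_multi_cube_pair,
    make_phantom,
    make_sparse_labeling,
    sparse_volumetric_dsc,
    surface_dsc,
    volumetric_dsc,
)
from surfdice.grid_masks import ShapeMismatchError
from surfdice.phantom_fixtures import PhantomSpec

from conftest import random_mask


def cube_mask(origin, size=2, shape=(10, 10, 10)):
    grid = np.zeros(shape, dtype=bool)
    grid[
        origin[0] : origin[0] + size,
        origin[1] : origin[1] + size,
        origin[2] : origin[2] + size,
    ] = True
    return BinaryMask(grid, ISOTROPIC_1MM)


class TestVolumetricDsc:
    def test_identical_masks_score_one(self):
        m = cube_mask((2, 2, 2))
        assert volumetric_dsc(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        assert volumetric_dsc(cube_mask((1, 1, 1)), cube_mask((6, 6, 6))) == 0.0

    def test_shifted_cube_overlap(self):
        # 2^3 cube shifted 1 voxel: 4 shared voxels of 8+8
        a = cube_mask((3, 3, 3))
        b = cube_mask((4, 3, 3))
        assert volumetric_dsc(a, b) == pytest.approx(0.5)

    def test_both_empty_is_undefined(self):
        e = BinaryMask(np.zeros((4, 4, 4)), ISOTROPIC_1MM)
        assert math.isnan(volumetric_dsc(e, e))

    def test_grid_mismatch_rejected(self):
        a = BinaryMask(np.zeros((4, 4, 4)), ISOTROPIC_1MM)
        b = BinaryMask(np.zeros((4, 4, 5)), ISOTROPIC_1MM)
        with pytest.raises(ShapeMismatchError):
            volumetric_dsc(a, b)


class TestSparseVolumetricDsc:
    def test_full_labeling_reduces_to_dense_dsc(self):
        ref = make_phantom(
            PhantomSpec(kind="sphere", grid_shape=(20, 20, 20), radius_mm=6.0)
        )
        pred = cube_mask((7, 7, 7), size=6, shape=(20, 20, 20))
        sparse_ref, labeled = make_sparse_labeling(ref, range(20))
        case = SparseCase(reference=sparse_ref, labeled=labeled, prediction=pred)
        assert sparse_volumetric_dsc([case]) == pytest.approx(
            volumetric_dsc(ref, pred), abs=0
        )

    def test_two_slice_cases_pool_before_dividing(self):
        # per case: |ref ∩ L| = 10, |pred ∩ L| = 10, intersection 5
        def build_case():
            shape = (6, 10, 4)
            ref = np.zeros(shape, dtype=bool)
            pred = np.zeros(shape, dtype=bool)
            labeled = np.zeros(shape, dtype=bool)
            labeled[:, :, 2] = True
            ref[0, 0:10, 2] = True
            pred[0, 5:10, 2] = True  # 5 shared
            pred[1, 0:5, 2] = True  # 5 labeled, nonoverlapping
            pred[1, 0:5, 0] = True  # unlabeled, must be ignored
            return SparseCase(
                reference=BinaryMask(ref, ISOTROPIC_1MM),
                labeled=LabeledRegion(labeled),
                prediction=BinaryMask(pred, ISOTROPIC_1MM),
            )

        assert sparse_volumetric_dsc([build_case(), build_case()]) == pytest.approx(
            0.5
        )

    def test_empty_predictions_score_zero(self):
        shape = (4, 4, 4)
        labeled = np.ones(shape, dtype=bool)
        ref = np.zeros(shape, dtype=bool)
        ref[1, 1, 1] = True
        case = SparseCase(
            reference=BinaryMask(ref, ISOTROPIC_1MM),
            labeled=LabeledRegion(labeled),
            prediction=BinaryMask(np.zeros(shape), ISOTROPIC_1MM),
        )
        assert sparse_volumetric_dsc([case]) == 0.0

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            sparse_volumetric_dsc([])

    def test_reference_outside_labeled_region_rejected(self):
        shape = (4, 4, 4)
        ref = np.ones(shape, dtype=bool)
        with pytest.raises(ValueError):
            SparseCase(
                reference=BinaryMask(ref, ISOTROPIC_1MM),
                labeled=LabeledRegion(np.zeros(shape)),
                prediction=BinaryMask(np.zeros(shape), ISOTROPIC_1MM),
            )


class TestSurfaceDsc:
    def test_mask_against_itself_is_perfect(self, table_1mm):
        m = make_phantom(
            PhantomSpec(kind="sphere", grid_shape=(30, 30, 30), radius_mm=9.0)
        )
        res = surface_dsc(m, m, 1.0, table=table_1mm)
        assert res.value == 1.0
        assert res.overlap_area_1 == res.area_1

    def test_far_apart_masks_score_zero(self, table_1mm):
        shape = (61, 9, 9)
        a = BinaryMask(np.zeros(shape), ISOTROPIC_1MM)
        b = BinaryMask(np.zeros(shape), ISOTROPIC_1MM)
        ga, gb = a.grid.copy(), b.grid.copy()
        ga[2:7, 2:7, 2:7] = True
        gb[52:57, 2:7, 2:7] = True
        res = surface_dsc(
            BinaryMask(ga, ISOTROPIC_1MM), BinaryMask(gb, ISOTROPIC_1MM), 1.0,
            table=table_1mm,
        )
        assert res.value == 0.0

    def test_single_displaced_cube_of_twenty_scores_095(self, table_1mm):
        a, b = make_multi_cube_pair(n_cubes=20, displaced=1)
        res = surface_dsc(a, b, 1.0, table=table_1mm)
        assert res.value == pytest.approx(0.95, abs=1e-12)

    def test_slab_offset_score_grows_with_tolerance(self, table_1mm):
        shape = (30, 12, 12)
        base = make_phantom(
            PhantomSpec(kind="slab", grid_shape=shape, axis=0, start_vox=10,
                        thickness_vox=5)
        )
        offset = make_phantom(
            PhantomSpec(kind="slab", grid_shape=shape, axis=0, start_vox=12,
                        thickness_vox=5)
        )
        at1 = surface_dsc(base, offset, 1.0, table=table_1mm).value
        at2 = surface_dsc(base, offset, 2.0, table=table_1mm).value
        assert at2 > at1
        # the dominant flat faces are exactly 2 mm apart
        assert at2 > 0.9

    def test_one_empty_mask_scores_zero(self, table_1mm):
        m = cube_mask((3, 3, 3))
        e = BinaryMask(np.zeros((10, 10, 10)), ISOTROPIC_1MM)
        res = surface_dsc(m, e, 2.0, table=table_1mm)
        assert res.value == 0.0
        assert res.defined

    def test_both_empty_is_undefined(self, table_1mm):
        e = BinaryMask(np.zeros((6, 6, 6)), ISOTROPIC_1MM)
        res = surface_dsc(e, e, 1.0, table=table_1mm)
        assert not res.defined
        assert math.isnan(res.value)

    def test_negative_tolerance_rejected(self, table_1mm):
        m = cube_mask((3, 3, 3))
        with pytest.raises(ValueError):
            surface_dsc(m, m, -0.5, table=table_1mm)

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_symmetry_bounds_and_overlap_accounting(self, table_1mm, seed):
        a = random_mask(seed, shape=(10, 10, 10), p=0.3)
        b = random_mask(seed + 100, shape=(10, 10, 10), p=0.3)
        r_ab = surface_dsc(a, b, 1.5, table=table_1mm)
        r_ba = surface_dsc(b, a, 1.5, table=table_1mm)
        assert r_ab.value == r_ba.value
        assert 0.0 <= r_ab.value <= 1.0
        assert 0.0 <= r_ab.overlap_area_1 <= r_ab.area_1
        assert 0.0 <= r_ab.overlap_area_2 <= r_ab.area_2

    def test_monotone_in_tolerance_and_saturates_at_diagonal(self, table_1mm):
        a = random_mask(21, shape=(12, 12, 12), p=0.25)
        b = random_mask(22, shape=(12, 12, 12), p=0.25)
        taus = [0.0, 0.5, 1.0, 2.0, 4.0]
        values = [surface_dsc(a, b, t, table=table_1mm).value for t in taus]
        assert all(v1 <= v2 + 1e-12 for v1, v2 in zip(values, values[1:]))
        diag = float(np.sqrt(3) * 13)  # raster physical diagonal, generous
        assert surface_dsc(a, b, diag, table=table_1mm).value == 1.0

    def test_joint_translation_invariance(self, table_1mm):
        a = random_mask(31, shape=(7, 7, 7), p=0.4)
        b = random_mask(32, shape=(7, 7, 7), p=0.4)
        big = np.zeros((14, 14, 14), dtype=bool)

        def embed(grid, shift):
            out = big.copy()
            out[
                shift[0] : shift[0] + 7,
                shift[1] : shift[1] + 7,
                shift[2] : shift[2] + 7,
            ] = grid
            return BinaryMask(out, ISOTROPIC_1MM)

        v0 = surface_dsc(
            embed(a.grid, (0, 0, 0)), embed(b.grid, (0, 0, 0)), 1.0,
            table=table_1mm,
        )
        v1 = surface_dsc(
            embed(a.grid, (5, 3, 6)), embed(b.grid, (5, 3, 6)), 1.0,
            table=table_1mm,
        )
        assert v1.value == pytest.approx(v0.value, abs=1e-12)
        assert volumetric_dsc(
            embed(a.grid, (5, 3, 6)), embed(b.grid, (5, 3, 6))
        ) == volumetric_dsc(embed(a.grid, (0, 0, 0)), embed(b.grid, (0, 0, 0)))
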