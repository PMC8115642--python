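"""ROI enumeration, max-WI search, Feret diameter and shrinkage proxy."""

import numpy as np
import pytest

from _oracles import brute_best_wi, brute_placement_count
from dcewash.errors import EmptyLesionError, GridMismatchError, NoPlacementError
from dcewash.kinetics import CurveClass
from dcewash.lesion_image import (
    LesionMask,
    Phase,
    PhaseVolume,
    RoiPlacement,
    ShrinkagePattern,
    classify_shrinkage,
    enumerate_roi_placements,
    lesion_max_wi,
    load_mask,
    load_phase_volume,
    longest_diameter,
    roi_mean_signal,
    save_volume,
)
from dcewash.synthetic_data import random_phantom_spec, simulate_phantom

ISO = (1.0, 1.0, 1.0)


def _mask(arr, spacing=ISO):
    return LesionMask(data=np.asarray(arr, dtype=bool), spacing=spacing)


def _vol(arr, phase=Phase.PRE, spacing=ISO):
    return PhaseVolume(data=np.asarray(arr, dtype=float), spacing=spacing, phase=phase)


def _ball_mask(shape, center, radius, spacing=ISO):
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


class TestEnumeratePlacements:
    def test_single_voxel_lesion_cannot_host_3mm_disc(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        with pytest.raises(NoPlacementError):
            enumerate_roi_placements(_mask(m))

    def test_voxel_fallback_for_tiny_lesion(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        placements = enumerate_roi_placements(_mask(m), fallback="voxel")
        assert len(placements) == 1
        assert placements[0].member_voxels == ((2, 2, 2),)

    def test_empty_mask_signals_empty_lesion(self):
        with pytest.raises(EmptyLesionError):
            enumerate_roi_placements(_mask(np.zeros((4, 4, 4), bool)))

    def test_cuboid_count_matches_brute_force(self):
        m = np.zeros((13, 13, 5), bool)
        m[1:12, 1:12, 1:4] = True  # solid 11 x 11 x 3 cuboid
        placements = enumerate_roi_placements(_mask(m), planes="all")
        assert len(placements) == brute_placement_count(m, ISO, 3.0, planes="all")
        placements_ax = enumerate_roi_placements(_mask(m), planes="axial")
        assert len(placements_ax) == brute_placement_count(m, ISO, 3.0, planes="axial")

    def test_sphere_placements_fully_contained(self):
        m = _ball_mask((25, 25, 25), (12, 12, 12), 10.0)
        placements = enumerate_roi_placements(_mask(m))
        assert placements
        for p in placements[:: max(1, len(placements) // 50)]:
            for i, j, k in p.member_voxels:
                assert m[i, j, k]

    def test_members_within_radius_of_center(self):
        m = _ball_mask((20, 20, 20), (10, 10, 10), 8.0)
        spacing = (1.0, 0.8, 1.2)
        placements = enumerate_roi_placements(_mask(m, spacing), diameter=3.0)
        p = placements[0]
        r_ax, c_ax = [a for a in range(3) if a != p.plane_axis]
        for vox in p.member_voxels:
            d = np.hypot(
                vox[r_ax] * spacing[r_ax] - p.center[0],
                vox[c_ax] * spacing[c_ax] - p.center[1],
            )
            assert d <= 1.5 + 1e-9

    def test_deterministic_ordering(self):
        m = _ball_mask((15, 15, 15), (7, 7, 7), 5.0)
        a = enumerate_roi_placements(_mask(m))
        b = enumerate_roi_placements(_mask(m))
        keys = [(p.plane_axis, p.slice_index, *p.center) for p in a]
        assert keys == sorted(keys)
        assert a == b


class TestRoiMeanSignal:
    def test_constant_volume(self):
        m = _ball_mask((12, 12, 12), (6, 6, 6), 4.0)
        p = enumerate_roi_placements(_mask(m))[0]
        vol = _vol(np.full((12, 12, 12), 7.0))
        assert roi_mean_signal(vol, p) == pytest.approx(7.0)

    def test_two_voxel_placement(self):
        p = RoiPlacement(0, 1, (1.0, 1.0), ((1, 1, 1), (1, 1, 2)))
        data = np.zeros((3, 3, 3))
        data[1, 1, 1], data[1, 1, 2] = 10.0, 20.0
        assert roi_mean_signal(_vol(data), p) == pytest.approx(15.0)

    def test_gradient_volume_matches_direct_summation(self, rng):
        m = _ball_mask((16, 16, 16), (8, 8, 8), 6.0)
        data = rng.normal(100, 10, size=(16, 16, 16))
        vol = _vol(data)
        for p in enumerate_roi_placements(_mask(m))[::37]:
            expected = sum(data[v] for v in p.member_voxels) / len(p.member_voxels)
            assert roi_mean_signal(vol, p) == pytest.approx(expected, rel=1e-12)

    def test_out_of_grid_placement_rejected(self):
        p = RoiPlacement(0, 0, (0.0, 0.0), ((0, 0, 5),))
        with pytest.raises(IndexError):
            roi_mean_signal(_vol(np.zeros((3, 3, 3))), p)


class TestLesionMaxWi:
    def test_planted_washout_nodule_recovered(self, washout_phantom):
        pre, early, delay, mask, truth = washout_phantom
        lk = lesion_max_wi(pre, early, delay, mask)
        assert truth.recoverable
        assert lk.best_result.wi == pytest.approx(truth.planted_max_wi, abs=1e-6)
        assert lk.best_result.curve_class is CurveClass.FAST_WASHOUT
        # winning ROI sits inside the planted nodule (radius 4 mm at center)
        center_mm = np.array([14.0, 14.0, 14.0])
        for vox in lk.best_placement.member_voxels:
            assert np.linalg.norm(np.array(vox) - center_mm) <= 4.0 + 1e-9

    def test_uniform_enhancement_equals_voxelwise_wi(self):
        shape = (14, 14, 14)
        m = _ball_mask(shape, (7, 7, 7), 5.0)
        pre = _vol(np.full(shape, 100.0), Phase.PRE)
        early = _vol(np.full(shape, 250.0), Phase.EARLY)
        delay = _vol(np.full(shape, 230.0), Phase.DELAY)
        lk = lesion_max_wi(pre, early, delay, _mask(m))
        assert lk.best_result.wi == pytest.approx(20.0, abs=1e-9)
        assert lk.n_placements == len(enumerate_roi_placements(_mask(m)))

    @pytest.mark.parametrize("seed", [3, 17, 42])
    def test_equals_brute_force_on_random_phantoms(self, seed):
        spec = random_phantom_spec(seed, max_side=24)
        pre, early, delay, mask, _ = simulate_phantom(spec)
        lk = lesion_max_wi(pre, early, delay, mask)
        best, n = brute_best_wi(
            pre.data, early.data, delay.data, mask.data, spec.spacing, 3.0
        )
        assert lk.best_result.wi == pytest.approx(best, abs=1e-9)
        assert lk.n_placements == n

    def test_grid_mismatch_names_axis(self):
        m = _mask(np.ones((6, 6, 6), bool))
        pre = _vol(np.ones((6, 6, 6)), Phase.PRE)
        early = _vol(np.ones((6, 6, 5)), Phase.EARLY)
        delay = _vol(np.ones((6, 6, 6)), Phase.DELAY)
        with pytest.raises(GridMismatchError, match="axis 2"):
            lesion_max_wi(pre, early, delay, m)

    def test_nonpositive_pre_placements_skipped(self):
        shape = (10, 10, 10)
        m = np.zeros(shape, bool)
        m[2:8, 2:8, 2:8] = True
        pre_data = np.full(shape, -1.0)
        pre_data[2:8, 2:8, 5:8] = 100.0  # only one side usable
        pre = _vol(pre_data, Phase.PRE)
        early = _vol(np.full(shape, 250.0), Phase.EARLY)
        delay = _vol(np.full(shape, 230.0), Phase.DELAY)
        lk = lesion_max_wi(pre, early, delay, _mask(m))
        assert lk.best_sample.si_pre > 0


class TestLongestDiameter:
    def test_empty_and_single_voxel(self):
        assert longest_diameter(_mask(np.zeros((4, 4, 4), bool))) == 0.0
        m = np.zeros((4, 4, 4), bool)
        m[1, 2, 3] = True
        assert longest_diameter(_mask(m)) == 0.0

    def test_box_in_plane_diagonal(self):
        m = np.zeros((32, 12, 12), bool)
        m[1:31, 1:11, 1:11] = True  # 30 x 10 x 10 voxels
        # best single-slice span: 29 x 9 mm center-to-center
        assert longest_diameter(_mask(m)) == pytest.approx(np.hypot(29, 9))

    def test_matches_bruteforce_pairwise_oracle(self, rng):
        m = rng.random((9, 9, 9)) < 0.2
        spacing = (1.0, 0.7, 1.3)
        best = 0.0
        for ax in range(3):
            r_ax, c_ax = [a for a in range(3) if a != ax]
            sp = np.array([spacing[r_ax], spacing[c_ax]])
            for s in range(m.shape[ax]):
                pts = np.argwhere(np.take(m, s, axis=ax)) * sp
                for i in range(len(pts)):
                    for j in range(i + 1, len(pts)):
                        best = max(best, float(np.linalg.norm(pts[i] - pts[j])))
        assert longest_diameter(_mask(m, spacing)) == pytest.approx(best)

    def test_translation_and_axis_permutation_invariance(self):
        m = np.zeros((20, 20, 20), bool)
        m[2:8, 3:12, 4:9] = True
        d0 = longest_diameter(_mask(m))
        shifted = np.roll(m, (5, 2, 6), axis=(0, 1, 2))
        assert longest_diameter(_mask(shifted)) == pytest.approx(d0)
        perm = np.transpose(m, (2, 0, 1))
        assert longest_diameter(_mask(perm)) == pytest.approx(d0)

    def test_monotone_under_dilation(self):
        from scipy import ndimage

        m = _ball_mask((20, 20, 20), (10, 10, 10), 4.0)
        d0 = longest_diameter(_mask(m))
        dil = ndimage.binary_dilation(m, iterations=2)
        assert longest_diameter(_mask(dil)) >= d0


class TestShrinkage:
    def test_concentric_smaller_sphere(self):
        base = _ball_mask((30, 30, 30), (15, 15, 15), 10.0)
        follow = _ball_mask((30, 30, 30), (15, 15, 15), 5.0)
        assert (
            classify_shrinkage(_mask(base), _mask(follow))
            is ShrinkagePattern.CONCENTRIC
        )

    def test_fragmentation_is_dendritic(self):
        base = _ball_mask((30, 30, 30), (15, 15, 15), 10.0)
        follow = np.zeros_like(base)
        for c in [(10, 10, 15), (20, 18, 15), (14, 20, 12)]:
            follow |= _ball_mask((30, 30, 30), c, 2.0)
        assert (
            classify_shrinkage(_mask(base), _mask(follow))
            is ShrinkagePattern.DENDRITIC
        )

    def test_boundary_crescent_is_dendritic(self):
        base = _ball_mask((30, 30, 30), (15, 15, 15), 10.0)
        shell = base & ~_ball_mask((30, 30, 30), (15, 15, 15), 8.5)
        crescent = shell.copy()
        crescent[:, :, :15] = False  # keep one side of the rim only
        assert (
            classify_shrinkage(_mask(base), _mask(crescent))
            is ShrinkagePattern.DENDRITIC
        )

    def test_empty_followup_is_cr_not_pr(self):
        base = _ball_mask((10, 10, 10), (5, 5, 5), 3.0)
        with pytest.raises(EmptyLesionError):
            classify_shrinkage(_mask(base), _mask(np.zeros_like(base)))


class TestNiftiIo:
    def test_roundtrip_volume_and_mask(self, tmp_path):
        data = np.arange(60, dtype=float).reshape(3, 4, 5)
        spacing = (1.0, 1.5, 2.0)
        save_volume(tmp_path / "v.nii.gz", data, spacing)
        vol = load_phase_volume(tmp_path / "v.nii.gz", Phase.EARLY)
        assert np.allclose(vol.data, data)
        assert vol.spacing == pytest.approx(spacing)
        save_volume(tmp_path / "m.nii.gz", data > 30, spacing)
        m = load_mask(tmp_path / "m.nii.gz")
        assert np.array_equal(m.data, data > 30)
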