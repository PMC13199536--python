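"""Segmentation agreement metrics against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from vfr.image import SegmentationMask
from vfr.mask_metrics import cross_sectional_area, dice_coefficient, \
    hausdorff_distance, mean_surface_distance, median_smooth_mask, \
    pairwise_geometric_summary, relative_volume_difference, surface_points

SP = 0.6


def _mask(data):
    return SegmentationMask(np.asarray(data, bool), (SP, SP, SP))


def _brute_surface(data):
    """Independent surface extraction: explicit face-neighbour check."""
    padded = np.pad(np.asarray(data, bool), 1)
    pts = []
    for i, j, k in np.argwhere(padded):
        neighbours = [padded[i - 1, j, k], padded[i + 1, j, k],
                      padded[i, j - 1, k], padded[i, j + 1, k],
                      padded[i, j, k - 1], padded[i, j, k + 1]]
        if not all(neighbours):
            pts.append((i - 1, j - 1, k - 1))
    return (np.asarray(pts) + 0.5) * SP


def _brute_msd_hd(a, b):
    pa, pb = _brute_surface(a), _brute_surface(b)
    d = cdist(pa, pb)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    msd = 0.5 * (d_ab.mean() + d_ba.mean())
    hd = max(d_ab.max(), d_ba.max())
    return msd, hd


def _random_mask(rng, shape=(14, 14, 14)):
    """Random connected-ish blob: union of a few balls."""
    ax = [np.arange(n) for n in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    out = np.zeros(shape, bool)
    for _ in range(rng.integers(1, 4)):
        c = rng.uniform(3, np.array(shape) - 3)
        r = rng.uniform(2, 4.5)
        out |= (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r ** 2
    return out


class TestVolumeMetrics:
    def test_rvd_direct_arithmetic(self):
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros((12, 12, 12), bool)
        a.flat[:1100] = True
        b.flat[:1000] = True
        assert relative_volume_difference(_mask(a), _mask(b)) == \
            pytest.approx(0.10)
        # asymmetric: reference is the second argument
        assert relative_volume_difference(_mask(b), _mask(a)) == \
            pytest.approx(100 / 1100)

    def test_rvd_identity_and_empty_reference(self):
        a = _mask(np.ones((3, 3, 3)))
        assert relative_volume_difference(a, a) == 0.0
        with pytest.raises(ValueError):
            relative_volume_difference(a, _mask(np.zeros((3, 3, 3))))

    def test_dice_limits_and_half_overlap(self):
        a = np.zeros((20, 12, 12), bool)
        b = np.zeros((20, 12, 12), bool)
        a[0:10, 1:11, 1:11] = True                 # 10^3 cube
        b[5:15, 1:11, 1:11] = True                 # shifted by half
        assert dice_coefficient(_mask(a), _mask(a)) == 1.0
        assert dice_coefficient(_mask(a), _mask(b)) == pytest.approx(0.5)
        c = np.zeros((20, 12, 12), bool)
        c[15:18, 0:3, 0:3] = True
        assert dice_coefficient(_mask(a), _mask(c)) == 0.0
        with pytest.raises(ValueError):
            dice_coefficient(_mask(np.zeros((2, 2, 2))),
                             _mask(np.zeros((2, 2, 2))))

    def test_dice_nested_masks_counting_formula(self):
        rng = np.random.default_rng(4)
        b = _random_mask(rng)
        a = b.copy()
        a[tuple(np.argwhere(b)[::3].T)] = False    # a strict subset of b
        expected = 2 * a.sum() / (a.sum() + b.sum())
        assert dice_coefficient(_mask(a), _mask(b)) == pytest.approx(expected)


class TestSurfaces:
    def test_cube_surface_voxel_count(self):
        data = np.zeros((7, 7, 7), bool)
        data[2:5, 2:5, 2:5] = True
        assert len(surface_points(_mask(data))) == 26

    def test_single_voxel(self):
        data = np.zeros((5, 5, 5), bool)
        data[2, 2, 2] = True
        pts = surface_points(_mask(data))
        assert pts.shape == (1, 3)
        assert np.allclose(pts[0], (2.5 * SP, 2.5 * SP, 2.5 * SP))

    def test_interior_never_listed(self):
        data = np.zeros((9, 9, 9), bool)
        data[2:7, 2:7, 2:7] = True
        pts = surface_points(_mask(data))
        center = np.array([4.5, 4.5, 4.5]) * SP
        assert not np.any(np.all(np.isclose(pts, center), axis=1))
        assert len(pts) == 5 ** 3 - 3 ** 3

    def test_volume_border_counts_as_surface(self):
        data = np.ones((4, 4, 4), bool)
        # all but the 2^3 interior voxels touch the volume border
        assert len(surface_points(_mask(data))) == 4 ** 3 - 2 ** 3


class TestDistances:
    def test_identity_zero(self):
        rng = np.random.default_rng(0)
        a = _mask(_random_mask(rng))
        assert mean_surface_distance(a, a) == 0.0
        assert hausdorff_distance(a, a) == 0.0

    def test_dilated_cube_matches_brute_force(self):
        from scipy import ndimage
        a = np.zeros((14, 14, 14), bool)
        a[4:10, 4:10, 4:10] = True
        b = ndimage.binary_dilation(a)
        msd_o, hd_o = _brute_msd_hd(a, b)
        assert mean_surface_distance(_mask(a), _mask(b)) == \
            pytest.approx(msd_o, abs=1e-12)
        assert hausdorff_distance(_mask(a), _mask(b)) == \
            pytest.approx(hd_o, abs=1e-12)

    def test_spike_sets_hausdorff(self):
        k = 4
        a = np.zeros((20, 10, 10), bool)
        a[2:8, 2:8, 2:8] = True
        b = a.copy()
        b[8:8 + k, 4, 4] = True                    # protruding spike
        assert hausdorff_distance(_mask(a), _mask(b)) == \
            pytest.approx(k * SP, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_pairs_match_brute_force(self, seed):
        """Distance-transform metrics equal the O(n^2) oracle to 1e-9 mm."""
        rng = np.random.default_rng(seed)
        a, b = _random_mask(rng), _random_mask(rng)
        msd_o, hd_o = _brute_msd_hd(a, b)
        assert mean_surface_distance(_mask(a), _mask(b)) == \
            pytest.approx(msd_o, abs=1e-9)
        assert hausdorff_distance(_mask(a), _mask(b)) == \
            pytest.approx(hd_o, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        a, b = _mask(_random_mask(rng)), _mask(_random_mask(rng))
        assert mean_surface_distance(a, b) == mean_surface_distance(b, a)
        assert hausdorff_distance(a, b) == hausdorff_distance(b, a)

    def test_hd_bounds_msd(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            a, b = _mask(_random_mask(rng)), _mask(_random_mask(rng))
            assert hausdorff_distance(a, b) >= mean_surface_distance(a, b)


class TestMedianSmoothing:
    def test_solid_cube_interior_and_faces_unchanged(self):
        """Median of a uniform region is the identity away from edges."""
        data = np.zeros((20, 20, 20), bool)
        data[4:16, 4:16, 4:16] = True
        out = median_smooth_mask(_mask(data), 3.0)
        # interior (2 voxels in from the cube surface) fully preserved
        assert out.data[6:14, 6:14, 6:14].all()
        # face centres preserved; far background stays empty
        assert out.data[10, 10, 15] and out.data[10, 10, 4]
        assert not out.data[:2].any() and not out.data[:, :, 18:].any()
        # only the cube edges/corners may be rounded off: every changed
        # voxel sits within 2 voxels of a cube edge (two near-face coords);
        # face centres and the interior are untouched
        changed = np.argwhere(out.data ^ data)
        near_face = np.isin(changed, (4, 5, 14, 15)).sum(axis=1)
        assert (near_face >= 2).all()

    def test_isolated_voxel_removed(self):
        data = np.zeros((11, 11, 11), bool)
        data[5, 5, 5] = True
        out = median_smooth_mask(_mask(data), 3.0)
        assert not out.data.any()

    def test_surface_pit_filled_matches_brute_force(self):
        """One-voxel pit on a flat face: compare with explicit 5^3 median."""
        data = np.zeros((16, 16, 16), bool)
        data[3:13, 3:13, 3:9] = True
        data[8, 8, 8] = False                      # pit in the top face
        out = median_smooth_mask(_mask(data), 3.0)   # w = round(3/0.6) = 5
        padded = np.pad(data, 2, mode="reflect")
        expected = np.median(
            np.lib.stride_tricks.sliding_window_view(padded, (5, 5, 5)),
            axis=(3, 4, 5)) > 0.5
        assert np.array_equal(out.data, expected)
        assert out.data[8, 8, 8]                   # the pit is gone

    def test_sub_voxel_kernel_is_identity(self):
        data = np.zeros((8, 8, 8), bool)
        data[3, 3, 3] = True
        with pytest.warns(UserWarning):
            out = median_smooth_mask(_mask(data), 0.5)
        assert np.array_equal(out.data, data)


class TestCSA:
    def test_elliptic_cylinder_area(self, small_phantom):
        import math

        from vfr.phantoms import PhantomGeometry, make_vertebra_phantom
        csa = cross_sectional_area(small_phantom.mask)
        assert csa == pytest.approx(small_phantom.csa_mm2, rel=0.02)
        straight = make_vertebra_phantom(
            PhantomGeometry(a=20, b=15, height=20, waist=0.0), spacing=0.6)
        assert cross_sectional_area(straight.mask) == \
            pytest.approx(math.pi * 20 * 15, rel=0.02)

    def test_axis_aligned_cuboid_exact(self):
        data = np.zeros((20, 20, 30), bool)
        data[2:12, 2:12, 5:25] = True
        m = SegmentationMask(data, (1.0, 1.0, 1.0))
        assert cross_sectional_area(m) == pytest.approx(100.0, abs=1e-12)

    def test_band_exclusion_neutral_on_uniform_cylinder(self):
        data = np.zeros((20, 20, 30), bool)
        data[2:12, 2:12, 5:25] = True
        m = SegmentationMask(data, (1.0, 1.0, 1.0))
        assert cross_sectional_area(m, endplate_fraction=0.0) == \
            cross_sectional_area(m, endplate_fraction=0.2)

    def test_too_few_slices_rejected(self):
        data = np.zeros((10, 10, 4), bool)
        data[2:8, 2:8, 1:3] = True
        with pytest.raises(ValueError):
            cross_sectional_area(SegmentationMask(data, (1, 1, 1)))


class TestPairwiseSummary:
    def test_identical_masks_zero_spread(self):
        rng = np.random.default_rng(2)
        m = _mask(_random_mask(rng))
        rep = pairwise_geometric_summary([m, m, m], "intra", smooth=False)
        assert len(rep.per_pair) == 3
        assert rep.mean["dc"] == 1.0
        assert rep.mean["rvd"] == rep.mean["msd_mm"] == rep.mean["hd_mm"] == 0
        assert all(v == 0 for v in rep.sd.values())

    def test_mean_sd_match_per_pair_table(self):
        rng = np.random.default_rng(7)
        masks = [_mask(_random_mask(rng)) for _ in range(3)]
        rep = pairwise_geometric_summary(masks, "inter", smooth=False)
        for m in ("rvd", "dc", "msd_mm", "hd_mm"):
            assert rep.mean[m] == pytest.approx(rep.per_pair[m].mean())
            assert rep.sd[m] == pytest.approx(rep.per_pair[m].std(ddof=1))

    def test_wrong_count_rejected(self):
        m = _mask(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="exactly 3"):
            pairwise_geometric_summary([m, m], "intra")
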