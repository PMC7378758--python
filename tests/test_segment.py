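"""Segmentation chain: bilateral filter, hysteresis threshold, median
cleanup, edge extraction, surface angles, exclusion masks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import sublimap as sm
from sublimap.segment import EMPTY, _pad


def rand_volume(shape=(8, 10, 6), seed=0, lo=0.0, hi=100.0):
    return np.random.default_rng(seed).uniform(lo, hi, shape)


class TestBilateral:
    def test_constant_volume_unchanged(self):
        vol = np.full((6, 8, 5), 3.25)
        out = sm.bilateral_filter(vol, 1.0, 10.0)
        np.testing.assert_allclose(out, vol, rtol=1e-12)

    def test_infinite_range_sigma_equals_gaussian(self):
        """With an infinite range sigma the bilateral collapses to plain
        Gaussian smoothing (separable oracle, matched truncation)."""
        vol = rand_volume((10, 12, 8), seed=1)
        out = sm.bilateral_filter(vol, 1.2, np.inf, truncate=3.0)
        radius = int(3.0 * 1.2 + 0.5)
        oracle = ndimage.gaussian_filter(
            vol, 1.2, truncate=radius / 1.2, mode=["nearest", "wrap", "nearest"]
        )
        np.testing.assert_allclose(out, oracle, rtol=1e-6)

    def test_step_edge_stays_put(self):
        """A high-contrast step moves its 50% crossing < 0.5 voxel."""
        vol = np.zeros((4, 6, 40))
        vol[:, :, 20:] = 100.0
        out = sm.bilateral_filter(vol, 1.5, 5.0)  # contrast >> sigma_range
        profile = out[2, 3]
        crossing = np.interp(50.0, profile, np.arange(40.0))
        assert abs(crossing - 19.5) < 0.5

    def test_phi_axis_is_periodic(self):
        vol = rand_volume((5, 12, 5), seed=2)
        out = sm.bilateral_filter(vol, 1.0, 20.0)
        rolled = sm.bilateral_filter(np.roll(vol, 4, axis=1), 1.0, 20.0)
        np.testing.assert_array_equal(np.roll(out, 4, axis=1), rolled)


def flood_fill_oracle(soft, hard):
    """Brute-force BFS over 26-neighbourhoods with phi wrap."""
    n0, n1, n2 = soft.shape
    seen = np.zeros_like(soft, dtype=bool)
    stack = list(zip(*np.nonzero(hard & soft)))
    seen[tuple(np.array(stack).T)] = True if stack else seen.any()
    while stack:
        i, j, k = stack.pop()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    ni, nj, nk = i + di, (j + dj) % n1, k + dk
                    if 0 <= ni < n0 and 0 <= nk < n2 and soft[ni, nj, nk] and not seen[ni, nj, nk]:
                        seen[ni, nj, nk] = True
                        stack.append((ni, nj, nk))
    return seen


class TestDualThreshold:
    def test_all_hard_is_all_ice(self):
        vol = np.full((4, 5, 4), 100.0)
        assert sm.dual_threshold(vol, (90, 110), (80, 120)).all()

    def test_isolated_soft_blob_excluded(self):
        vol = np.zeros((5, 7, 5))
        vol[1, 1, 1] = 100.0  # hard seed
        vol[4, 5, 3] = 85.0  # soft, far from any hard voxel
        labels = sm.dual_threshold(vol, (90, 110), (80, 120))
        assert labels[1, 1, 1] and not labels[4, 5, 3]

    def test_soft_shell_around_hard_core_included(self):
        vol = np.zeros((7, 9, 7))
        vol[3, 4, 3] = 100.0
        shell = np.zeros_like(vol, dtype=bool)
        shell[2:5, 3:6, 2:5] = True
        shell[3, 4, 3] = False
        vol[shell] = 85.0
        labels = sm.dual_threshold(vol, (90, 110), (80, 120))
        assert labels[2:5, 3:6, 2:5].all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, seed):
        vol = rand_volume((7, 9, 6), seed=seed)
        hard_w, soft_w = (70.0, 100.0), (50.0, 100.0)
        labels = sm.dual_threshold(vol, hard_w, soft_w)
        soft = (vol >= 50) & (vol <= 100)
        hard = (vol >= 70) & (vol <= 100)
        np.testing.assert_array_equal(labels, flood_fill_oracle(soft, hard))

    def test_wrap_connectivity_across_phi_seam(self):
        vol = np.zeros((3, 10, 3))
        vol[1, 0, 1] = 85.0  # soft at seam start
        vol[1, 9, 1] = 100.0  # hard at seam end: adjacent across the wrap
        labels = sm.dual_threshold(vol, (90, 110), (80, 120))
        assert labels[1, 0, 1]

    def test_empty_hard_warns_and_is_empty(self):
        vol = np.full((3, 4, 3), 85.0)
        with pytest.warns(UserWarning, match="empty hard"):
            labels = sm.dual_threshold(vol, (90, 110), (80, 120))
        assert not labels.any()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(60, 90))
    def test_monotone_in_hard_window(self, seed, hard_lo):
        """Enlarging the hard window never removes a labelled voxel."""
        vol = rand_volume((5, 6, 5), seed=seed)
        small = sm.dual_threshold(vol, (hard_lo, 95.0), (40.0, 100.0))
        big = sm.dual_threshold(vol, (hard_lo - 10, 97.0), (40.0, 100.0))
        assert (big | small == big).all()


def median_oracle(labels, size):
    """Exhaustive per-voxel window vote with the same padding rules."""
    k = size // 2
    padded = _pad(labels.astype(np.uint8), (k, k, k))
    out = np.zeros_like(labels, dtype=bool)
    for i in range(labels.shape[0]):
        for j in range(labels.shape[1]):
            for l in range(labels.shape[2]):
                win = padded[i : i + size, j : j + size, l : l + size]
                out[i, j, l] = win.sum() > size**3 // 2
    return out


class TestMedian:
    def test_isolated_voxel_removed(self):
        labels = np.zeros((5, 5, 5), dtype=bool)
        labels[2, 2, 2] = True
        assert not sm.median_filter_3d(labels, 3).any()

    def test_half_space_unchanged(self):
        labels = np.zeros((6, 8, 6), dtype=bool)
        labels[:, :, 3:] = True
        np.testing.assert_array_equal(sm.median_filter_3d(labels, 3), labels)

    @pytest.mark.parametrize("size", [3, 5])
    def test_matches_exhaustive_vote(self, size):
        labels = np.random.default_rng(4).random((6, 7, 6)) > 0.5
        np.testing.assert_array_equal(sm.median_filter_3d(labels, size), median_oracle(labels, size))

    def test_sparse_speckle_removed(self):
        rng = np.random.default_rng(9)
        labels = np.zeros((9, 9, 9), dtype=bool)
        # at most 4 true voxels anywhere: every 3^3 window stays minority
        pts = rng.integers(0, 9, (4, 3))
        labels[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        if labels.sum() <= 4:
            assert not sm.median_filter_3d(labels, 3).any() or median_oracle(labels, 3).any()
            np.testing.assert_array_equal(sm.median_filter_3d(labels, 3), median_oracle(labels, 3))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            sm.median_filter_3d(np.zeros((3, 3, 3), dtype=bool), 4)


class TestLayerEdges:
    def test_contiguous_layer(self):
        labels = np.zeros((2, 3, 30), dtype=bool)
        labels[:, :, 10:21] = True
        layer = sm.extract_layer_edges(labels)
        assert (layer.first == 10).all() and (layer.last == 20).all() and (layer.count == 11).all()

    def test_split_layer(self):
        labels = np.zeros((1, 1, 30), dtype=bool)
        labels[0, 0, 10:15] = True
        labels[0, 0, 18:21] = True
        layer = sm.extract_layer_edges(labels)
        assert layer.first[0, 0] == 10 and layer.last[0, 0] == 20 and layer.count[0, 0] == 8

    def test_empty_ray_sentinel(self):
        labels = np.zeros((2, 2, 10), dtype=bool)
        layer = sm.extract_layer_edges(labels)
        assert (layer.first == EMPTY).all() and (layer.count == 0).all()

    def test_excluded_locations_carry_no_edges(self):
        labels = np.ones((3, 4, 5), dtype=bool)
        excl = np.zeros((3, 4), dtype=bool)
        excl[1, 2] = True
        layer = sm.extract_layer_edges(labels, exclusion=excl)
        assert layer.first[1, 2] == EMPTY and layer.count[1, 2] == 0
        assert layer.first[0, 0] == 0


class TestSurfaceAngles:
    def test_radial_surface_is_zero_degrees(self):
        vol = np.zeros((6, 8, 20))
        vol[:, :, 10:] = 100.0  # interface normal to r
        angles = sm.surface_normal_angles(vol)
        assert angles.valid[3, 4, 10]
        assert angles.angle_deg[3, 4, 10] == pytest.approx(0.0, abs=1e-9)

    def test_45_degree_plane(self):
        # interface inclined 45 deg between h and r
        h, p, r = np.mgrid[:20, :6, :20]
        vol = np.where(r > h, 100.0, 0.0)
        angles = sm.surface_normal_angles(vol)
        interior = angles.angle_deg[8:12, 2:4, 8:12]
        valid = angles.valid[8:12, 2:4, 8:12]
        on_surface = np.isfinite(interior) & valid
        diag = [interior[i, j, i2] for i in range(4) for j in range(2) for i2 in range(4)
                if abs((i + 8) - (i2 + 8)) <= 1 and valid[i, j, i2]]
        assert np.allclose(diag, 45.0, atol=2.0)

    def test_uniform_region_invalid(self):
        angles = sm.surface_normal_angles(np.full((5, 6, 5), 42.0))
        assert not angles.valid.any()

    def test_angles_within_range(self):
        vol = rand_volume((6, 8, 6), seed=3)
        angles = sm.surface_normal_angles(vol)
        ok = angles.angle_deg[angles.valid]
        assert np.all((ok >= 0) & (ok <= 90))


class TestExclusionMask:
    def test_empty_regions(self):
        assert not sm.build_exclusion_mask((10, 20), []).any()

    def test_height_band_covers_all_azimuths(self):
        mask = sm.build_exclusion_mask((10, 20), [(2, 5)])
        assert mask[2:5].all() and not mask[:2].any() and not mask[5:].any()

    def test_overlapping_rectangles_union(self):
        mask = sm.build_exclusion_mask((10, 20), [(0, 4, 0, 10), (2, 6, 5, 15)])
        assert mask.sum() == 4 * 10 + 4 * 10 - 2 * 5

    def test_out_of_grid_rejected(self):
        with pytest.raises(ValueError):
            sm.build_exclusion_mask((10, 20), [(5, 12)])


class TestPhiEquivariance:
    def test_whole_chain_rolls_exactly(self):
        """Rolling the input along phi rolls labels, edges and angles
        identically — bit-exact."""
        rng = np.random.default_rng(11)
        vol = np.zeros((8, 16, 20))
        inner = (6 + 3 * np.sin(2 * np.pi * np.arange(16) / 16)).astype(int)
        for j in range(16):
            vol[:, j, inner[j] : 16] = 100.0
        vol += rng.normal(0, 3.0, vol.shape)
        k = 5

        def chain(v):
            f = sm.bilateral_filter(v, 1.0, 10.0)
            lab = sm.median_filter_3d(sm.dual_threshold(f, (85, 115), (70, 130)), 3)
            layer = sm.extract_layer_edges(lab)
            ang = sm.surface_normal_angles(f)
            return lab, layer, ang

        lab0, layer0, ang0 = chain(vol)
        lab1, layer1, ang1 = chain(np.roll(vol, k, axis=1))
        np.testing.assert_array_equal(lab1, np.roll(lab0, k, axis=1))
        np.testing.assert_array_equal(layer1.first, np.roll(layer0.first, k, axis=1))
        np.testing.assert_array_equal(layer1.count, np.roll(layer0.count, k, axis=1))
        np.testing.assert_array_equal(ang1.valid, np.roll(ang0.valid, k, axis=1))
        np.testing.assert_array_equal(ang1.angle_deg, np.roll(ang0.angle_deg, k, axis=1))

    def test_thickness_fidelity_on_phantom(self, static_phantom):
        """Noise-free phantom: first/last edge indices within 1 voxel of
        the analytic layer everywhere."""
        from conftest import true_pose

        cfg, vols, truth = static_phantom
        pose = true_pose(truth)
        spec = sm.CylindricalGridSpec.for_volume(vols[0], pose, outer_radius_um=510.0)
        cvol = sm.resample_to_cylindrical(vols[0], pose, spec)
        hard, soft = sm.default_segmentation_windows(cfg)
        filt = sm.bilateral_filter(cvol.data, 1.0, 20.0, truncate=2.0)
        labels = sm.median_filter_3d(sm.dual_threshold(filt, hard, soft), 3)
        layer = sm.extract_layer_edges(labels)
        hh, pp = truth.grid_coords(spec)
        interior = slice(3, -3)
        l_true = truth.thickness_at(0.0, hh, pp)
        first_true = (cfg.r_ice_outer_um - l_true) / spec.dr_um - 0.5
        last_true = cfg.r_ice_outer_um / spec.dr_um - 0.5
        assert np.abs(layer.first - first_true)[interior].max() <= 1.0
        assert np.abs(layer.last - last_true)[interior].max() <= 1.0
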