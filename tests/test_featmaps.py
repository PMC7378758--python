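"""Feature maps: thickness, intrusions, max angles, sublimation times."""

import numpy as np
import pytest

import sublimap as sm
from sublimap import featmaps as fm
from sublimap.segment import EMPTY, SegmentedLayer
from conftest import small_phantom_config, true_pose


def layer_from(first, last, count, exclusion=None):
    first = np.asarray(first)
    shape = first.shape
    return SegmentedLayer(
        labels=np.zeros(shape + (1,), dtype=bool),
        first=first,
        last=np.asarray(last),
        count=np.asarray(count),
        exclusion=np.zeros(shape, dtype=bool) if exclusion is None else exclusion,
    )


class TestThicknessMaps:
    def test_contiguous_layer(self):
        maps = fm.thickness_maps(layer_from([[10]], [[20]], [[11]]), dr_um=30.0)
        assert maps.lice_um[0, 0] == 330.0
        assert maps.lprime_um[0, 0] == 330.0
        assert not maps.intrusion[0, 0]

    def test_split_layer_flags_intrusion(self):
        maps = fm.thickness_maps(layer_from([[10]], [[20]], [[8]]), dr_um=30.0)
        assert maps.lice_um[0, 0] == 330.0
        assert maps.lprime_um[0, 0] == 240.0
        assert maps.intrusion[0, 0]

    def test_empty_ray_is_zero(self):
        maps = fm.thickness_maps(layer_from([[EMPTY]], [[EMPTY]], [[0]]), dr_um=30.0)
        assert maps.lice_um[0, 0] == 0.0 and maps.lprime_um[0, 0] == 0.0
        assert not maps.intrusion[0, 0]

    def test_lprime_never_exceeds_lice(self):
        rng = np.random.default_rng(0)
        first = rng.integers(0, 5, (6, 8))
        extent = rng.integers(1, 10, (6, 8))
        count = np.minimum(rng.integers(1, 12, (6, 8)), extent)
        maps = fm.thickness_maps(layer_from(first, first + extent - 1, count), dr_um=30.0)
        assert (maps.lprime_um <= maps.lice_um + 1e-9).all()
        np.testing.assert_array_equal(maps.intrusion, maps.lprime_um < maps.lice_um)


class TestMaxAngleMaps:
    def test_growing_series_takes_last_frame(self):
        frames = [np.full((2, 2), a) for a in (10.0, 20.0, 30.0)]
        t = np.array([0.0, 5.0, 10.0])
        out = fm.max_angle_maps(frames, t)
        assert (out.max_angle_deg == 30.0).all() and (out.time_of_max_s == 10.0).all()

    def test_constant_series_ties_to_first_frame(self):
        frames = [np.full((2, 2), 25.0)] * 3
        out = fm.max_angle_maps(frames, np.array([0.0, 5.0, 10.0]))
        assert (out.time_of_max_s == 0.0).all()

    def test_matches_bruteforce_over_random_series(self):
        rng = np.random.default_rng(3)
        frames = [rng.uniform(0, 90, (4, 5)) for _ in range(7)]
        t = np.arange(7) * 10.0
        out = fm.max_angle_maps(frames, t)
        stack = np.stack(frames)
        np.testing.assert_allclose(out.max_angle_deg, stack.max(axis=0))
        np.testing.assert_allclose(out.time_of_max_s, t[stack.argmax(axis=0)])

    def test_nan_frames_ignored_and_exclusion_applied(self):
        a = np.array([[10.0, np.nan], [np.nan, np.nan]])
        b = np.array([[5.0, 20.0], [np.nan, np.nan]])
        excl = np.array([[False, False], [False, True]])
        out = fm.max_angle_maps([a, b], np.array([0.0, 1.0]), exclusion=excl)
        assert out.max_angle_deg[0, 0] == 10.0 and out.max_angle_deg[0, 1] == 20.0
        assert not out.valid[1, 0] and not out.valid[1, 1]


class TestSublimationTime:
    def test_simple_transition(self):
        present = np.array([1, 1, 1, 1, 1, 0, 0, 0], dtype=bool)[:, None, None]
        t = np.arange(8) * 100.0
        out = fm.sublimation_time_map(present, t, persistence=1)
        assert out.time_s[0, 0] == 500.0

    def test_never_sublimated_is_nan(self):
        present = np.ones((5, 1, 1), dtype=bool)
        out = fm.sublimation_time_map(present, np.arange(5.0))
        assert np.isnan(out.time_s[0, 0])

    def test_flicker_needs_persistence(self):
        """ice/not/ice then permanently not-ice: m=2 finds the sustained run."""
        present = np.array([1, 0, 1, 0, 0, 0], dtype=bool)[:, None, None]
        t = np.arange(6) * 10.0
        m1 = fm.sublimation_time_map(present, t, persistence=1)
        m2 = fm.sublimation_time_map(present, t, persistence=2)
        assert m1.time_s[0, 0] == 10.0  # first ice-free frame
        assert m2.time_s[0, 0] == 30.0  # first frame of the sustained run

    def test_matches_bruteforce_runs(self):
        rng = np.random.default_rng(8)
        present = rng.random((10, 3, 4)) > 0.4
        t = np.arange(10) * 7.0
        for m in (1, 2, 3):
            out = fm.sublimation_time_map(present, t, persistence=m)
            for i in range(3):
                for j in range(4):
                    expected = np.nan
                    for s in range(10 - m + 1):
                        if not present[s : s + m, i, j].any():
                            expected = t[s]
                            break
                    if np.isnan(expected):
                        assert np.isnan(out.time_s[i, j])
                    else:
                        assert out.time_s[i, j] == expected


class TestPostSublimationAttenuation:
    def test_constant_after_sublimation(self):
        vals = np.full((6, 2, 2), 7.0)
        t = np.arange(6) * 1.0
        subl = fm.SublimationMaps(time_s=np.full((2, 2), 2.0))
        out = fm.post_sublimation_attenuation(vals, t, subl)
        np.testing.assert_allclose(out.attenuation, 7.0)

    def test_sentinel_time_is_undefined(self):
        vals = np.ones((4, 1, 1))
        subl = fm.SublimationMaps(time_s=np.array([[np.nan]]))
        out = fm.post_sublimation_attenuation(vals, np.arange(4.0), subl)
        assert np.isnan(out.attenuation[0, 0])

    def test_matches_direct_average(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 10, (8, 3, 3))
        t = np.arange(8) * 2.0
        times = rng.choice([1.9, 6.0, np.nan], (3, 3))
        out = fm.post_sublimation_attenuation(vals, t, fm.SublimationMaps(time_s=times))
        for i in range(3):
            for j in range(3):
                if np.isnan(times[i, j]):
                    assert np.isnan(out.attenuation[i, j])
                else:
                    sel = t > times[i, j]
                    np.testing.assert_allclose(out.attenuation[i, j], vals[sel, i, j].mean())


@pytest.fixture(scope="module")
def sublimating():
    import warnings as _warnings

    cfg = small_phantom_config(
        l0_um=240.0, rate_um_per_h=240.0,
        timestamps_s=(0.0, 1200.0, 2400.0, 3600.0),
    )
    vols, truth = sm.generate_phantom(cfg)
    pose = true_pose(truth)
    spec = sm.CylindricalGridSpec.for_volume(vols[0], pose, outer_radius_um=510.0)
    hard, soft = sm.default_segmentation_windows(cfg)
    frames = []
    for vol in vols:
        cvol = sm.resample_to_cylindrical(vol, pose, spec)
        filt = sm.bilateral_filter(cvol.data, 1.0, 20.0, truncate=2.0)
        with _warnings.catch_warnings():
            # the final frame has fully sublimated: empty segmentation is expected
            _warnings.simplefilter("ignore", UserWarning)
            labels = sm.median_filter_3d(sm.dual_threshold(filt, hard, soft), 3)
        frames.append(sm.extract_layer_edges(labels))
    return cfg, truth, spec, frames


class TestPhantomFidelity:

    def test_lice_tracks_truth_every_frame(self, sublimating):
        cfg, truth, spec, frames = sublimating
        hh, pp = truth.grid_coords(spec)
        for t, layer in zip(cfg.timestamps_s, frames):
            maps = fm.thickness_maps(layer, spec.dr_um, timestamp=t)
            err = np.abs(maps.lice_um - truth.thickness_at(t, hh, pp))[3:-3]
            assert err.max() <= spec.dr_um  # within one voxel everywhere

    def test_no_intrusions_on_smooth_phantom(self, sublimating):
        _, _, spec, frames = sublimating
        for layer in frames:
            maps = fm.thickness_maps(layer, spec.dr_um)
            assert maps.intrusion.sum() == 0  # smooth layer: 100% intrusion-free

    def test_cavity_intrusion_flags_cover_cavity_rays(self):
        cav = sm.Cavity(h_center=0.0, phi_center=np.pi / 2, r_center=345.0,
                        h_semi=120.0, arc_semi=150.0, r_semi=60.0)
        cfg = small_phantom_config(l0_um=270.0, cavities=(cav,))
        vols, truth = sm.generate_phantom(cfg)
        pose = true_pose(truth)
        spec = sm.CylindricalGridSpec.for_volume(vols[0], pose, outer_radius_um=510.0)
        cvol = sm.resample_to_cylindrical(vols[0], pose, spec)
        hard, soft = sm.default_segmentation_windows(cfg)
        filt = sm.bilateral_filter(cvol.data, 1.0, 20.0, truncate=2.0)
        labels = sm.median_filter_3d(sm.dual_threshold(filt, hard, soft), 3)
        maps = fm.thickness_maps(sm.extract_layer_edges(labels), spec.dr_um)
        hh, pp = truth.grid_coords(spec)
        # flagged intrusions lie on (or within a voxel of) cavity rays
        assert maps.intrusion.any()
        grown = truth.cavity_ray_mask(hh[:, :, None] + np.array([-30.0, 0.0, 30.0]),
                                      pp[:, :, None]).any(-1)
        grown |= np.roll(grown, 1, axis=1) | np.roll(grown, -1, axis=1)
        assert not (maps.intrusion & ~grown).any()
        # rays whose radial chord through the void spans >= 3 voxels must be
        # flagged (narrower gaps can legitimately close under the 3^3 median)
        darc = (np.mod(pp - cav.phi_center + np.pi, 2 * np.pi) - np.pi) * cav.r_center
        inside = (hh - cav.h_center) ** 2 / cav.h_semi**2 + darc**2 / cav.arc_semi**2
        with np.errstate(invalid="ignore"):
            chord = 2 * cav.r_semi * np.sqrt(np.clip(1 - inside, 0, None))
        assert maps.intrusion[chord >= 3 * spec.dr_um].all()

    def test_maps_roll_with_phi(self, sublimating):
        _, _, spec, frames = sublimating
        layer = frames[0]
        rolled_labels = np.roll(layer.labels, 4, axis=1)
        m0 = fm.thickness_maps(sm.extract_layer_edges(layer.labels), spec.dr_um)
        m1 = fm.thickness_maps(sm.extract_layer_edges(rolled_labels), spec.dr_um)
        np.testing.assert_array_equal(m1.lice_um, np.roll(m0.lice_um, 4, axis=1))
        np.testing.assert_array_equal(m1.intrusion, np.roll(m0.intrusion, 4, axis=1))
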