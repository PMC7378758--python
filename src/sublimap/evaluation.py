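"""Standard benchmark protocols on ground-truth phantoms.

Each benchmark builds a phantom emulating the scanned sample — a misaligned
spin-frozen vial with a receding ice annulus — runs the corresponding part
of the analysis chain, and returns scalar quality measures against the
phantom's ground truth: axis-recovery error and RHT repeatability for the
pose stage, thickness-map fidelity and intrusion detection for the
segmentation stage, rate-recovery error and normalised-profile histogram
concentration for the kinetics stage, plus brute-force reference
equivalences for the individual operators.  The problem sizes (128^3 pose
and kinetics phantoms, 96^3 thickness phantom, 30 um voxels throughout)
are the package's standard desk-scale configuration.
"""

from __future__ import annotations

import numpy as np

from . import featmaps as fm
from . import kinetics as kin
from . import segment as seg
from .geometry import (
    ConeBeamGeometry,
    CylindricalGridSpec,
    azimuthal_divisions,
    magnification_and_voxel,
    reconstruction_schedule,
    resample_to_cylindrical,
)
from .kinetics import rate_to_voxels_per_rotation
from .phantom import (
    Cavity,
    PhantomConfig,
    default_segmentation_windows,
    generate_phantom,
)
from .pose import VialPose, estimate_pose, pose_repeatability

__all__ = [
    "scan_geometry_summary",
    "pose_recovery_benchmark",
    "thickness_fidelity_benchmark",
    "kinetics_recovery_benchmark",
    "operator_reference_checks",
]

# the scanner's published operating point
SCANNER = ConeBeamGeometry(sdd_mm=365.7, sod_mm=109.7, pixel_pitch_um=100.0)
ROTATION_TIME_S = 176.11
PROJECTIONS_PER_ROTATION = 1600
SAMPLE_OUTER_RADIUS_UM = 7639.0  # wedge-rule radius matching the projection count
VOXEL_UM = 30.0


def scan_geometry_summary() -> dict:
    """Closed-form scan-geometry arithmetic at the published operating point."""
    mag, px = magnification_and_voxel(SCANNER)
    mannitol = reconstruction_schedule(35, ROTATION_TIME_S, window=1, step=0.5)
    bsa = reconstruction_schedule(40, ROTATION_TIME_S, window=1, step=1)
    water = reconstruction_schedule(30, ROTATION_TIME_S, window=1, step=1)
    return {
        "magnification": mag,
        "projected_pixel_um": px,
        "mannitol_volume_count": mannitol.n_volumes,
        "mannitol_interval_min": mannitol.interval_s / 60.0,
        "bsa_volume_count": bsa.n_volumes,
        "bsa_scan_duration_min": bsa.total_span_s / 60.0,
        "water_scan_duration_min": water.total_span_s / 60.0,
        "azimuthal_divisions": azimuthal_divisions(SAMPLE_OUTER_RADIUS_UM, VOXEL_UM),
        "front_advance_voxels_per_rotation": rate_to_voxels_per_rotation(180.0, VOXEL_UM),
    }


def _glass_window(cfg: PhantomConfig) -> tuple[float, float]:
    att = cfg.attenuation
    margin = 0.4 * min(abs(att.glass - att.ice), abs(att.glass - att.wrap))
    return (att.glass - margin, att.glass + margin)


def _noise_10pct(cfg_att) -> float:
    return 0.10 * (cfg_att.ice - cfg_att.dry)


def pose_recovery_benchmark(seed: int = 0, n_repeats: int = 4) -> dict:
    """Axis recovery on a misaligned, tilted, noisy 128^3 phantom.

    The vial axis is offset by (8, -7) voxels and tilted 1.5 deg; noise is
    10% of the ice contrast.  Returns the worst axis-intersection error
    over all analysed heights (in voxels) and the 4-repeat RHT spread.
    """
    cfg = PhantomConfig(
        shape=(128, 128, 128),
        spacing_um=VOXEL_UM,
        axis_offset_um=(240.0, -210.0),
        tilt_deg=1.5,
        tilt_azimuth_deg=30.0,
        r_core_um=300.0,
        r_ice_outer_um=1400.0,
        r_glass_outer_um=1550.0,
        r_wrap_outer_um=1680.0,
        l0_um=600.0,
        noise_sigma=0.0,
        timestamps_s=(0.0,),
        seed=seed,
    )
    vols, truth = generate_phantom(cfg)
    vol = vols[0]
    from .phantom import add_noise

    vol = add_noise(vol, _noise_10pct(cfg.attenuation), seed=seed + 1)
    window = _glass_window(cfg)
    pose = estimate_pose(vol, window=window, n_heights=40, n_triplets=5000, seed=seed)
    z_idx = np.unique(np.round(np.linspace(0, 127, 40)).astype(int))
    z_eval = vol.axis_coords(0)[z_idx]
    err = pose.axis_xy_at_z(z_eval) - truth.axis_xy_at_z(z_eval)
    max_err_vox = float(np.abs(err).max() / cfg.spacing_um)
    rep = pose_repeatability(
        vol, window, n_repeats=n_repeats, seeds=[seed + i for i in range(n_repeats)],
        n_heights=40, n_triplets=5000,
    )
    return {
        "max_axis_error_voxels": max_err_vox,
        "repeat_spread_max_um": float(rep["spread_um"].max()),
        "n_heights": int(len(z_idx)),
    }


def _segment_chain(cfg: PhantomConfig, vol, pose: VialPose, spec: CylindricalGridSpec,
                   exclusion: np.ndarray | None = None):
    hard, soft = default_segmentation_windows(cfg)
    cvol = resample_to_cylindrical(vol, pose, spec)
    att = cfg.attenuation
    sigma_range = max(2.0 * cfg.noise_sigma, 0.2 * (att.ice - att.dry))
    filt = seg.bilateral_filter(cvol.data.astype(np.float32), 1.0, sigma_range, truncate=2.0)
    labels = seg.median_filter_3d(seg.dual_threshold(filt, hard, soft), 3)
    return seg.extract_layer_edges(labels, exclusion), filt


def _grid_for(cfg: PhantomConfig, vol, pose: VialPose) -> CylindricalGridSpec:
    outer = min(cfg.r_ice_outer_um + 3 * VOXEL_UM, cfg.r_glass_outer_um - VOXEL_UM)
    return CylindricalGridSpec.for_volume(vol, pose, outer_radius_um=outer)


def thickness_fidelity_benchmark(seed: int = 0) -> dict:
    """Thickness maps vs analytic truth on a noise-free 96^3 phantom, and
    intrusion detection on the same phantom with a buried cavity.

    Three height rows at each end of the grid are excluded (the phantom's
    layer runs to the volume boundary there, as a vial's narrowing sides
    would).  Reports the fraction of valid locations within one voxel of
    truth, intrusion false positives outside the cavity footprint (grown
    by one voxel) and coverage of rays whose radial chord through the
    cavity spans at least three voxels.
    """
    base = dict(
        shape=(96, 96, 96),
        spacing_um=VOXEL_UM,
        axis_offset_um=(60.0, -30.0),
        tilt_deg=1.0,
        r_core_um=300.0,
        r_ice_outer_um=1150.0,
        r_glass_outer_um=1290.0,
        r_wrap_outer_um=1380.0,
        l0_um=600.0,
        rate_um_per_h=600.0,
        timestamps_s=(0.0, 1800.0),
        seed=seed,
    )
    cfg = PhantomConfig(**base)
    vols, truth = generate_phantom(cfg)
    pose = VialPose(point=truth.axis_point, direction=truth.axis_direction)
    spec = _grid_for(cfg, vols[0], pose)
    exclusion = seg.build_exclusion_mask(
        (spec.n_h, spec.n_phi), [(0, 3), (spec.n_h - 3, spec.n_h)]
    )
    hh, pp = truth.grid_coords(spec)
    within = []
    for vol in vols:
        layer, _ = _segment_chain(cfg, vol, pose, spec, exclusion)
        maps = fm.thickness_maps(layer, spec.dr_um, timestamp=vol.timestamp)
        err = np.abs(maps.lice_um - truth.thickness_at(vol.timestamp, hh, pp))
        within.append(err[maps.valid] <= spec.dr_um + 1e-9)
    pct_within = 100.0 * float(np.concatenate(within).mean())

    cav = Cavity(h_center=0.0, phi_center=np.pi / 2, r_center=850.0,
                 h_semi=250.0, arc_semi=300.0, r_semi=90.0)
    cfg_cav = PhantomConfig(**{**base, "cavities": (cav,), "timestamps_s": (0.0,)})
    vols_cav, truth_cav = generate_phantom(cfg_cav)
    layer, _ = _segment_chain(cfg_cav, vols_cav[0], pose, spec, exclusion)
    maps = fm.thickness_maps(layer, spec.dr_um)
    grown = truth_cav.cavity_ray_mask(
        hh[:, :, None] + np.array([-VOXEL_UM, 0.0, VOXEL_UM]), pp[:, :, None]
    ).any(-1)
    grown |= np.roll(grown, 1, axis=1) | np.roll(grown, -1, axis=1)
    false_pos = int((maps.intrusion & ~grown & maps.valid).sum())
    darc = (np.mod(pp - cav.phi_center + np.pi, 2 * np.pi) - np.pi) * cav.r_center
    inside = (hh - cav.h_center) ** 2 / cav.h_semi**2 + darc**2 / cav.arc_semi**2
    chord = 2 * cav.r_semi * np.sqrt(np.clip(1 - inside, 0.0, None))
    core = (chord >= 3 * spec.dr_um) & maps.valid
    coverage = 100.0 * float(maps.intrusion[core].mean())
    return {
        "pct_within_one_voxel": pct_within,
        "n_locations": int(np.concatenate(within).size),
        "intrusion_false_positives": false_pos,
        "intrusion_core_coverage_pct": coverage,
        "n_core_rays": int(core.sum()),
    }


def kinetics_recovery_benchmark(seed: int = 0, n_frames: int = 20) -> dict:
    """Rate-map recovery on a 128^3 phantom with spatially varying rates.

    True rates are drawn uniformly in [0.5, 1.5] mm/h on a coarse (h, phi)
    node grid and interpolated; the initial thickness is rate * scan span,
    so every location declines linearly to zero exactly at the last frame
    (the all-linear regime of the normalised-profile histogram).  Frames
    are spaced 2.93 min apart; noise is 10% of the ice contrast.
    """
    rng = np.random.default_rng(seed)
    interval_s = 175.8  # 2.93 min cadence
    times = tuple(np.arange(n_frames) * interval_s)
    span_h = times[-1] / 3600.0
    rate_field = rng.uniform(500.0, 1500.0, (10, 12))
    cfg = PhantomConfig(
        shape=(128, 128, 128),
        spacing_um=VOXEL_UM,
        axis_offset_um=(60.0, -30.0),
        tilt_deg=0.5,
        r_core_um=150.0,
        r_ice_outer_um=1700.0,
        r_glass_outer_um=1820.0,
        r_wrap_outer_um=1900.0,
        l0_um=rate_field * span_h,
        rate_um_per_h=rate_field,
        noise_sigma=0.0,
        timestamps_s=times,
        seed=seed,
    )
    cfg.noise_sigma = _noise_10pct(cfg.attenuation)
    vols, truth = generate_phantom(cfg)
    pose = VialPose(point=truth.axis_point, direction=truth.axis_direction)
    spec = _grid_for(cfg, vols[0], pose)
    exclusion = seg.build_exclusion_mask(
        (spec.n_h, spec.n_phi), [(0, 3), (spec.n_h - 3, spec.n_h)]
    )
    lice = np.empty((n_frames, spec.n_h, spec.n_phi))
    for i, vol in enumerate(vols):
        layer, _ = _segment_chain(cfg, vol, pose, spec, exclusion)
        lice[i] = fm.thickness_maps(layer, spec.dr_um).lice_um
    t = np.asarray(times)
    fits = kin.fit_decline_maps(lice, t, exclusion=exclusion, zero_tol_um=0.5 * spec.dr_um)
    hh, pp = truth.grid_coords(spec)
    true_rate = truth.rate_at(hh, pp) / 1000.0  # mm/h
    ok = fits.valid & np.isfinite(fits.rate_mm_per_h)
    rmse = float(np.sqrt(np.mean((fits.rate_mm_per_h[ok] - true_rate[ok]) ** 2)))
    mean_est = float(fits.rate_mm_per_h[ok].mean())
    mean_true = float(true_rate[ok].mean())
    # histogram of the phantom's known linear profiles through the package's
    # normalisation/binning path: the all-linear reference concentration
    lice_true = np.stack([truth.thickness_at(ts, hh, pp) for ts in t])
    fits_true = kin.fit_decline_maps(lice_true, t, exclusion=exclusion)
    antidiag_pct = _antidiagonal_mass_pct(kin.normalize_profiles(lice_true, t, fits_true))
    # the same histogram from the measured maps: late-time voxel quantization
    # and noise flicker smear it (informational, mirrors real-scan smearing)
    antidiag_measured_pct = _antidiagonal_mass_pct(kin.normalize_profiles(lice, t, fits))
    return {
        "rate_rmse_pct_of_mean": 100.0 * rmse / mean_true,
        "rate_mean_error_pct": 100.0 * abs(mean_est - mean_true) / mean_true,
        "rate_mean_mm_per_h": mean_est,
        "rate_mean_true_mm_per_h": mean_true,
        "hist_antidiagonal_mass_pct": antidiag_pct,
        "hist_antidiagonal_measured_pct": antidiag_measured_pct,
        "n_locations": int(ok.sum()),
    }


def _antidiagonal_mass_pct(profiles: kin.NormalizedProfiles) -> float:
    """Histogram mass within one bin of the L* = 1 - t* anti-diagonal."""
    counts, te, le = kin.profile_histogram(profiles, 50, 50)
    ti, li = np.nonzero(counts)
    tc = (te[ti] + te[ti + 1]) / 2
    lc = (le[li] + le[li + 1]) / 2
    near = np.abs(lc - (1.0 - tc)) <= 1.5 * (le[1] - le[0])
    return 100.0 * float(counts[ti[near], li[near]].sum() / counts.sum())


# -- brute-force reference implementations (operator cross-checks) ----------


def _kasa_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(cx), float(cy), float(np.sqrt(c + cx * cx + cy * cy))


def _flood_fill(soft: np.ndarray, hard: np.ndarray) -> np.ndarray:
    """BFS hysteresis over 26-neighbourhoods with phi wrap."""
    n0, n1, n2 = soft.shape
    seen = np.zeros_like(soft, dtype=bool)
    stack = list(zip(*np.nonzero(hard & soft)))
    for p in stack:
        seen[p] = True
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


def _median_vote(labels: np.ndarray, size: int) -> np.ndarray:
    from .segment import _pad

    k = size // 2
    padded = _pad(labels.astype(np.uint8), (k, k, k))
    out = np.zeros_like(labels, dtype=bool)
    for i in range(labels.shape[0]):
        for j in range(labels.shape[1]):
            for l in range(labels.shape[2]):
                out[i, j, l] = padded[i : i + size, j : j + size, l : l + size].sum() > size**3 // 2
    return out


def operator_reference_checks(seed: int = 0) -> dict:
    """Cross-checks of each operator against an independent brute-force
    reference on small inputs; all deviations should be at the stated
    floors (one accumulator bin, interpolation round-off, or exactly
    zero)."""
    from scipy import ndimage

    from .pose import rht_detect_circle

    rng = np.random.default_rng(seed)

    ang = rng.uniform(0, 2 * np.pi, 200)
    pts = np.column_stack([12.0 + 45.0 * np.cos(ang), -7.0 + 45.0 * np.sin(ang)])
    det = rht_detect_circle(pts, n_triplets=3000, seed=seed)
    cx, cy, r = _kasa_circle(pts)
    rht_dev = max(abs(det.center[0] - cx), abs(det.center[1] - cy), abs(det.radius - r))

    vol = rng.uniform(0, 100, (12, 14, 10))
    out = seg.bilateral_filter(vol, 1.2, np.inf, truncate=3.0)
    radius = int(3.0 * 1.2 + 0.5)
    oracle = ndimage.gaussian_filter(vol, 1.2, truncate=radius / 1.2,
                                     mode=["nearest", "wrap", "nearest"])
    bilateral_dev = float(np.abs((out - oracle) / oracle).max())

    vol2 = rng.uniform(0, 100, (8, 10, 8))
    labels = seg.dual_threshold(vol2, (70.0, 100.0), (50.0, 100.0))
    ref = _flood_fill((vol2 >= 50) & (vol2 <= 100), (vol2 >= 70) & (vol2 <= 100))
    dual_mismatch = int((labels != ref).sum())

    speckle = rng.random((7, 8, 7)) > 0.5
    median_mismatch = int((seg.median_filter_3d(speckle, 3) != _median_vote(speckle, 3)).sum())

    # phi-roll equivariance of the whole segment -> thickness chain
    vol3 = np.zeros((8, 16, 20))
    inner = (6 + 3 * np.sin(2 * np.pi * np.arange(16) / 16)).astype(int)
    for j in range(16):
        vol3[:, j, inner[j] : 16] = 100.0
    vol3 += rng.normal(0, 3.0, vol3.shape)

    def chain(v):
        f = seg.bilateral_filter(v, 1.0, 10.0)
        lab = seg.median_filter_3d(seg.dual_threshold(f, (85, 115), (70, 130)), 3)
        return fm.thickness_maps(seg.extract_layer_edges(lab), 30.0)

    m0 = chain(vol3)
    m1 = chain(np.roll(vol3, 5, axis=1))
    roll_mismatch = int((m1.lice_um != np.roll(m0.lice_um, 5, axis=1)).sum())
    roll_mismatch += int((m1.lprime_um != np.roll(m0.lprime_um, 5, axis=1)).sum())

    return {
        "rht_vs_leastsquares_dev_bins": float(rht_dev),
        "bilateral_vs_gaussian_max_rel_dev": bilateral_dev,
        "dual_threshold_vs_floodfill_mismatches": dual_mismatch,
        "median_vs_exhaustive_mismatches": median_mismatch,
        "phi_roll_equivariance_mismatches": roll_mismatch,
    }
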