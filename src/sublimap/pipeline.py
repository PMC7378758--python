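"""End-to-end pipeline: volumes -> pose -> cylindrical grid -> segmentation
-> feature maps -> kinetics, with a run manifest for reproducibility.

Input volumes either come from a phantom configuration (synthetic runs
with ground truth) or from a volume-series directory on disk.  Every
artifact is written under the configured output directory; the manifest
records the full parameter set, a hash of it, and library versions, so a
run can be reconstructed from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import featmaps as fm
from . import io as smio
from . import kinetics as kin
from . import segment as seg
from .geometry import CylindricalGridSpec, CylindricalVolume, resample_to_cylindrical
from .phantom import (
    Cavity,
    Crack,
    PhantomConfig,
    RegionAttenuation,
    default_segmentation_windows,
    generate_phantom,
)
from .pose import VialPose, estimate_pose
from .volume import CartesianVolume

__all__ = ["ConfigError", "PipelineConfig", "PipelineResult", "run_pipeline", "load_pipeline_config"]

log = logging.getLogger("sublimap")


class ConfigError(ValueError):
    """Invalid pipeline configuration (raised before any computation)."""


@dataclass
class PipelineConfig:
    """Validated parameter set for one pipeline run."""

    output_dir: str
    input_dir: str | None = None
    phantom: PhantomConfig | None = None
    # pose
    pose_window: tuple[float, float] | None = None  # glass grey window
    pose_n_heights: int = 40
    pose_retain_fraction: float = 0.10
    pose_n_triplets: int = 5000
    pose_smooth_sigma: float = 1.0
    seed: int = 0
    # cylindrical grid
    grid_dr_um: float = 30.0
    grid_dh_um: float = 30.0
    grid_outer_radius_um: float | None = None
    resample_order: int = 3
    # segmentation
    seg_sigma_spatial: float = 1.0
    seg_sigma_range: float | None = None
    seg_truncate: float = 2.0
    seg_hard_window: tuple[float, float] | None = None
    seg_soft_window: tuple[float, float] | None = None
    seg_median_size: int = 3
    exclusion_regions: list = field(default_factory=list)
    # kinetics
    kin_persistence: int = 1
    kin_bins: int = 50
    kin_require_reached_zero: bool = False

    def validate(self) -> None:
        if (self.input_dir is None) == (self.phantom is None):
            raise ConfigError("exactly one of input_dir or phantom must be given")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ConfigError(f"input directory {self.input_dir} does not exist")
        if self.phantom is None:
            if self.pose_window is None:
                raise ConfigError("pose_window is required for on-disk input")
            if self.seg_hard_window is None or self.seg_soft_window is None:
                raise ConfigError("segmentation windows are required for on-disk input")
            if self.grid_outer_radius_um is None:
                raise ConfigError("grid_outer_radius_um is required for on-disk input")
        if not 0 < self.pose_retain_fraction <= 1:
            raise ConfigError("pose_retain_fraction must be in (0, 1]")
        if self.kin_persistence < 1:
            raise ConfigError("kinetics persistence must be >= 1")

    def resolved(self) -> "PipelineConfig":
        """Fill phantom-derived defaults (grey windows, grid radius)."""
        cfg = dataclasses.replace(self)
        if cfg.phantom is not None:
            att = cfg.phantom.attenuation
            if cfg.pose_window is None:
                # window around the glass mean, clear of ice and wrap
                margin = 0.4 * min(abs(att.glass - att.ice), abs(att.glass - att.wrap))
                cfg.pose_window = (att.glass - margin, att.glass + margin)
            if cfg.seg_hard_window is None or cfg.seg_soft_window is None:
                hard, soft = default_segmentation_windows(cfg.phantom)
                cfg.seg_hard_window = cfg.seg_hard_window or hard
                cfg.seg_soft_window = cfg.seg_soft_window or soft
            if cfg.grid_outer_radius_um is None:
                # stay inside the glass wall: the glass-to-wrap partial-volume
                # shell sweeps through ice-like grey values
                cfg.grid_outer_radius_um = max(
                    cfg.phantom.r_ice_outer_um + cfg.grid_dr_um,
                    min(
                        cfg.phantom.r_ice_outer_um + 3 * cfg.grid_dr_um,
                        cfg.phantom.r_glass_outer_um - cfg.grid_dr_um,
                    ),
                )
            if cfg.seg_sigma_range is None:
                gap = abs(att.ice - att.dry)
                cfg.seg_sigma_range = max(2.0 * cfg.phantom.noise_sigma, 0.2 * gap)
        if cfg.seg_sigma_range is None:
            raise ConfigError("seg_sigma_range is required for on-disk input")
        return cfg


@dataclass
class PipelineResult:
    pose: VialPose
    grid: CylindricalGridSpec
    layer_maps: list[fm.LayerMaps]
    angle_maps: fm.AngleMaps
    sublimation: fm.SublimationMaps
    fits: kin.DeclineFitMaps
    stats: kin.RateStats
    histogram: np.ndarray
    exclusion: np.ndarray
    output_dir: Path


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return json.loads(json.dumps(d, default=lambda o: list(o) if isinstance(o, (tuple, np.ndarray)) else str(o)))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis chain and write all artifacts.

    Deterministic for a fixed configuration and seed: reruns produce
    byte-identical CSV outputs.
    """
    config.validate()
    cfg = config.resolved()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if cfg.phantom is not None:
        log.info("generating phantom: shape=%s frames=%d", cfg.phantom.shape, len(cfg.phantom.timestamps_s))
        volumes, _truth = generate_phantom(cfg.phantom)
    else:
        log.info("reading volume series from %s", cfg.input_dir)
        volumes = smio.read_volume_series(cfg.input_dir)
    timestamps = np.array([v.timestamp for v in volumes])

    log.info("pose estimation on frame 0 (n_heights=%d, n_triplets=%d)", cfg.pose_n_heights, cfg.pose_n_triplets)
    pose = estimate_pose(
        volumes[0],
        window=cfg.pose_window,
        n_heights=cfg.pose_n_heights,
        retain_fraction=cfg.pose_retain_fraction,
        n_triplets=cfg.pose_n_triplets,
        smooth_sigma=cfg.pose_smooth_sigma,
        seed=cfg.seed,
    )
    smio.write_pose(out / "pose.json", pose)

    grid = CylindricalGridSpec.for_volume(
        volumes[0], pose, outer_radius_um=cfg.grid_outer_radius_um,
        dr_um=cfg.grid_dr_um, dh_um=cfg.grid_dh_um,
    )
    exclusion = seg.build_exclusion_mask((grid.n_h, grid.n_phi), cfg.exclusion_regions)

    layer_maps: list[fm.LayerMaps] = []
    angle_series: list[np.ndarray] = []
    presence = np.empty((len(volumes), grid.n_h, grid.n_phi), dtype=bool)
    lice = np.empty((len(volumes), grid.n_h, grid.n_phi))
    band_mean = np.empty((len(volumes), grid.n_h, grid.n_phi))
    band = None
    for i, vol in enumerate(volumes):
        cvol = resample_to_cylindrical(vol, pose, grid, order=cfg.resample_order)
        filt = seg.bilateral_filter(
            cvol.data.astype(np.float32), cfg.seg_sigma_spatial, cfg.seg_sigma_range,
            truncate=cfg.seg_truncate,
        )
        labels = seg.dual_threshold(filt, cfg.seg_hard_window, cfg.seg_soft_window)
        labels = seg.median_filter_3d(labels, cfg.seg_median_size)
        layer = seg.extract_layer_edges(labels, exclusion)
        maps = fm.thickness_maps(layer, grid.dr_um, timestamp=vol.timestamp)
        angles = seg.surface_normal_angles(filt, grad_floor=1e-3)
        angle_series.append(fm.surface_angle_map(angles, layer))
        if band is None:
            # radial band holding the initial ice layer; attenuation is
            # averaged over it in every later frame
            has0 = layer.first != seg.EMPTY
            lo_band = int(layer.first[has0].min()) if has0.any() else 0
            hi_band = int(layer.last[has0].max()) if has0.any() else grid.n_r - 1
            band = (lo_band, hi_band)
        band_mean[i] = filt[:, :, band[0] : band[1] + 1].mean(axis=2)
        presence[i] = layer.count > 0
        lice[i] = maps.lice_um
        layer_maps.append(maps)
        log.info("frame %d/%d done (t=%.1f s)", i + 1, len(volumes), vol.timestamp)

    angle_maps = fm.max_angle_maps(angle_series, timestamps, exclusion=exclusion)
    subl = fm.sublimation_time_map(presence, timestamps, persistence=cfg.kin_persistence)
    subl = fm.post_sublimation_attenuation(band_mean, timestamps, subl)
    fits = kin.fit_decline_maps(lice, timestamps, exclusion=exclusion, zero_tol_um=0.5 * grid.dr_um)
    profiles = kin.normalize_profiles(lice, timestamps, fits, require_reached_zero=cfg.kin_require_reached_zero)
    hist, _, _ = kin.profile_histogram(profiles, cfg.kin_bins, cfg.kin_bins)
    stats = kin.rate_map_and_stats(fits, exclusion=exclusion)

    # -- outputs -----------------------------------------------------------
    smio.write_map_csv(out / "lice_initial.csv", layer_maps[0].lice_um, "lice_um")
    smio.write_map_csv(out / "lice_final.csv", layer_maps[-1].lice_um, "lice_um")
    smio.write_map_csv(out / "lprime_initial.csv", layer_maps[0].lprime_um, "lprime_um")
    smio.write_map_csv(out / "rate_map.csv", stats.rate_map, "rate_mm_per_h")
    smio.write_map_csv(out / "max_angle.csv", angle_maps.max_angle_deg, "angle_deg")
    smio.write_map_csv(out / "sublimation_time.csv", subl.time_s, "time_s")
    smio.write_map_csv(out / "post_sublimation_attenuation.csv", subl.attenuation, "attenuation")
    for i, maps in enumerate(layer_maps):
        smio.write_map_tiff(out / f"lice_{i:04d}.tif", maps.lice_um)
    np.savetxt(out / "profile_histogram.csv", hist, delimiter=",", fmt="%d")
    (out / "rate_stats.json").write_text(
        json.dumps(
            {
                "mean_mm_per_h": stats.mean,
                "std_mm_per_h": stats.std,
                "five_number": {
                    "min": stats.minimum, "q1": stats.q1, "median": stats.median,
                    "q3": stats.q3, "max": stats.maximum,
                },
                "n_valid": stats.n_valid,
            },
            indent=2,
        )
    )
    cfg_dict = _config_dict(cfg)
    cfg_text = yaml.safe_dump(cfg_dict, sort_keys=True)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "versions": {"numpy": np.__version__, "sublimap": _version()},
        "n_frames": len(volumes),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline finished in %.1f s", manifest["elapsed_s"])
    return PipelineResult(
        pose=pose, grid=grid, layer_maps=layer_maps, angle_maps=angle_maps,
        sublimation=subl, fits=fits, stats=stats, histogram=hist,
        exclusion=exclusion, output_dir=out,
    )


def _version() -> str:
    from . import __version__

    return __version__


def phantom_config_from_dict(section: dict) -> PhantomConfig:
    """Build a :class:`~sublimap.phantom.PhantomConfig` from a parsed YAML
    mapping (nested attenuation/cracks/cavities sections included)."""
    ph = dict(section)
    if "attenuation" in ph:
        ph["attenuation"] = RegionAttenuation(**ph["attenuation"])
    ph["cracks"] = tuple(Crack(**c) for c in ph.get("cracks", []))
    ph["cavities"] = tuple(Cavity(**c) for c in ph.get("cavities", []))
    for key in ("shape", "axis_offset_um", "timestamps_s"):
        if key in ph:
            ph[key] = tuple(ph[key])
    try:
        return PhantomConfig(**ph)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid phantom section: {exc}") from exc


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    The phantom section mirrors :class:`~sublimap.phantom.PhantomConfig`
    with ``attenuation``, ``cracks`` and ``cavities`` as nested mappings.
    Validation runs immediately, before any computation.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a mapping")
    ph = raw.pop("phantom", None)
    phantom = phantom_config_from_dict(ph) if ph is not None else None
    for key in ("pose_window", "seg_hard_window", "seg_soft_window"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    try:
        cfg = PipelineConfig(phantom=phantom, **raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg
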