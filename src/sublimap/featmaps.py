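"""Reduction of segmented 4D data to 2D (h, phi) feature maps.

The unwrapped cylindrical layer is summarised per location: the radial
ice thickness L_ice (first-to-last segmented voxel extent), the integrated
thickness L' (ice voxel count times the radial spacing, which drops below
L_ice wherever a cavity or channel intrudes into the layer), the maximal
surface-normal angle over the time series with its time of occurrence, the
time at which each location finishes sublimating, and the mean attenuation
after that time (which is where a faint dry-cake residue shows up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import EMPTY, AngleField, SegmentedLayer

__all__ = [
    "LayerMaps",
    "AngleMaps",
    "SublimationMaps",
    "thickness_maps",
    "surface_angle_map",
    "max_angle_maps",
    "sublimation_time_map",
    "post_sublimation_attenuation",
]


@dataclass
class LayerMaps:
    """Per-(h, phi) thickness maps of one frame (all lengths in um).

    ``lice`` is the first-to-last radial extent of the segmented layer,
    ``lprime`` the integrated (voxel-count) thickness; an intrusion is
    flagged wherever the layer is split, i.e. ``lprime < lice``.
    """

    lice_um: np.ndarray
    lprime_um: np.ndarray
    intrusion: np.ndarray
    valid: np.ndarray
    timestamp: float = 0.0


@dataclass
class AngleMaps:
    """Maximal surface angle over the time series and when it occurred."""

    max_angle_deg: np.ndarray
    time_of_max_s: np.ndarray
    valid: np.ndarray


@dataclass
class SublimationMaps:
    """Per-location sublimation time (s; NaN = not sublimated within the
    scan) and mean post-sublimation attenuation (NaN where undefined)."""

    time_s: np.ndarray
    attenuation: np.ndarray | None = None


def thickness_maps(layer: SegmentedLayer, dr_um: float, timestamp: float = 0.0) -> LayerMaps:
    """Thickness maps from extracted layer edges.

    The extent convention counts voxels inclusively: a single-voxel layer
    has thickness ``dr``, not zero.  Empty rays get zero thickness and
    stay valid; excluded locations are invalid.
    """
    has = layer.first != EMPTY
    extent = np.where(has, layer.last - layer.first + 1, 0)
    lice = extent * float(dr_um)
    lprime = layer.count * float(dr_um)
    intrusion = has & (layer.count < extent)
    return LayerMaps(
        lice_um=lice,
        lprime_um=lprime,
        intrusion=intrusion,
        valid=~layer.exclusion,
        timestamp=timestamp,
    )


def surface_angle_map(angles: AngleField, layer: SegmentedLayer) -> np.ndarray:
    """Surface angle at the innermost ice voxel of each ray (degrees).

    The sublimation front is the inner edge of the layer, so the angle map
    samples the angle field at ``first``; rays without ice (or excluded)
    are NaN.
    """
    n_h, n_phi = layer.first.shape
    out = np.full((n_h, n_phi), np.nan)
    has = layer.first != EMPTY
    hh, pp = np.nonzero(has)
    rr = layer.first[hh, pp]
    vals = angles.angle_deg[hh, pp, rr]
    ok = angles.valid[hh, pp, rr]
    out[hh[ok], pp[ok]] = vals[ok]
    return out


def max_angle_maps(
    angle_maps: list[np.ndarray],
    timestamps_s: np.ndarray,
    exclusion: np.ndarray | None = None,
) -> AngleMaps:
    """Maximum of per-frame surface-angle maps and its timestamp.

    NaN entries are ignored; ties keep the earliest frame.  Locations with
    no valid angle in any frame (or excluded) are invalid.
    """
    if len(angle_maps) < 1:
        raise ValueError("need at least one frame of angles")
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    if len(angle_maps) != timestamps_s.size:
        raise ValueError("one timestamp per frame required")
    shape = angle_maps[0].shape
    best = np.full(shape, -np.inf)
    t_best = np.full(shape, np.nan)
    for amap, t in zip(angle_maps, timestamps_s):
        upd = np.nan_to_num(amap, nan=-np.inf) > best  # strict > keeps earliest on ties
        best = np.where(upd, amap, best)
        t_best = np.where(upd, t, t_best)
    valid = np.isfinite(best)
    if exclusion is not None:
        valid &= ~exclusion
    best = np.where(valid, best, np.nan)
    t_best = np.where(valid, t_best, np.nan)
    return AngleMaps(max_angle_deg=best, time_of_max_s=t_best, valid=valid)


def sublimation_time_map(
    ice_present: np.ndarray,
    timestamps_s: np.ndarray,
    persistence: int = 1,
) -> SublimationMaps:
    """Time each location stops holding ice.

    ``ice_present`` is a boolean (n_t, ...) stack of per-frame ice
    presence (per ray or per voxel); the sublimation time is the mid
    timestamp of the first frame that starts a run of ``persistence``
    consecutive ice-free frames.  Locations that keep ice to the end get
    NaN.  ``persistence > 1`` guards against segmentation flicker at
    fast-moving edges.
    """
    ice_present = np.asarray(ice_present, dtype=bool)
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    n_t = ice_present.shape[0]
    if timestamps_s.size != n_t:
        raise ValueError("one timestamp per frame required")
    if not 1 <= persistence <= n_t:
        raise ValueError("persistence must be in [1, n_frames]")
    free = ~ice_present
    runs = np.lib.stride_tricks.sliding_window_view(free, persistence, axis=0).all(axis=-1)
    n_starts = runs.shape[0]
    any_run = runs.any(axis=0)
    idx = runs.argmax(axis=0)
    time = np.where(any_run, timestamps_s[np.clip(idx, 0, n_starts - 1)], np.nan)
    return SublimationMaps(time_s=time)


def post_sublimation_attenuation(
    values: np.ndarray,
    timestamps_s: np.ndarray,
    sublimation: SublimationMaps,
) -> SublimationMaps:
    """Mean of per-location attenuation over frames strictly after the
    sublimation time; NaN where the location never sublimated or no frame
    lies after its time."""
    values = np.asarray(values, dtype=float)
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    t_s = sublimation.time_s
    after = timestamps_s.reshape((-1,) + (1,) * t_s.ndim) > np.nan_to_num(t_s, nan=np.inf)
    n_after = after.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(after, values, 0.0).sum(axis=0) / n_after
    mean = np.where(n_after > 0, mean, np.nan)
    return SublimationMaps(time_s=t_s, attenuation=mean)
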