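"""Per-location sublimation kinetics from thickness time series.

At each (h, phi) location the radial ice thickness L_ice(t) declines as
the front recedes.  The end of drying t_end is taken as the earliest frame
whose thickness is closest to zero, a straight line is fitted by ordinary
least squares to the frames up to and including t_end, and its negative
slope (in mm/h) is the local average sublimation rate.  Profiles
normalised by the initial thickness and t_end, L*(t*) with t* = t / t_end,
collapse purely linear declines onto the anti-diagonal 1 - t*; a 2D
histogram of all normalised samples makes deviations (accelerating fronts,
sudden non-radial drops) visible at a glance.  The linear model is a
deliberate oversimplification of the true local dynamics; it summarises,
it does not explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DeclineFit",
    "DeclineFitMaps",
    "NormalizedProfiles",
    "RateStats",
    "find_t_end",
    "fit_decline",
    "fit_decline_maps",
    "normalize_profiles",
    "profile_histogram",
    "rate_map_and_stats",
    "rate_to_voxels_per_rotation",
]

UM_PER_S_TO_MM_PER_H = 3600.0 / 1000.0


@dataclass
class DeclineFit:
    """Linear decline fit at one location."""

    rate_mm_per_h: float
    t_end_s: float
    l0_um: float
    residual_rms_um: float
    valid: bool
    reached_zero: bool  # whether the series actually got to (near) zero


@dataclass
class DeclineFitMaps:
    """Per-location decline fits over the whole (h, phi) grid."""

    rate_mm_per_h: np.ndarray
    t_end_s: np.ndarray
    l0_um: np.ndarray
    residual_rms_um: np.ndarray
    valid: np.ndarray
    reached_zero: np.ndarray


@dataclass
class NormalizedProfiles:
    """Normalised thickness profiles L*(t*) per valid location.

    ``t_star``/``l_star`` are (n_locations, n_frames) arrays, NaN beyond
    each location's t_end; ``n_excluded`` counts locations dropped for
    zero initial thickness or invalid fits.
    """

    t_star: np.ndarray
    l_star: np.ndarray
    n_excluded: int


@dataclass
class RateStats:
    """Rate map (mm/h, NaN where invalid/excluded) with global statistics
    and a box-plot five-number summary."""

    rate_map: np.ndarray
    mean: float
    std: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n_valid: int


def find_t_end(thickness_um: np.ndarray, timestamps_s: np.ndarray) -> float:
    """Timestamp of the earliest frame whose thickness is closest to zero."""
    l = np.asarray(thickness_um, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    if l.size < 2 or l.size != t.size:
        raise ValueError("need >= 2 frames with matching timestamps")
    return float(t[np.argmin(np.abs(l))])  # argmin takes the first minimum


def fit_decline(
    thickness_um: np.ndarray,
    timestamps_s: np.ndarray,
    zero_tol_um: float = 0.0,
) -> DeclineFit:
    """Ordinary least squares on L_ice(t) over the frames with t <= t_end.

    The rate is the negative slope converted to mm/h (declines positive).
    Invalid when the initial thickness is zero or fewer than two frames
    fall inside the fit window.
    """
    l = np.asarray(thickness_um, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    t_end = find_t_end(l, t)
    sel = t <= t_end
    reached = bool(np.min(np.abs(l)) <= zero_tol_um)
    if l[0] > 0 and sel.sum() < 2 and np.ptp(l) == 0:
        # constant series: t_end collapses to the first frame, but the flat
        # line is still an exact zero-rate fit
        return DeclineFit(0.0, t_end, float(l[0]), 0.0, True, reached)
    if l[0] == 0 or sel.sum() < 2:
        return DeclineFit(np.nan, t_end, float(l[0]), np.nan, False, reached)
    slope, intercept = np.polyfit(t[sel], l[sel], 1)
    resid = l[sel] - (slope * t[sel] + intercept)
    rms = float(np.sqrt(np.mean(resid**2)))
    return DeclineFit(
        rate_mm_per_h=float(-slope) * UM_PER_S_TO_MM_PER_H,
        t_end_s=t_end,
        l0_um=float(l[0]),
        residual_rms_um=rms,
        valid=True,
        reached_zero=reached,
    )


def fit_decline_maps(
    thickness_um: np.ndarray,
    timestamps_s: np.ndarray,
    exclusion: np.ndarray | None = None,
    zero_tol_um: float = 0.0,
) -> DeclineFitMaps:
    """Vectorised :func:`fit_decline` over a (n_t, n_h, n_phi) stack.

    Locations sharing the same t_end frame index are fitted together with
    the closed-form OLS estimator; the result is identical to the scalar
    path at every location.
    """
    L = np.asarray(thickness_um, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    n_t = L.shape[0]
    if t.size != n_t or n_t < 2:
        raise ValueError("need >= 2 frames with matching timestamps")
    shape = L.shape[1:]
    idx_end = np.abs(L).argmin(axis=0)  # first minimum per location
    rate = np.full(shape, np.nan)
    rms = np.full(shape, np.nan)
    t_end = t[idx_end]
    l0 = L[0]
    reached = np.min(np.abs(L), axis=0) <= zero_tol_um
    constant = (l0 > 0) & (idx_end == 0) & (np.ptp(L, axis=0) == 0)
    rate[constant] = 0.0
    rms[constant] = 0.0
    valid = ((l0 > 0) & (idx_end >= 1)) | constant
    if exclusion is not None:
        valid &= ~exclusion
    for k in np.unique(idx_end[valid]):
        sel = valid & (idx_end == k)
        tk = t[: k + 1]
        Lk = L[: k + 1][:, sel]  # (k+1, n_sel)
        tm = tk.mean()
        denom = np.sum((tk - tm) ** 2)
        slope = ((tk - tm) @ (Lk - Lk.mean(axis=0))) / denom
        intercept = Lk.mean(axis=0) - slope * tm
        resid = Lk - (np.outer(tk, slope) + intercept)
        rate[sel] = -slope * UM_PER_S_TO_MM_PER_H
        rms[sel] = np.sqrt(np.mean(resid**2, axis=0))
    return DeclineFitMaps(
        rate_mm_per_h=rate,
        t_end_s=t_end.astype(float),
        l0_um=l0.astype(float),
        residual_rms_um=rms,
        valid=valid,
        reached_zero=reached,
    )


def normalize_profiles(
    thickness_um: np.ndarray,
    timestamps_s: np.ndarray,
    fits: DeclineFitMaps,
    require_reached_zero: bool = False,
) -> NormalizedProfiles:
    """Normalise each valid location's profile by L(0) and t_end.

    Samples with t <= t_end map to t* = t / t_end in [0, 1] and
    L* = L / L(0); later samples are NaN.  Locations with zero initial
    thickness or invalid fits are excluded (optionally also those that
    never reached zero thickness).
    """
    L = np.asarray(thickness_um, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    use = fits.valid & (fits.l0_um > 0) & (fits.t_end_s > 0)
    if require_reached_zero:
        use = use & fits.reached_zero
    n_excluded = int(use.size - use.sum())
    flat = L.reshape(L.shape[0], -1)[:, use.ravel()].T  # (n_loc, n_t)
    t_end = fits.t_end_s.ravel()[use.ravel()][:, None]
    l0 = fits.l0_um.ravel()[use.ravel()][:, None]
    t_star = np.broadcast_to(t, flat.shape) / t_end
    l_star = flat / l0
    beyond = t[None, :] > t_end
    t_star = np.where(beyond, np.nan, t_star)
    l_star = np.where(beyond, np.nan, l_star)
    return NormalizedProfiles(t_star=t_star, l_star=l_star, n_excluded=n_excluded)


def profile_histogram(
    profiles: NormalizedProfiles,
    n_bins_t: int = 50,
    n_bins_l: int = 50,
    value_range: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.05), (0.0, 1.05)),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D histogram of all (t*, L*) samples.

    Samples are clipped into the histogram range so the total count equals
    the number of finite samples exactly.  Returns (counts, t_edges,
    l_edges) with counts indexed (t-bin, L-bin).
    """
    ts = profiles.t_star.ravel()
    ls = profiles.l_star.ravel()
    ok = np.isfinite(ts) & np.isfinite(ls)
    if not ok.any():
        raise ValueError("no profile samples to histogram")
    (t_lo, t_hi), (l_lo, l_hi) = value_range
    eps_t = (t_hi - t_lo) * 1e-9
    eps_l = (l_hi - l_lo) * 1e-9
    ts = np.clip(ts[ok], t_lo, t_hi - eps_t)
    ls = np.clip(ls[ok], l_lo, l_hi - eps_l)
    counts, t_edges, l_edges = np.histogram2d(
        ts, ls, bins=(n_bins_t, n_bins_l), range=value_range
    )
    return counts, t_edges, l_edges


def rate_map_and_stats(fits: DeclineFitMaps, exclusion: np.ndarray | None = None) -> RateStats:
    """Masked rate map with global mean/std and five-number summary.

    The standard deviation is the population value over valid locations.
    """
    valid = fits.valid & np.isfinite(fits.rate_mm_per_h)
    if exclusion is not None:
        valid = valid & ~exclusion
    if not valid.any():
        raise ValueError("no valid locations for rate statistics")
    rates = fits.rate_mm_per_h[valid]
    rate_map = np.where(valid, fits.rate_mm_per_h, np.nan)
    q1, med, q3 = np.percentile(rates, [25, 50, 75])
    return RateStats(
        rate_map=rate_map,
        mean=float(rates.mean()),
        std=float(rates.std()),
        minimum=float(rates.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(rates.max()),
        n_valid=int(valid.sum()),
    )


def rate_to_voxels_per_rotation(advance_um_per_rotation: float, voxel_um: float) -> float:
    """Front advance per full rotation expressed in voxels."""
    if not voxel_um > 0:
        raise ValueError("voxel size must be > 0")
    return advance_um_per_rotation / voxel_um
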