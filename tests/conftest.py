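import numpy as np
import pytest

import sublimap as sm


def small_phantom_config(**overrides) -> sm.PhantomConfig:
    """A 48^3, 30 um phantom whose regions fit the field of view."""
    base = dict(
        shape=(48, 48, 48),
        spacing_um=30.0,
        r_core_um=210.0,
        r_ice_outer_um=480.0,
        r_glass_outer_um=540.0,
        r_wrap_outer_um=600.0,
        l0_um=240.0,
        rate_um_per_h=0.0,
        timestamps_s=(0.0,),
        seed=0,
    )
    base.update(overrides)
    return sm.PhantomConfig(**base)


@pytest.fixture(scope="session")
def static_phantom():
    """One noise-free static frame plus its truth, shared across tests."""
    cfg = small_phantom_config(axis_offset_um=(60.0, -30.0), tilt_deg=1.0)
    vols, truth = sm.generate_phantom(cfg)
    return cfg, vols, truth


def true_pose(truth: sm.PhantomTruth) -> sm.VialPose:
    return sm.VialPose(point=truth.axis_point, direction=truth.axis_direction)


def glass_window(cfg: sm.PhantomConfig) -> tuple[float, float]:
    att = cfg.attenuation
    margin = 0.4 * min(abs(att.glass - att.ice), abs(att.glass - att.wrap))
    return (att.glass - margin, att.glass + margin)


def circle_points(center, radius, n, jitter=0.0, rng=None):
    """n points on a circle, optionally jittered."""
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.stack([center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)], axis=1)
    if jitter:
        pts = pts + (rng or np.random.default_rng(0)).normal(0, jitter, pts.shape)
    return pts


def kasa_circle_fit(points: np.ndarray) -> tuple[tuple[float, float], float]:
    """Algebraic least-squares circle fit (independent oracle for the RHT)."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    return (float(cx), float(cy)), float(np.sqrt(c + cx * cx + cy * cy))
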