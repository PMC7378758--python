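"""Cone-beam scan geometry and sliding-window reconstruction schedules.

A gantry-based micro-CT scanner magnifies the object by the ratio of the
source-detector and source-object distances; a continuous scan is cut into
overlapping reconstruction windows, each attributed to its mid-time.
"""

import sublimap as sm

geom = sm.ConeBeamGeometry(sdd_mm=365.7, sod_mm=109.7, pixel_pitch_um=100.0)
mag, px = sm.magnification_and_voxel(geom)
print(f"magnification {mag:.4f}, projected pixel {px:.2f} um")

# 35 rotations of 176.11 s, reconstructing one full rotation every half turn
sched = sm.reconstruction_schedule(35, 176.11, window=1, step=0.5)
print(f"{sched.n_volumes} volumes, one every {sched.interval_s / 60:.2f} min, "
      f"total {sched.total_span_s / 60:.0f} min")

# wedge-voxel rule: azimuthal divisions so the arc at the sample's outer
# edge equals the 30 um radial voxel
n_phi = sm.azimuthal_divisions(7639.0, 30.0)
print(f"{n_phi} azimuthal divisions at a 7.64 mm outer radius")

# a front advancing 180 um during one rotation crosses this many voxels
print(f"{sm.rate_to_voxels_per_rotation(180.0, 30.0):.0f} voxels per rotation at the fastest observed rate")
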