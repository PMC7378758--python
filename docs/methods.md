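# Methods

## The measurement problem

A spin-frozen vial holds its product as a near-cylindrical frozen layer on
the inner glass wall.  During primary drying the layer sublimates at its
inner (vacuum-facing) surface, so the relevant observable at each point of
the unwrapped cylinder (height h, azimuth Φ) is the radial ice thickness
L_ice(h, Φ, t) and how it declines.  `sublimap` turns a time series of
reconstructed attenuation volumes into those per-location observables.
Four regions matter radially, in ascending order: the inner vacuum, the
low-density dry cake (nearly invisible at typical contrast), the dense ice
annulus, and the glass wall with its heating wrap.  Because the cake is
invisible, all information is read from the dry-layer/ice interface — the
sublimation front — which is the inner edge of the segmented ice.

## Pose estimation

The vial axis is estimated from a single volume.  At `n_heights = 40`
evenly spaced slices (configurable), the glass wall is isolated by a grey
window; among the windowed pixels, only the fraction `retain_fraction =
0.10` with the largest radial gradient magnitude is kept.  The radial
gradient is the central-difference gradient of a Gaussian-smoothed copy
of the slice (σ = 1 px) projected on the ray from the slice centre; ties
break in lexicographic (row, col) order so the selection is
deterministic.  A randomized Hough transform samples `n_triplets = 5000`
non-degenerate random triplets of the retained pixels (degenerate
triplets, triangle area < 1e−6 px², are resampled and do not count),
computes each circumscribed circle, and accumulates (cx, cy, r) in
1-voxel bins.  The winning bin is the one with the highest count over its
3×3×3 bin neighbourhood — ties prefer larger radius (the outer wall),
then lexicographic centre — and the reported circle is the mean of the
votes in that neighbourhood, which recovers the centre to well below a
voxel on clean data.  The axis is the principal eigenvector of the
vote-count-weighted covariance of the per-slice centres (as 3D points),
through the weighted centroid, signed toward increasing height.  Each
slice draws from its own RNG stream spawned from one run seed, so repeat
runs with different seeds measure exactly the RHT's sampling noise.

Order of operations (window segmentation before gradient selection) and
the glass grey window itself are configuration; the defaults used on
phantoms derive from the configured attenuations.  On benchmark phantoms
(offset up to 10 voxels, tilt up to 2°, noise 10% of ice contrast) the
recovered axis is within a few hundredths of a voxel of truth at every
analysed height, and the 4-repeat spread is well below one accumulator
bin.  Translating the volume content by whole voxels translates the
estimate accordingly; because the top-10% gradient cut can flip a few
borderline pixels, equivariance is exact only to about 0.2 voxel, which
is how the property is tested.

## Cylindrical grid and resampling

The analysis grid follows the fitted axis: wedge voxels indexed
(h, Φ, r) with Δr = Δh = 30 µm by default (matching the Cartesian voxel
size) and `N_Φ = round(2πR/Δr)` azimuthal divisions, so a wedge's arc at
the outer radius R equals its radial size.  At the real sample's outer
radius (≈7.64 mm) this rule yields 1600 divisions — the projection count
per rotation.  Voxel centres sit at r_k = (k+0.5)Δr, Φ_j = (j+0.5)·2π/N_Φ
(right-handed about the axis, Φ = 0 toward world +x projected off the
axis) and h_i = h0 + i·Δh along the axis from a declared origin.

A reconstructor working natively on this grid would avoid interpolation
altogether; this package instead consumes already-reconstructed Cartesian
volumes and resamples them with order-3 spline interpolation
(`scipy.ndimage.map_coordinates`).  Samples leaving the Cartesian extent
are set to a fill value and flagged invalid rather than clamped, so
volume edges cannot leak into thickness maps.  The residual cost of this
choice is characterised in tests: rotating a phantom about its axis and
resampling agrees with rolling the cylindrical volume along Φ except for
sub-voxel rasterisation differences at rendered material edges (mean
deviation ≈1–2% of the ice attenuation within the ice band), and the
mean attenuation well inside the annulus is conserved to <1%.

One practical rule matters: the grid's outer radius must stay inside the
glass wall.  Partial-volume voxels on the glass→wrap boundary sweep
through ice-like grey values and would otherwise be picked up by the
segmentation; the pipeline's default radius is therefore
min(r_ice + 3Δr, r_glass − Δr).

## Segmentation chain

All operators treat Φ as periodic (wedge voxels across Φ = 0 are
physically adjacent) and replicate at the r and h boundaries.

* **Bilateral filter** — windowed sum with weights
  `exp(−d²/2σ_s²)·exp(−ΔI²/2σ_r²)`; the spatial Gaussian is sampled and
  truncated at `truncate` σ (default 3 in the API, 2 in the pipeline for
  speed).  With σ_r = ∞ it reduces exactly to the matching separable
  Gaussian, which is the test oracle.  Defaults on phantoms: σ_s = 1
  voxel, σ_r = max(2σ_noise, 20% of ice–dry contrast).
* **Dual threshold** — hysteresis semantics: voxels in the hard grey
  window are ice; voxels in the soft window (which must contain the hard
  one) are ice iff 26-connected, with Φ wrap, to a hard voxel.
  Connected components come from `scipy.ndimage.label`; components
  touching across the Φ seam are merged by union-find.  Phantom-derived
  default windows: ice mean ± max(3σ_noise, 25% of the smallest
  neighbouring contrast) (hard) and ± max(5σ_noise, 40%) capped below
  49% (soft) — instrument-dependent settings on real data.
* **3D median** — majority vote over an odd kernel (default 3³) on the
  binary labels, after thresholding.  It removes speckle up to a few
  voxels per window and, as a side effect, closes radial gaps of 1–2
  voxels — which bounds the smallest detectable cavity (below).
* **Edges** — per (h, Φ), the innermost and outermost ice r-indices and
  the ice voxel count along the ray; excluded locations carry a sentinel.
* **Surface angles** — 3×3×3 Sobel–Feldman gradients per axis; the angle
  is arccos(|g_r|/‖g‖) in degrees, so inner and outer surfaces give the
  same value in [0°, 90°]; voxels with gradient magnitude below a floor
  are invalid.  The per-location surface angle is sampled at the
  innermost ice voxel — the sublimation front.
* **Exclusion masks** — unions of height bands and (h, Φ) rectangles,
  declared in configuration; they stand in for sensor shadows and the
  vial's narrowing neck, which are excluded rather than corrected.

## Thickness convention and intrusions

"Radial distance between the first and the last segmented voxel" is
ambiguous between centre-to-centre and extent; the extent convention
`L_ice = (last − first + 1)·Δr` is used so a single-voxel layer has
thickness Δr rather than zero.  `L′ = count·Δr` integrates actual ice
along the ray; an intrusion is flagged exactly where `L′ < L_ice`.
Because the median filter closes 1–2-voxel gaps, a cavity is reliably
flagged where its radial chord spans ≥3 voxels; narrower fringes may
close, which is the stated detection limit.

## Time attribution and sublimation times

Each reconstructed volume is attributed the midpoint of its sliding
reconstruction window.  Schedule arithmetic: with `n` rotations of period
T, window w and step s (in rotations), there are `floor((n−w)/s)+1`
volumes; volume i spans [i·s·T, i·s·T + w·T].  Times are recomputed from
(i, s, T) on demand, so a recompute is bit-identical to the stored list.
The per-location sublimation time is the mid-timestamp of the first frame
opening a run of `persistence` consecutive ice-free frames;
`persistence = 1` by default, with 2 recommended when fast-moving edges
make segmentation flicker.  Post-sublimation attenuation averages a
per-location attenuation series (mean over the initial ice band in the
pipeline) over frames strictly after that time.

## Decline model

Per location, t_end is the timestamp of the earliest frame whose
thickness is closest to zero (ties earliest).  An OLS line is fitted to
L_ice(t) over frames with t ≤ t_end; the rate is −slope in mm/h.  OLS is
a deliberate simplification — the decline model summarises the 4D data,
it does not model heat or mass transfer.  Locations with zero initial
thickness or a single-frame window are invalid; an exactly constant
positive series is the one single-frame-window case treated as a valid
zero-rate fit (its flat line is exact).  A `reached_zero` flag records
whether the series actually attained (near-)zero, so profiles that never
fully dry — common for pure water — can be excluded from normalised
histograms on request; by default they are included with t_end at the
series minimum.  The vectorised fitter groups locations by their t_end
frame index and applies the closed-form OLS estimator per group; it is
exactly the scalar estimator, and is tested against it.

Normalised profiles use t* = t/t_end and L* = L_ice/L_ice(0); histograms
default to 50×50 bins over [0, 1.05]², with samples clipped into range so
the total count equals the number of finite samples exactly.

## The phantom generator

The generator renders, per time point, concentric regions around a
configurable axis (offset in x/y, tilt with azimuth): vacuum core
(r < r_core), dry cake [r_core, R_i(t)), ice [R_i(t), r_ice), glass
[r_ice, r_glass), wrap [r_glass, r_wrap), background beyond.  The ice
inner radius is R_i(t) = r_ice − L(h, Φ, t) with
L = max(0, L0 − ρ·t) from per-location initial-thickness and rate fields
(bilinear, Φ-periodic); cracks are rectangular (h, Φ) notches removing a
fixed radial depth from the inner surface, cavities are ellipsoidal voids
in (h, arc, r).  Voxel values are partial-volume means over a 2×2×2
subgrid of region attenuations (configurable; counting-based checks in
the tests use 4×4×4 where the eighth-step quantization of the default
would bias midpoint thresholding), plus optional Gaussian noise with one
RNG stream per frame spawned from the config seed — regeneration is
bit-identical.

Region attenuations are free parameters, not calibrated to any
instrument: vacuum 0, dry 6, wrap 60, ice 100, glass 220 (arbitrary
units).  The ordering — dry barely above vacuum, ice well above wrap,
glass highest — reproduces the regime where the cake is invisible and
all contrast lives at the ice interfaces.  What the phantom does *not*
emulate: projection-domain physics (no sinograms, beam hardening, rings
or streaks), motion blur within a reconstruction window, the vial's
curved bottom and narrowing neck (the layer spans the full height;
exclusion masks stand in for the neck), and real freeze-drying
microstructure.  Passing tests therefore demonstrate the correctness of
the geometry, segmentation and kinetics chain under controlled contrast
and noise — not robustness to reconstruction artefacts, which on real
scans must be handled by window choice, exclusion regions and the
persistence parameter.

## Benchmark problem sizes

The standard desk-scale benchmarks (in `sublimap.evaluation`, driven by
`scripts/acceptance.py` and the acceptance tests) use: a 128³ pose
phantom at 30 µm voxels with (8, −7)-voxel offset, 1.5° tilt and noise at
10% of the ice contrast; a 96³ noise-free thickness phantom with and
without a buried cavity; and a 128³, 20-frame kinetics phantom with rates
drawn uniformly in [0.5, 1.5] mm/h on a coarse node grid, frames every
2.93 min, and L0 = rate × scan span so every location declines linearly
to zero exactly at the last frame.  That initial-thickness choice makes
the normalised-profile anti-diagonal statement exact in truth and leaves
the OLS window unclipped.  The measured (through-segmentation) histogram
of the same phantom concentrates ≈87% of its mass within one bin of the
anti-diagonal rather than ≥95%: the shortfall is confined to late-time
samples where the remaining layer is 2–3 voxels thick and 30 µm
quantization plus noise flicker dominate — the same smearing seen in
real-scan profile histograms.  Both numbers are reported.

## Numerical choices and edge cases

* Accumulator bins are 1 voxel in (cx, cy, r); sub-voxel precision comes
  from averaging the votes of the winning 3×3×3 bin neighbourhood.
* Resampling fill values never enter maps: invalidity is tracked
  explicitly.
* `azimuthal_divisions` rounds to nearest; Δr = Δh = 30 µm defaults.
* Rates are µm/s internally and mm/h in every output; the single
  conversion constant lives in the kinetics module.
* Histograms clip into range rather than dropping samples (exact count
  conservation).
* The rate statistic's standard deviation is the population value over
  valid map locations.
* Degenerate inputs raise early with the offending frame/region named:
  unordered timestamps, shape mismatches, out-of-grid exclusion regions,
  windows with lo ≥ hi, soft windows not containing hard ones, fewer
  than 3 RHT points, axes outside the volume.

## Known limitations

Segmentation accuracy is bounded by the voxel size: thickness is exact
to ±1 voxel, layers thinner than ~1.5 voxels vanish under the majority
median, and cavities with sub-3-voxel chords may close.  The bilateral
filter is O(window³) per voxel; pipeline defaults (σ_s = 1, truncate 2)
keep a 20-frame 128³-scale run in minutes on one CPU.  The pose model
assumes circular cross-sections (no ellipse fitting) and a single static
pose per scan (no per-frame motion correction).  Real-scan phenomena the
phantom does not produce — streaks near thermocouples, motion artefacts
at fast fronts — are handled operationally (exclusion regions, larger
persistence), not corrected.
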