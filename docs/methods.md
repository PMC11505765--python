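# Methods

This note documents the physical models, numerical choices and known
limitations of `rm3d`. Everything stated here is computed by the package's
tests or scripts; nothing is quoted from external measurements.

## Scope and model chain

The package studies passive depth-modulation of a single-energy scanned
proton beam by a 3D-printed range-modulator (RM): an array of pins on a
3 mm lateral period whose local material thickness maps lateral position to
water-equivalent thickness (WET), spreading the pristine Bragg peak into a
spread-out Bragg peak (SOBP). The model chain is

1. an analytic depth-dose kernel (Bortfeld parametrization),
2. SOBP layer-weight optimization and pin-contour construction,
3. exact WET ray tracing through the (possibly rigidly transformed)
   modulator solid,
4. a deterministic pencil-beam dose engine in a water phantom,
5. local gamma-index comparison of reference vs. misaligned setups.

Coordinates are right-handed, the beam travels toward +z, the isocenter is
z = 0, and all internal lengths are mm.

## Depth-dose kernel

The pristine curve uses the Bortfeld analytic Bragg parametrization
(parabolic-cylinder form near the peak, the straggling-free closed form far
upstream), with intrinsic range straggling `sigma = 0.012 R0^0.935` (cm) and
a low-energy tail fraction `eps = 0.1`, chosen to keep the peak-to-entrance
ratio in the 3–4 range typical of a 250 MeV beam (measured 3.45). The
tabulation (0.5 mm steps, to 1.2 x range) is then shifted so the distal 80%
falloff depth equals the Bragg–Kleeman law `R = alpha E^p` with
`alpha = 0.0022 cm MeV^-p`, `p = 1.77` (386.2 mm at 250 MeV): the *range
calibration* is exact by construction, and any upstream WET acts as a pure
translation of the curve. The mean excitation energy of water (I = 78 eV)
is carried on the material record as documentation; the range calibration
subsumes it. Beam momentum spread is zero by default; an optional extra
straggling width is exposed but unused in the study.

Nuclear fluence attenuation is available as a simple exponential factor per
cm (default off): SOBP flatness and misalignment sensitivity are
WET-distribution effects, and an attenuation common to reference and
modified runs cancels from every comparison.

## Beam line and lateral transport

Spots are deflected at two points (Y magnet at z = −2560 mm, X magnet at
−2000 mm) so the central trajectory crosses the requested (x, y) at the
isocenter; downstream positions therefore *magnify* about the magnet points
(about +20% at 400 mm depth for the X axis), which the engine applies per
scored depth. The source is 3 mm FWHM with 1 mrad Gaussian divergence.

Lateral spread combines, in quadrature: source size, free divergence
growth, and multiple Coulomb scattering integrated Fermi–Eyges style — a
Highland scattering power `(13.6 MeV / pv)^2 / X0` with the per-slab
logarithmic correction, the beam energy degraded along the stack via
residual range, and the lever arm `(z_eval − l)^2` to the scoring plane.
Radiation lengths come from a small built-in table (water 360.8 mm, PMMA
340.7 mm, printer resin 340 mm). Behind the 17–20 cm pre-absorber the
absorber term dominates (sigma ≈ 5–10 mm in the phantom), which is why the
thin-modulator approximation below is benign for dose.

## SOBP design

Layer pullbacks step by 3 mm of WET (the pin period in water-equivalent
terms). The deepest layer is pulled back `R80 − distal − 0.5 mm`; the extra
0.5 mm *distal overshoot*, together with ending the unit-plateau fit
2.5 mm before the distal edge, places the composed SOBP's distal 80%
falloff on the requested distal depth within 0.3 mm while keeping the
plateau interior (edges excluded by one WET step) flat to < 1%. Weights are
solved by non-negative least squares on a 0.5 mm depth grid with a small
second-difference penalty (0.03). The penalty matters: the straggled peak
(sigma 3.7 mm) is wider than the 3 mm layer step, so the unregularized
problem is overcomplete and NNLS returns a sparse vertex with whole layers
zeroed — which would translate into double-height pin risers, bad for both
printability and tilt robustness. The chosen value is the smallest that
removes the zeros while preserving the 1% flatness contract.

A step pin encodes weight k as a concentric square ring of area fraction
w_k at physical height `pullback_k / RSP`, widest (deepest) ring outermost,
tip at the cell center. The stepless contour interpolates the cumulative
area-vs-WET staircase with a monotone (PCHIP) spline through its exact
bin-edge knots and inverts it, so re-binning at the design step recovers
every weight to better than 1e-3. Half of the deepest layer's mass is kept
as a flat valley floor rather than interpolated: printed stepless
modulators have a flat valley between pins, and a full interpolation would
bias the deepest layer's mass half a bin shallower, softening the distal
SOBP edge by ~1.5%.

## Cube modulator

The study target is a 6 cm cube rotated 45° about x then y, corner toward
the nozzle: in beam's eye view it spans SOBP lengths from 0 up to 84.9 mm
(the central chord `60/cos45°`·…, computed analytically by slab
intersection in the cube frame) over a 102.4 mm depth extent. Its center
depth is not an external datum; the default places the deepest distal edge
exactly at the post-absorber, post-base-layer calibrated range (cube
spanning ≈ 77–179 mm of phantom depth, consistent with proximal/distal
analysis slices at 110/160 mm). Each 3 mm cell whose center falls inside
the silhouette (dilated by one cell) gets a weight solve for its own depth
interval — cached per quantized interval length, since the pristine curve
makes the solution shift-invariant — plus a compensator offset (uniform
extra height) parking its deepest Bragg peak on its own distal edge. An
8 mm base layer sits under all pins and 2 mm protection walls ring the
footprint. Spot MUs follow the per-pin fluence demand (the unnormalized
weight total), a documented stand-in for the treatment planning system's
proprietary optimization; every robustness comparison is engine-vs-engine
and independent of the exact MU pattern.

## Geometry sampling (WET sample tables)

The dose engine consumes a *WET sample table*: lab-frame axial rays with
exact material path lengths and area weights. Rays form per-cell lattices
whose offsets vary per lattice line (a low-discrepancy sequence per row and
column); this matters because a lattice aligned with the pin grid aliases
the thin concentric rings — a 0.25 mm cell-aligned lattice sees only ~6
Chebyshev shells per 3 mm cell and corrupts the encoded weight
distribution. With line-decorrelated offsets the aggregated WET
distribution converges to the exact area fractions (≤ 1% per layer at 24
rays/cell/axis, ≤ 0.1% at 36).

Each ray is intersected *analytically* with the modulator solid: pins
decompose into stacked axis-aligned boxes (one per tier), and base slab and
walls are boxes, so identity, translations, and rotations about a lateral
or the beam axis reduce to exact slab-interval intersections — no raster,
no tessellation, no Monte Carlo noise. Stepless profiles are quantized into
0.25–0.5 mm tiers for the oblique path only (the axial path evaluates the
continuous profile exactly). The tessellated-STL route (watertight
wedding-cake shells, MeshLab-style transform, axial ray casting of the
triangles) exists in parallel and is tested to agree with the analytic
solid; the scenario runner uses the analytic route by default because it is
the same rigid-body operation without tessellation error and orders of
magnitude cheaper at full pin counts.

An optional `in_pin_scatter` mode replaces each ray by a symmetric
five-direction ensemble at the in-pin Highland scattering slope, emulating
the lateral wander of protons inside tall pin columns. It is off by
default: the crude quadrature pushes ensemble tails into the nonlinear
(> 1°) tilt regime and degrades 0° fidelity more than it helps.

## Dose engine

Per scan spot, the fluence at the modulator plane is the spot Gaussian
(source size + divergence growth, sigma ≈ 2.7 mm there); the total field is
deposited cloud-in-cell on a fine grid and blurred once. Sample rays pick
up their column's WET plus the absorber WET and are histogrammed into
(WET bin, lateral pixel). Dose at depth z is the superposition over WET
bins of the pulled-back Bragg curve, each bin's fluence map convolved with
the depth-dependent scattering kernel (bins grouped into 12 mm WET classes
for the kernel), magnified about the magnets, and resampled onto the
scoring grid (2.5 mm lateral, 1 mm depth — the detector-array resolution
the study standardizes on). The modulator's WET is assigned at the
modulator plane (thin-modulator approximation) and in-pin scattering is
neglected for dose; both are justified by absorber-dominated lateral
spread. Everything is deterministic and linear in MU; doses are in
arbitrary units (comparisons normalize to plateau means or are local-gamma
based, so the unit never matters).

For planar fluence maps (the pin-grid texture study) the per-bin blur uses
the spread accumulated *up to the scoring plane*, including scattering
inside the pin column itself — there the in-pin term is the whole effect:
directly behind the modulator the tall-pin regions are locally smeared
while valleys stay sharp (coefficient of variation ≈ 0.27 on the 3 mm
pattern), and 17 cm of PMMA later the pattern is gone (CoV ≈ 0.05, the
residual being spot-grid ripple).

For a *single pencil beam* through a uniform 2D RM, the center-line depth
dose is diluted by lateral spread growth (the beam widens with depth), so
SOBP flatness and tilt metrics use the laterally *integrated* depth dose —
exact, since lateral transport integrates out — which is flat for an ideal
modulator and is the natural analogue of a plotted SOBP curve.

## Gamma index

Local-normalization gamma per reference voxel with dose criterion 2%, DTA
2 mm, low-dose threshold 20% of the maximum: the evaluated distribution is
linearly interpolated at offsets on a grid of dta/10 within a radius of
3 x dta, offsets scanned in increasing radius with early termination once
the spatial term alone exceeds the worst current minimum. Voxels below the
threshold are excluded before normalization, so no division by zero can
occur. Slice gamma is 2D-within-slice (a planar-detector comparison).
Passing rates are kept at full precision internally and rounded to integer
percent only in the report table. The test suite checks the implementation
against an independent brute-force dense-search oracle on random fields
(agreement ≤ 0.01 in gamma).

## Misalignment study

Reference: 170 mm PMMA ending 50 mm before the water phantom surface
(isocenter at the surface), modulator 5 mm upstream of the absorber.
Baseline (no modulator): 200 mm PMMA, isocenter 90 mm inside the phantom.
Scenarios shift the plan (+1 mm X), translate the modulator (+1.5 mm X,
+1.5 mm X/Y) or rotate it (0.5°, 1.5° about Y) around a pivot 200 mm in −x
and 180 mm upstream of the modulator's own isocenter (footprint center at
the pin-base plane — a stated convention). Each scenario is scored with 2D
gamma at 110/160 mm, the center-line SOBP deviation, and the lateral
displacement of the distal 80% isodose surface (row-wise 1D registration
of the distal crossing-depth maps at 0.05 mm resolution).

The center-line SOBP metric is evaluated on the reference profile's
*actual* plateau (where it stays within 98% of its inner mean). The cube's
distal surface slopes away from the central chord, so lateral scattering
pulls the delivered center-line distal edge ~6 mm shallower than the
geometric design interval; evaluating into that falloff would measure
range-edge displacement, not plateau change.

### Problem sizes

The default "desk" profile uses 12 sample rays per cell and axis, 1 mm WET
bins and fluence pixels, the full 80 x 80 mm² / 5 mm-spacing plan (289
spots), and the full scoring grid; a cube-RM dose computes in a few
seconds and the complete five-scenario study in under a minute on one
core. The "pencil"/"full" profiles double the sampling density for 2D-RM
and convergence work. These sizes are the package's standard operating
points; all reported comparisons are converged against them (halving the
discretization moves gamma rates by < 1 point and SOBP metrics by < 0.1%,
except where noted).

## Known limitations

- Straight-ray optics inside the modulator: no condensed-history transport
  in the pins. Consequence: the SOBP response to *small* tilts of
  staircase pins is overestimated — tilt "corner-cutting" at each ring
  riser moves first-order mass into intermediate path lengths that real
  in-pin scattering already populates at 0°. At 0.5° tilt the package
  measures a ~0.6% maximum SOBP deviation where condensed-history
  simulation reports ≤ 0.2% (itself below that simulation's 0.7%
  statistical noise); at 1–2° the degradation is nonperturbative and the
  engines agree qualitatively (central Gaussian-like peak, monotone
  worsening).
- No nuclear secondaries, LET, or RBE; fluence attenuation only as an
  optional exponential.
- Water-box phantom and analytic targets only; no CT, DICOM or patient
  anatomy.
- The spot-MU heuristic is flat-demand based, not a dose optimization:
  absolute lateral dose edges are approximate (all comparisons are
  engine-vs-engine, so this cancels).
- The synthetic study is noise-free by construction; agreement levels
  quoted for gamma comparisons say nothing about detector noise,
  positioning reproducibility or printing artifacts in real deliveries.
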