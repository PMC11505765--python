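# rm3d — 3D range-modulators for single-energy proton therapy

`rm3d` is a research toolkit for **3D range-modulators** (3D RM): passive,
3D-printable pin arrays that spread the Bragg peak of a single-energy
scanned proton beam into a target-conformal dose, replacing active energy
switching — the beam-delivery approach behind ultra-fast and FLASH-capable
proton treatments. It is aimed at medical physicists and beam-modelling
researchers who want to design modulators, simulate the delivered dose, and
quantify how sensitive that dose is to modulator misalignment, without
running full Monte Carlo transport.

The package covers the whole chain:

- **Beam model** — analytic Bragg curves in water (Bortfeld
  parametrization), range-calibrated to the Bragg–Kleeman law
  `R = αE^p` (α = 0.0022 cm·MeV⁻ᵖ, p = 1.77); Highland/Fermi–Eyges lateral
  scattering; two-point magnet deflection of scan spots.
- **SOBP design** — non-negative least-squares layer weights `w` such that
  `Σₖ wₖ D(z + Δₖ)` is flat on a chosen plateau, where `D` is the pristine
  depth-dose and `Δₖ` the per-layer WET pullback.
- **Pin contours** — each weight becomes a concentric ring whose *partial
  area is proportional to the weight of its Bragg peak*, as a discrete
  staircase ("step") or a quasi-continuous interpolated profile
  ("stepless").
- **Target-specific modulators** — per-pin SOBP intervals from analytic
  ray–target intersection (the study target is a 6 cm cube rotated 45°/45°),
  compensator offsets, base layer, walls; STL export (binary and ASCII).
- **Dose engine** — deterministic pencil-beam superposition: exact WET ray
  tracing through the (possibly rigidly transformed) modulator solid,
  fluence-weighted Bragg-curve superposition with depth-dependent Gaussian
  lateral kernels, scored on a 2.5 mm × 1 mm grid.
- **Gamma analysis** — local gamma index γ(r) = min over e of
  √[(|e−r|/2 mm)² + ((Dₑ(e)−Dᵣ(r))/(2% · Dᵣ(r)))²] with a 20% low-dose
  threshold, in 1D/2D/3D, plus SOBP flatness/deviation metrics.
- **Scenario pipeline** — reference vs. misaligned simulations (field
  shift, modulator shifts and rotations, tilt sweeps of uniform 2D RMs)
  with Table-style gamma reports.

## Worked example

Design the pin of a uniform 2D modulator that delivers a flat 10 cm SOBP in
water behind a 17 cm PMMA pre-absorber:

```python
import numpy as np
from rm3d.beam_model import bragg_curve, wet_of_slab, PMMA, RIGUR
from rm3d.sobp_design import (optimize_sobp_weights, sobp_base_pullback,
                              weights_to_step_contour)

curve = bragg_curve(250.0)
print(f"range_80 = {curve.range_80:.1f} mm, "
      f"peak/entrance = {curve.peak_to_entrance:.2f}")

absorber_wet = wet_of_slab(PMMA, 170.0)
distal = curve.range_80 - absorber_wet - wet_of_slab(RIGUR, 8.0) - 0.5
proximal = distal - 100.0

w = optimize_sobp_weights(curve, proximal, distal)
pin = weights_to_step_contour(w, 3.0, RIGUR)
print(f"layers = {len(w.weights)}, deepest weight = {w.weights[0]:.3f}")
print(f"pin: {len(pin.levels_height_mm)} levels, "
      f"tip height = {pin.max_height:.2f} mm")

z = np.arange(proximal + 3, distal - 3, 0.25)
base = sobp_base_pullback(curve, distal)
d = sum(wt * curve.at(z + base + pb)
        for wt, pb in zip(w.weights, w.pullbacks_mm))
print(f"plateau flatness = {100*np.max(np.abs(d-d.mean()))/d.mean():.2f}%")
```

prints

```
range_80 = 386.2 mm, peak/entrance = 3.45
layers = 35, deepest weight = 0.336
pin: 35 levels, tip height = 87.55 mm
plateau flatness = 0.94%
```

i.e. a 250 MeV beam reaches 386 mm in water; behind 197 mm of absorber WET
the modulator must cover a 79–179 mm plateau, which takes 35 layers at 3 mm
WET steps and a pin 87.6 mm tall on a 3 mm base — and the optimized weights
reproduce the plateau flat to 0.94%.

The misalignment study runs from the command line:

```sh
rm3d report                      # all five misalignment scenarios + table
rm3d tilt-sweep --angles 0,0.5,1,2
rm3d build-cube --out cube_rm.stl
rm3d gamma reference.h5 modified.h5 --dd 2 --dta 2 --local --threshold 0.2
```

`rm3d report` prints the per-scenario proximal (11 cm) and distal (16 cm)
2D gamma passing rates — e.g. a +1 mm field shift or a +1.5 mm modulator
shift passes 100%/100%, while a 1.5° modulator rotation collapses to
~78%/27% — the quantitative version of "align the modulator to better than
a degree".

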