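"""Beam-line model: materials, analytic Bragg curves, scattering and scan geometry.

The depth-dose kernel is the Bortfeld analytic parametrization of a proton
Bragg curve in water, calibrated so that the distal 80% falloff depth follows
the power law R(E) = alpha * E**p with alpha = 0.0022 cm/MeV**p and p = 1.77.
Lateral spread combines the source emittance (size + divergence) with multiple
Coulomb scattering in the traversed material stack, computed with a
Highland-type scattering power integrated Fermi-Eyges style (second angular
moment with the lever arm to the evaluation plane).

Coordinates are right-handed, the beam travels toward +z, the isocenter is at
z = 0 and every length is in mm unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import pbdv

__all__ = [
    "Material",
    "WATER",
    "PMMA",
    "RIGUR",
    "AIR",
    "MATERIALS",
    "BraggCurve",
    "BeamLine",
    "ScanSpot",
    "SpotTrajectory",
    "bragg_curve",
    "wet_of_slab",
    "spot_direction",
    "lateral_sigma",
    "scatter_sigma",
    "proton_pv",
    "range_from_energy",
    "energy_from_range",
]

# Bragg-Kleeman range power law in water, R in cm, E in MeV.
ALPHA_CM = 0.0022
P_EXP = 1.77

PROTON_MASS_MEV = 938.272


@dataclass(frozen=True)
class Material:
    """A beam-line material.

    ``relative_stopping_power`` (RSP) converts physical thickness to
    water-equivalent thickness; ``radiation_length_mm`` feeds the Highland
    scattering model.  ``excitation_energy_ev`` is carried as metadata only
    (it labels the water calibration, it does not enter the range law).
    """

    name: str
    density: float  # g/cm^3
    relative_stopping_power: float
    radiation_length_mm: float
    excitation_energy_ev: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.relative_stopping_power <= 0:
            raise ValueError("relative_stopping_power must be > 0")


WATER = Material("water", 1.0, 1.0, 360.8, excitation_energy_ev=78.0)
PMMA = Material("pmma", 1.19, 1.16, 340.7)
# Polymerized printer resin; density printed by the vendor, RSP defaulted
# PMMA-like and configurable (no measured value available).
RIGUR = Material("rigur", 1.2, 1.165, 340.0)
AIR = Material("air", 1.205e-3, 1.064e-3, 3.039e5)

MATERIALS = {m.name: m for m in (WATER, PMMA, RIGUR, AIR)}


def range_from_energy(energy_mev: float) -> float:
    """Bragg-Kleeman 80% range in water, mm."""
    return 10.0 * ALPHA_CM * energy_mev**P_EXP


def energy_from_range(range_mm) -> np.ndarray:
    """Inverse of :func:`range_from_energy` (vectorized)."""
    r_cm = np.asarray(range_mm, dtype=float) / 10.0
    return (np.maximum(r_cm, 1e-9) / ALPHA_CM) ** (1.0 / P_EXP)


def proton_pv(energy_mev) -> np.ndarray:
    """Proton momentum*velocity (beta*p*c) in MeV for kinetic energy in MeV."""
    e = np.asarray(energy_mev, dtype=float)
    pc = np.sqrt(e**2 + 2.0 * e * PROTON_MASS_MEV)
    beta = pc / (e + PROTON_MASS_MEV)
    return beta * pc


def wet_of_slab(material: Material, physical_thickness_mm: float) -> float:
    """Water-equivalent thickness of a slab: thickness x RSP."""
    if physical_thickness_mm < 0:
        raise ValueError("slab thickness must be >= 0")
    return physical_thickness_mm * material.relative_stopping_power


@dataclass
class BraggCurve:
    """Tabulated depth-dose of a monoenergetic beam in water.

    ``depth_mm`` is water-equivalent depth, ``dose`` is relative dose per unit
    fluence normalized to a peak value of 1.  ``range_80`` is the distal 80%
    falloff depth; the tabulation is range-calibrated so that it matches the
    Bragg-Kleeman law to well below the sampling step.
    """

    energy_mev: float
    depth_mm: np.ndarray
    dose: np.ndarray
    range_80: float

    def at(self, depth_mm) -> np.ndarray:
        """Dose at arbitrary depths; zero outside the tabulated support."""
        return np.interp(np.asarray(depth_mm, dtype=float), self.depth_mm, self.dose,
                         left=self.dose[0], right=0.0)

    def pulled_back(self, wet_mm: float) -> "BraggCurve":
        """Curve behind an upstream slab of the given WET (pure translation)."""
        return replace(
            self,
            dose=self.at(self.depth_mm + wet_mm),
            range_80=self.range_80 - wet_mm,
        )

    @property
    def peak_depth(self) -> float:
        return float(self.depth_mm[int(np.argmax(self.dose))])

    @property
    def peak_to_entrance(self) -> float:
        return float(self.dose.max() / self.dose[0])


def _bortfeld_shape(z_cm: np.ndarray, r0_cm: float, sigma_cm: float,
                    eps: float) -> np.ndarray:
    """Bortfeld analytic Bragg curve (arbitrary units), piecewise evaluated.

    Far upstream of the peak the straggling-free closed form is used; within
    ~10 sigma of the range the parabolic-cylinder-function form with range
    straggling sigma applies; beyond r0 + 5 sigma the dose is zero.
    """
    z = np.asarray(z_cm, dtype=float)
    d = np.zeros_like(z)
    zeta = (r0_cm - z) / sigma_cm

    plateau = zeta > 10.0
    if np.any(plateau):
        rz = r0_cm - z[plateau]
        d[plateau] = (17.93 * rz ** (-0.435)
                      + (0.444 + 31.7 * eps / r0_cm) * rz**0.565)

    peak = (zeta <= 10.0) & (zeta >= -5.0)
    if np.any(peak):
        zp = zeta[peak]
        d1 = pbdv(-0.565, -zp)[0]
        d2 = pbdv(-1.565, -zp)[0]
        d[peak] = (np.exp(-(zp**2) / 4.0) * sigma_cm**0.565
                   * ((11.26 / sigma_cm) * d1
                      + (0.157 + 11.26 * eps / r0_cm) * d2))
    return d


def bragg_curve(energy_mev: float, depth_step_mm: float = 0.5, *,
                eps: float = 0.1, extra_straggling_mm: float = 0.0) -> BraggCurve:
    """Analytic Bragg curve in water, range-calibrated, sampled to 1.2 x range.

    Parameters
    ----------
    energy_mev : beam kinetic energy, valid on [1, 300] MeV.
    depth_step_mm : sampling step of the tabulation.
    eps : fraction of primary fluence in the low-energy tail (Bortfeld's
        epsilon); raises the entrance dose slightly.
    extra_straggling_mm : optional additional Gaussian range spread (quadrature
        with the intrinsic straggling); the knob standing in for a nonzero
        beam momentum spread, default 0 (the delivery studied here uses none).
    """
    if not (1.0 <= energy_mev <= 300.0):
        raise ValueError(f"energy {energy_mev} MeV outside supported [1, 300]")
    if depth_step_mm <= 0:
        raise ValueError("depth_step must be > 0")

    r_target_mm = range_from_energy(energy_mev)
    r0_cm = r_target_mm / 10.0
    sigma_cm = np.hypot(0.012 * r0_cm**0.935, extra_straggling_mm / 10.0)

    depth = np.arange(0.0, 1.2 * r_target_mm + depth_step_mm, depth_step_mm)
    dose = _bortfeld_shape(depth / 10.0, r0_cm, sigma_cm, eps)
    dose = np.clip(dose, 0.0, None)
    dose /= dose.max()

    # Range calibration: shift the tabulation so the measured distal 80%
    # crossing lands exactly on the Bragg-Kleeman range.
    d80_raw = _distal_falloff_depth(depth, dose, 0.8)
    shift = r_target_mm - d80_raw
    dose = np.interp(depth - shift, depth, dose, left=dose[0], right=0.0)

    curve = BraggCurve(energy_mev, depth, dose,
                       _distal_falloff_depth(depth, dose, 0.8))
    return curve


def _distal_falloff_depth(depth: np.ndarray, dose: np.ndarray,
                          level: float) -> float:
    """Depth of the distal crossing of ``level * max(dose)``."""
    target = level * dose.max()
    ipk = int(np.argmax(dose))
    distal = dose[ipk:]
    below = np.nonzero(distal < target)[0]
    if below.size == 0:
        return float(depth[-1])
    j = below[0]
    d1, d0 = distal[j], distal[j - 1]
    frac = (d0 - target) / (d0 - d1)
    return float(depth[ipk + j - 1] + frac * (depth[ipk + j] - depth[ipk + j - 1]))


@dataclass(frozen=True)
class BeamLine:
    """Scanned-beam source geometry of a compact gantry beam line.

    The beam starts at ``source_plane_z`` travelling +z, is deflected in Y at
    ``y_magnet_z`` and in X at ``x_magnet_z`` so that the central trajectory
    crosses the requested spot position at the isocenter plane z = 0.
    """

    energy_mev: float = 250.0
    momentum_spread: float = 0.0
    source_plane_z: float = -2560.0
    x_magnet_z: float = -2000.0
    y_magnet_z: float = -2560.0
    initial_fwhm_mm: float = 3.0
    divergence_sigma_mrad: float = 1.0

    def __post_init__(self) -> None:
        if not (self.source_plane_z <= self.y_magnet_z <= self.x_magnet_z < 0):
            raise ValueError("magnet ordering must satisfy "
                             "source <= y_magnet <= x_magnet < 0")
        if self.initial_fwhm_mm <= 0:
            raise ValueError("initial_fwhm must be > 0")

    @property
    def source_sigma_mm(self) -> float:
        return self.initial_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ScanSpot:
    """One raster position (at the isocenter plane) with its monitor units."""

    x: float
    y: float
    mu: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("spot MU must be >= 0")


@dataclass(frozen=True)
class SpotTrajectory:
    """Piecewise-linear central trajectory of a scan spot."""

    spot: ScanSpot
    beamline: BeamLine
    kick_x_mrad: float
    kick_y_mrad: float
    direction: tuple[float, float, float]

    def position_at(self, z: float | np.ndarray):
        """Central (x, y) of the trajectory at plane z (vectorized in z)."""
        z = np.asarray(z, dtype=float)
        bl = self.beamline
        x = np.where(z >= bl.x_magnet_z,
                     self.spot.x * (z - bl.x_magnet_z) / (0.0 - bl.x_magnet_z),
                     0.0)
        y = np.where(z >= bl.y_magnet_z,
                     self.spot.y * (z - bl.y_magnet_z) / (0.0 - bl.y_magnet_z),
                     0.0)
        return x, y


def spot_direction(spot: ScanSpot, beamline: BeamLine) -> SpotTrajectory:
    """Two-point deflection geometry of a scan spot.

    The kick angles are the unique pair that steers the trajectory through
    (spot.x, spot.y) at z = 0 with a Y kick at the Y magnet and an X kick at
    the X magnet.
    """
    tan_x = spot.x / (0.0 - beamline.x_magnet_z)
    tan_y = spot.y / (0.0 - beamline.y_magnet_z)
    d = np.array([tan_x, tan_y, 1.0])
    d /= np.linalg.norm(d)
    return SpotTrajectory(
        spot=spot,
        beamline=beamline,
        kick_x_mrad=float(np.arctan(tan_x) * 1e3),
        kick_y_mrad=float(np.arctan(tan_y) * 1e3),
        direction=(float(d[0]), float(d[1]), float(d[2])),
    )


def scatter_sigma(stack: list[tuple[Material, float]], z_eval,
                  energy_mev: float = 250.0, *, step_mm: float = 2.0,
                  z_entry: float = 0.0) -> np.ndarray:
    """Lateral scattering sigma at plane(s) z_eval behind a material stack.

    ``stack`` lists (material, physical thickness) slabs in beam order,
    starting at ``z_entry``; gaps between slabs are not represented (insert
    explicit air slabs if the drift matters — in practice air scatter is
    negligible and only the slab-to-plane lever arms count, which are encoded
    by each slab's position along z).

    Uses a differential Highland scattering power with the beam energy
    degraded along the stack via residual range, and accumulates the second
    lateral moment sum T(l) * dl * (z_eval - l)^2 (Fermi-Eyges).
    """
    z_eval = np.atleast_1d(np.asarray(z_eval, dtype=float))
    sig2 = np.zeros_like(z_eval)
    residual = range_from_energy(energy_mev)
    z = z_entry
    for mat, thick in stack:
        if thick <= 0:
            continue
        n = max(1, int(np.ceil(thick / step_mm)))
        dl = thick / n
        l_mid = z + (np.arange(n) + 0.5) * dl
        wet_mid = (l_mid - z) * mat.relative_stopping_power
        res_mid = residual - wet_mid
        e_mid = energy_from_range(np.maximum(res_mid, range_from_energy(3.0)))
        pv = proton_pv(e_mid)
        # Highland with per-slab logarithmic correction
        x_over_x0 = thick / mat.radiation_length_mm
        log_corr = (1.0 + 0.038 * np.log(max(x_over_x0, 1e-12))) ** 2
        log_corr = max(log_corr, 1e-4)
        t_power = (13.6 / pv) ** 2 / mat.radiation_length_mm * log_corr
        lever2 = (z_eval[:, None] - l_mid[None, :]) ** 2
        contrib = (t_power[None, :] * dl * lever2)
        # slabs downstream of the evaluation plane do not contribute
        contrib[z_eval[:, None] <= l_mid[None, :] - 0.5 * dl] = 0.0
        sig2 += contrib.sum(axis=1)
        residual -= thick * mat.relative_stopping_power
        z += thick
    return np.sqrt(sig2)


def lateral_sigma(depth_in_water_mm, upstream_wet_mm: float,
                  beamline: BeamLine, *, distance_from_source_mm=None,
                  air_gap_mm: float = 50.0) -> np.ndarray:
    """Total lateral sigma of a pencil beam at depth in the phantom.

    Combines in quadrature the source size, the free divergence growth over
    the source-to-point distance, and multiple Coulomb scattering in an
    upstream water-equivalent slab (placed ending ``air_gap_mm`` before the
    phantom surface) plus the water overburden.

    ``distance_from_source_mm`` overrides the drift used for the divergence
    term; default is source plane to the evaluation point.
    """
    depth = np.atleast_1d(np.asarray(depth_in_water_mm, dtype=float))
    if np.any(depth < 0) or upstream_wet_mm < 0:
        raise ValueError("depths must be >= 0")

    if distance_from_source_mm is None:
        dist = (0.0 - beamline.source_plane_z) + depth
    else:
        dist = np.broadcast_to(
            np.asarray(distance_from_source_mm, dtype=float), depth.shape)
    sig2 = (beamline.source_sigma_mm**2
            + (beamline.divergence_sigma_mrad * 1e-3 * dist) ** 2)

    sig_scat = np.zeros_like(depth)
    max_depth = float(depth.max()) if depth.size else 0.0
    stack: list[tuple[Material, float]] = []
    z0 = -(air_gap_mm + upstream_wet_mm)
    if upstream_wet_mm > 0:
        stack.append((WATER, upstream_wet_mm))
        stack.append((AIR, air_gap_mm))
    else:
        z0 = 0.0
    if max_depth > 0 or stack:
        stack.append((WATER, max(max_depth, 1e-6)))
        sig_scat = scatter_sigma(stack, depth, beamline.energy_mev,
                                 z_entry=z0)
    return np.sqrt(sig2 + sig_scat**2)
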