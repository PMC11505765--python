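"""Simplified pencil-beam dose engine for modulator + absorber setups.

For every scan spot, sub-rays are sampled on a deterministic stratified grid
over the spot's lateral fluence at the modulator plane.  Each sub-ray picks
up the upstream WET of its column (modulator heightfield x RSP plus the
absorber), and the spot fluence is histogrammed into WET bins on a fine
lateral grid.  The dose at depth z is then the superposition, over WET bins,
of the pulled-back Bragg curve weighted by that bin's fluence map, convolved
with the depth-dependent lateral scattering kernel and magnified about the
scanning magnets (the beam diverges from two deflection points, so lateral
positions scale with distance).  Everything is deterministic; dose is linear
in MU and reported in arbitrary units.

The modulator's WET is assigned at the modulator plane (thin-modulator
approximation) and in-pin scattering is neglected for dose: behind the thick
pre-absorber the beam width is dominated by absorber scattering.  In-pin
scattering *is* modelled for planar fluence scoring, where it is the whole
effect (the pin-grid pattern directly behind the modulator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .beam_model import (AIR, BeamLine, BraggCurve, Material, PMMA, WATER,
                         bragg_curve, scatter_sigma, spot_direction,
                         wet_of_slab)

log = logging.getLogger(__name__)

__all__ = [
    "Scene",
    "Sampling",
    "PROFILES",
    "DoseGrid",
    "FluenceMap",
    "compute_dose",
    "score_fluence",
    "sobp_profile",
    "fluence_cov",
]


@dataclass(frozen=True)
class Scene:
    """Beam-path geometry: modulator, pre-absorber, air gap, water phantom.

    ``phantom_surface_z`` places the water surface relative to the isocenter
    (0 for the modulator study, -90 for the base-line setup where the
    isocenter sits 9 cm inside the phantom).  The absorber exits
    ``air_gap_mm`` upstream of the surface; the modulator plane sits
    ``rm_gap_mm`` upstream of the absorber entrance.
    """

    absorber_thickness_mm: float = 170.0
    absorber_material: Material = PMMA
    air_gap_mm: float = 50.0
    rm_gap_mm: float = 5.0
    phantom_surface_z: float = 0.0

    @property
    def absorber_exit_z(self) -> float:
        return self.phantom_surface_z - self.air_gap_mm

    @property
    def absorber_entry_z(self) -> float:
        return self.absorber_exit_z - self.absorber_thickness_mm

    @property
    def modulator_plane_z(self) -> float:
        return self.absorber_entry_z - self.rm_gap_mm

    @property
    def absorber_wet_mm(self) -> float:
        return wet_of_slab(self.absorber_material, self.absorber_thickness_mm)


@dataclass(frozen=True)
class Sampling:
    """Discretization of the engine; the defaults are the desk profile."""

    samples_per_cell: int = 12  # WET rays per 3 mm pin period (squared)
    n_sigma: float = 3.5
    fluence_res_mm: float = 1.0
    wet_bin_mm: float = 1.0
    sigma_class_wet_mm: float = 12.0
    stepless_tier_mm: float = 0.5
    in_pin_scatter: bool = False
    depth_max_mm: float = 220.0
    depth_step_mm: float = 1.0
    lateral_half_mm: float = 66.25
    lateral_res_mm: float = 2.5


#: engine profiles: "desk" for routine runs, "full" for fine sub-sampling,
#: "pencil" for single-spot 2D RM studies
PROFILES = {
    "desk": Sampling(),
    "full": Sampling(samples_per_cell=24, fluence_res_mm=0.5,
                     wet_bin_mm=0.5, stepless_tier_mm=0.25),
    "pencil": Sampling(samples_per_cell=24, fluence_res_mm=0.5,
                       wet_bin_mm=0.5, lateral_half_mm=40.0),
}


@dataclass
class DoseGrid:
    """Relative dose on a Cartesian grid.

    ``values[ix, iy, iz]``; x/y are lateral voxel centers (mm, isocenter
    frame), z is depth relative to the water-phantom surface (not absolute
    position).
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    depth_mm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < -1e-9):
            raise ValueError("dose values must be >= 0")

    @property
    def spacing(self) -> tuple[float, float, float]:
        def step(a):
            return float(a[1] - a[0]) if a.size > 1 else 1.0
        return (step(self.x_mm), step(self.y_mm), step(self.depth_mm))

    def depth_slice(self, depth_mm: float) -> np.ndarray:
        """Transverse slice at the nearest scored depth."""
        if not (self.depth_mm[0] - 0.5 * self.spacing[2]
                <= depth_mm <= self.depth_mm[-1] + 0.5 * self.spacing[2]):
            raise ValueError(f"depth {depth_mm} mm outside scored range")
        iz = int(np.argmin(np.abs(self.depth_mm - depth_mm)))
        return self.values[:, :, iz]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("x_mm", data=self.x_mm)
            fh.create_dataset("y_mm", data=self.y_mm)
            fh.create_dataset("depth_mm", data=self.depth_mm)
            fh.create_dataset("values", data=self.values,
                              compression="gzip")
            fh.attrs["frame"] = "depth relative to phantom surface"

    @classmethod
    def from_hdf5(cls, path) -> "DoseGrid":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(fh["x_mm"][:], fh["y_mm"][:], fh["depth_mm"][:],
                       fh["values"][:])

    def slice_to_csv(self, depth_mm: float, path) -> None:
        sl = self.depth_slice(depth_mm)
        pd.DataFrame(sl, index=pd.Index(self.x_mm, name="x_mm"),
                     columns=pd.Index(self.y_mm, name="y_mm")).to_csv(path)


@dataclass
class FluenceMap:
    """Planar fluence (arbitrary units) on a lateral grid at ``plane_z``."""

    plane_z: float
    x_mm: np.ndarray
    y_mm: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.counts < -1e-12):
            raise ValueError("fluence counts must be >= 0")


def _magnification(z_abs, magnet_z: float, z_ref: float) -> np.ndarray:
    """Lateral scale factor at absolute z for rays fanning from a magnet."""
    return (z_abs - magnet_z) / (z_ref - magnet_z)


class _BinnedFluence:
    """Per-WET-bin fluence histograms at the modulator plane."""

    def __init__(self, xs, ys, wet_centers, columns_mm, hist, lost_fraction):
        self.xs = xs
        self.ys = ys
        self.wet_centers = wet_centers  # total upstream WET per bin
        self.columns_mm = columns_mm  # physical modulator column per bin
        self.hist = hist  # (n_bins, nx, ny)
        self.lost_fraction = lost_fraction


def _spot_sigma(scene: Scene, beamline: BeamLine) -> float:
    """Lateral sigma of one spot at the modulator plane (source + drift)."""
    z_mod = scene.modulator_plane_z
    return float(np.sqrt(beamline.source_sigma_mm**2
                         + (beamline.divergence_sigma_mrad * 1e-3
                            * (z_mod - beamline.source_plane_z)) ** 2))


def _spot_fluence_field(plan, scene: Scene, beamline: BeamLine,
                        sampling: Sampling):
    """Total spot fluence density (MU/mm^2) at the modulator plane.

    Spot centers (at the plane, after demagnification through the magnet
    geometry) are deposited with cloud-in-cell weights and blurred with the
    spot sigma.  Returns (xs, ys, density, sigma_spot).
    """
    z_mod = scene.modulator_plane_z
    sig = _spot_sigma(scene, beamline)
    res = sampling.fluence_res_mm

    pos = []
    for spot in plan.spots:
        if spot.mu == 0.0:
            continue
        cx, cy = spot_direction(spot, beamline).position_at(z_mod)
        pos.append((float(cx), float(cy), spot.mu))
    if not pos:
        raise ValueError("plan has no spots with MU > 0")
    pos = np.asarray(pos)

    pad = sampling.n_sigma * sig + 6.0
    half = max(np.abs(pos[:, :2]).max() + pad, sampling.lateral_half_mm + 5.0)
    xs = np.arange(-half, half + res, res)
    ys = xs.copy()
    dens = np.zeros((xs.size, ys.size))

    fx = (pos[:, 0] - xs[0]) / res
    fy = (pos[:, 1] - ys[0]) / res
    ix = np.floor(fx).astype(int)
    iy = np.floor(fy).astype(int)
    tx = fx - ix
    ty = fy - iy
    ok = (ix >= 0) & (ix < xs.size - 1) & (iy >= 0) & (iy < ys.size - 1)
    mu = pos[:, 2]
    for dx, wx_ in ((0, 1 - tx), (1, tx)):
        for dy, wy_ in ((0, 1 - ty), (1, ty)):
            np.add.at(dens, (ix[ok] + dx, iy[ok] + dy),
                      (mu * wx_ * wy_)[ok])
    dens /= res**2
    dens = ndimage.gaussian_filter(dens, sig / res, mode="constant",
                                   truncate=6.0)
    return xs, ys, dens, sig


def _beam_region(plan, scene: Scene, beamline: BeamLine,
                 sampling: Sampling):
    """Lab-frame lateral box covered by the beam at the modulator plane."""
    z_mod = scene.modulator_plane_z
    px, py = [], []
    for spot in plan.spots:
        cx, cy = spot_direction(spot, beamline).position_at(z_mod)
        px.append(float(cx))
        py.append(float(cy))
    pad = sampling.n_sigma * _spot_sigma(scene, beamline) + 3.0
    return (min(px) - pad, max(px) + pad, min(py) - pad, max(py) + pad)


def _bin_fluence(plan, scene: Scene, beamline: BeamLine, sampling: Sampling,
                 samples, rsp_mod: float) -> _BinnedFluence:
    """Histogram sample fluence into (WET bin, lateral pixel)."""
    fxs, fys, dens, _sig = _spot_fluence_field(plan, scene, beamline,
                                               sampling)
    res = sampling.fluence_res_mm
    abs_wet = scene.absorber_wet_mm

    if samples is None:
        hist = (dens * res**2)[None, :, :].copy()
        return _BinnedFluence(fxs, fys, np.array([abs_wet]),
                              np.array([0.0]), hist, 0.0)

    wet_mod = samples.column_mm * rsp_mod
    nb = int(np.floor(wet_mod.max() / sampling.wet_bin_mm)) + 1
    wet_centers = abs_wet + np.arange(nb) * sampling.wet_bin_mm
    columns = np.arange(nb) * sampling.wet_bin_mm / rsp_mod
    b = np.clip(np.round(wet_mod / sampling.wet_bin_mm).astype(int), 0,
                nb - 1)

    # fluence seen by each sample ray
    gx = (samples.x - fxs[0]) / res
    gy = (samples.y - fys[0]) / res
    phi = ndimage.map_coordinates(dens, [gx, gy], order=1, mode="constant")
    w = phi * samples.area_mm2

    ix = np.floor(gx + 0.5).astype(int)
    iy = np.floor(gy + 0.5).astype(int)
    ok = (ix >= 0) & (ix < fxs.size) & (iy >= 0) & (iy < fys.size)
    hist = np.zeros((nb, fxs.size, fys.size))
    np.add.at(hist, (b[ok], ix[ok], iy[ok]), w[ok])

    # fluence mass the sample table did not cover (beam outside the
    # modulator footprint) stays un-deposited; report it
    total = dens.sum() * res**2
    lost_fraction = max(0.0, 1.0 - hist.sum() / max(total, 1e-30))
    if lost_fraction > 1e-3:
        log.warning("%.2f%% of the beam fluence misses the modulator "
                    "sample table", 100 * lost_fraction)
    return _BinnedFluence(fxs, fys, wet_centers, columns, hist,
                          lost_fraction)


def _geometry_samples(plan, scene: Scene, beamline: BeamLine,
                      sampling: Sampling, modulator=None, transform=None,
                      heightfield=None):
    """WET samples of the modulator geometry covering the beam region.

    ``heightfield`` (xs, ys, column_mm) — e.g. from the mesh ray-casting
    path — turns every pixel into one sample; otherwise the analytic
    :func:`rm3d.mesh_geometry.wet_sample_table` is used.
    """
    if heightfield is not None:
        from .mesh_geometry import WetSampleTable

        xs, ys, h = heightfield
        res = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return WetSampleTable(gx.ravel(), gy.ravel(), h.ravel(),
                              np.full(h.size, res**2))
    if modulator is None:
        return None
    from .mesh_geometry import wet_sample_table

    region = _beam_region(plan, scene, beamline, sampling)
    return wet_sample_table(modulator, transform,
                            samples_per_cell=sampling.samples_per_cell,
                            region=region,
                            stepless_tier_mm=sampling.stepless_tier_mm,
                            in_pin_scatter=sampling.in_pin_scatter)


def _sigma_for_class(scene: Scene, beamline: BeamLine, wet_mod: float,
                     depths: np.ndarray, rsp_mod: float) -> np.ndarray:
    """Scattering sigma (mm, lab frame) vs scored depth for one WET class."""
    z_mod = scene.modulator_plane_z
    col_phys = wet_mod / max(rsp_mod, 1e-6)
    stack = []
    if col_phys > 0:
        stack.append((Material("modulator", 1.2, rsp_mod, 340.0), col_phys))
    stack.append((AIR, scene.rm_gap_mm))
    stack.append((scene.absorber_material, scene.absorber_thickness_mm))
    stack.append((AIR, scene.air_gap_mm))
    stack.append((WATER, float(depths.max()) + 1.0))
    z_eval = scene.phantom_surface_z + depths
    sig_scat = scatter_sigma(stack, z_eval, beamline.energy_mev,
                             z_entry=z_mod - col_phys)
    sig_div = beamline.divergence_sigma_mrad * 1e-3 * (z_eval - z_mod)
    return np.sqrt(sig_scat**2 + sig_div**2)


def compute_dose(plan, scene: Scene, beamline: BeamLine, *,
                 modulator=None, transform=None, heightfield=None,
                 curve: BraggCurve | None = None,
                 sampling: Sampling | None = None,
                 fluence_attenuation_per_cm: float = 0.0) -> DoseGrid:
    """Score 3D dose in the water phantom for a raster plan.

    ``modulator`` is an analytic modulator (optionally with a rigid
    ``transform``); alternatively pass a precomputed ``heightfield``
    (xs, ys, column_mm) from the mesh ray-casting path.  Dose is linear in
    MU and deterministic.
    """
    if not plan.spots:
        raise ValueError("plan has no spots")
    sampling = sampling or Sampling()
    curve = curve or bragg_curve(beamline.energy_mev)

    rsp_mod = (modulator.material.relative_stopping_power
               if modulator is not None else 1.16)
    samples = _geometry_samples(plan, scene, beamline, sampling, modulator,
                                transform, heightfield)
    binned = _bin_fluence(plan, scene, beamline, sampling, samples, rsp_mod)

    depths = np.arange(sampling.depth_step_mm / 2, sampling.depth_max_mm,
                       sampling.depth_step_mm)
    nxs = np.arange(-sampling.lateral_half_mm + sampling.lateral_res_mm / 2,
                    sampling.lateral_half_mm, sampling.lateral_res_mm)
    nys = nxs.copy()
    out = np.zeros((nxs.size, nys.size, depths.size))

    # depth-dose per WET bin
    dmat = np.stack([curve.at(depths + w) for w in binned.wet_centers])
    if fluence_attenuation_per_cm > 0:
        att = np.exp(-fluence_attenuation_per_cm
                     * (binned.wet_centers[:, None] + depths[None, :]) / 10.0)
        dmat = dmat * att

    z_mod = scene.modulator_plane_z
    z_abs = scene.phantom_surface_z + depths
    mx = _magnification(z_abs, beamline.x_magnet_z, z_mod)
    my = _magnification(z_abs, beamline.y_magnet_z, z_mod)

    abs_wet = scene.absorber_wet_mm
    cls_width = sampling.sigma_class_wet_mm
    mod_wet = binned.wet_centers - abs_wet
    cls_idx = np.floor(mod_wet / cls_width).astype(int)
    res = sampling.fluence_res_mm

    # sampling coordinates of the scoring grid on the fluence maps, per z
    fx0, fy0 = binned.xs[0], binned.ys[0]
    for ci in np.unique(cls_idx):
        sel = cls_idx == ci
        if not binned.hist[sel].any():
            continue
        tz = np.tensordot(dmat[sel].T, binned.hist[sel], axes=(1, 0))
        wet_c = float(mod_wet[sel].mean())
        sig = _sigma_for_class(scene, beamline, wet_c, depths, rsp_mod)
        for iz in range(depths.size):
            if not tz[iz].any():
                continue
            sig_pix_x = sig[iz] / mx[iz] / res
            sig_pix_y = sig[iz] / my[iz] / res
            sm = ndimage.gaussian_filter(tz[iz], (sig_pix_x, sig_pix_y),
                                         mode="constant")
            cx = (nxs / mx[iz] - fx0) / res
            cy = (nys / my[iz] - fy0) / res
            gx, gy = np.meshgrid(cx, cy, indexing="ij")
            vals = ndimage.map_coordinates(sm, [gx, gy], order=1,
                                           mode="constant")
            out[:, :, iz] += vals / (mx[iz] * my[iz])

    return DoseGrid(nxs, nys, depths, np.clip(out, 0.0, None))


def integrated_depth_dose(plan, scene: Scene, beamline: BeamLine, *,
                          modulator=None, transform=None, heightfield=None,
                          curve: BraggCurve | None = None,
                          sampling: Sampling | None = None):
    """Laterally integrated depth-dose curve (depths_mm, dose).

    Lateral transport integrates out of the depth profile, so this is the
    exact fluence-weighted superposition of pulled-back Bragg curves — the
    natural quantity for SOBP flatness and tilt-sensitivity comparisons of
    uniform (2D) modulators irradiated by a pencil beam.
    """
    sampling = sampling or Sampling()
    curve = curve or bragg_curve(beamline.energy_mev)
    rsp_mod = (modulator.material.relative_stopping_power
               if modulator is not None else 1.16)
    samples = _geometry_samples(plan, scene, beamline, sampling, modulator,
                                transform, heightfield)
    binned = _bin_fluence(plan, scene, beamline, sampling, samples, rsp_mod)
    depths = np.arange(sampling.depth_step_mm / 2, sampling.depth_max_mm,
                       sampling.depth_step_mm)
    dmat = np.stack([curve.at(depths + w) for w in binned.wet_centers])
    weights = binned.hist.sum(axis=(1, 2))
    return depths, weights @ dmat


def score_fluence(plan, scene: Scene, beamline: BeamLine, *,
                  plane: str | float = "absorber_entrance",
                  modulator=None, transform=None, heightfield=None,
                  sampling: Sampling | None = None) -> FluenceMap:
    """Planar fluence map with in-pin scattering blur.

    ``plane`` is "absorber_entrance", "phantom_surface", or an absolute z.
    Each WET class's fluence histogram is blurred with the lateral spread
    its rays have accumulated by the scoring plane: scattering inside the
    pin column itself plus (downstream planes) the absorber, which is what
    turns the sharp pin-grid pattern directly behind the modulator into a
    featureless fluence at the phantom surface.
    """
    sampling = sampling or Sampling()
    if plane == "absorber_entrance":
        plane_z = scene.absorber_entry_z
    elif plane == "phantom_surface":
        plane_z = scene.phantom_surface_z
    else:
        plane_z = float(plane)
    if not (scene.modulator_plane_z - 1e-6 <= plane_z
            <= scene.phantom_surface_z + 1e-6):
        raise ValueError("scoring plane must lie between the modulator "
                         "plane and the phantom surface")

    rsp_mod = (modulator.material.relative_stopping_power
               if modulator is not None else 1.16)
    samples = _geometry_samples(plan, scene, beamline, sampling, modulator,
                                transform, heightfield)
    binned = _bin_fluence(plan, scene, beamline, sampling, samples, rsp_mod)

    abs_wet = scene.absorber_wet_mm
    res = sampling.fluence_res_mm
    z_mod = scene.modulator_plane_z

    total = np.zeros(binned.hist.shape[1:])
    for b, wet_total in enumerate(binned.wet_centers):
        if not binned.hist[b].any():
            continue
        col_phys = binned.columns_mm[b]
        stack = [(Material("modulator", 1.2, rsp_mod, 340.0), col_phys)] \
            if col_phys > 0 else []
        stack.append((AIR, scene.rm_gap_mm))
        if plane_z > scene.absorber_entry_z + 1e-9:
            thick = min(plane_z - scene.absorber_entry_z,
                        scene.absorber_thickness_mm)
            stack.append((scene.absorber_material, thick))
        if plane_z > scene.absorber_exit_z + 1e-9:
            stack.append((AIR, plane_z - scene.absorber_exit_z))
        sig = float(scatter_sigma(stack, np.array([plane_z]),
                                  beamline.energy_mev,
                                  z_entry=z_mod - col_phys)[0])
        total += ndimage.gaussian_filter(binned.hist[b],
                                         max(sig, 1e-6) / res,
                                         mode="constant")
    return FluenceMap(plane_z, binned.xs, binned.ys, total)


def fluence_cov(fmap: FluenceMap, half_width_mm: float = 15.0) -> float:
    """Coefficient of variation of the fluence over a central square."""
    selx = np.abs(fmap.x_mm) <= half_width_mm
    sely = np.abs(fmap.y_mm) <= half_width_mm
    region = fmap.counts[np.ix_(selx, sely)]
    mean = region.mean()
    if mean <= 0:
        return 0.0
    return float(region.std() / mean)


def sobp_profile(dose: DoseGrid, point=(0.0, 0.0),
                 window_voxels: int = 1) -> np.ndarray:
    """Depth-dose profile through a lateral point with optional averaging.

    Returns the dose vs ``dose.depth_mm``; ``window_voxels`` is the side of
    the lateral averaging window (1 = single column).
    """
    ix = int(np.argmin(np.abs(dose.x_mm - point[0])))
    iy = int(np.argmin(np.abs(dose.y_mm - point[1])))
    h = window_voxels // 2
    sl = dose.values[max(0, ix - h):ix + h + 1,
                     max(0, iy - h):iy + h + 1, :]
    return sl.mean(axis=(0, 1))
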