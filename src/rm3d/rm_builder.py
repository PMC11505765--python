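"""Target-specific 3D range-modulator construction and raster plans.

The study target is a cube rotated 45 degrees about both lateral axes, one
corner toward the nozzle, inside a water phantom: in beam's eye view it
presents a wide range of SOBP depths and lengths with a maximum SOBP of
~8.5 cm, a deliberately misalignment-sensitive worst case.  Each 3 mm pin
cell whose center falls inside the target silhouette (plus a margin) gets an
SOBP weight solve for its own depth interval, a step or stepless contour, and
a compensator offset (extra uniform height) that parks its deepest Bragg peak
on the pin's own distal edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

from .beam_model import BraggCurve, Material, RIGUR, ScanSpot
from .sobp_design import (PinContour, WeightVector, optimize_sobp_weights,
                          sobp_base_pullback, step_to_stepless,
                          weights_to_step_contour)

__all__ = [
    "CubeTarget",
    "PlacedPin",
    "Modulator",
    "RasterPlan",
    "target_depth_interval",
    "build_cube_modulator",
    "uniform_modulator",
    "plan_from_layers",
    "uniform_field_plan",
]


@dataclass(frozen=True)
class CubeTarget:
    """Cube rotated about x then y, centered on the beam axis."""

    side_mm: float = 60.0
    rotation_x_deg: float = 45.0
    rotation_y_deg: float = 45.0
    center_depth_mm: float = 128.0

    def __post_init__(self) -> None:
        if self.side_mm <= 0:
            raise ValueError("cube side must be > 0")

    def rotation(self) -> np.ndarray:
        """Lab-from-cube rotation matrix (x rotation applied first)."""
        ax = np.deg2rad(self.rotation_x_deg)
        ay = np.deg2rad(self.rotation_y_deg)
        rx = np.array([[1, 0, 0],
                       [0, np.cos(ax), -np.sin(ax)],
                       [0, np.sin(ax), np.cos(ax)]])
        ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                       [0, 1, 0],
                       [-np.sin(ay), 0, np.cos(ay)]])
        return ry @ rx

    def depth_extent(self) -> tuple[float, float]:
        """Support of the cube along the depth axis."""
        d = np.abs(self.rotation().T @ np.array([0.0, 0.0, 1.0]))
        half = 0.5 * self.side_mm * d.sum()
        return self.center_depth_mm - half, self.center_depth_mm + half


def target_depth_interval(target: CubeTarget, lateral_point):
    """Entry/exit depths of the axial ray through ``lateral_point``.

    Analytic slab intersection in the cube's own frame; returns
    (proximal, distal) in phantom depth or None outside the silhouette.
    Vectorized: pass arrays (x, y) to get masked arrays.
    """
    x, y = lateral_point
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)

    r = target.rotation()
    # ray p(t) = (x, y, t); in cube frame u = R^T (p - c)
    c = np.array([0.0, 0.0, target.center_depth_mm])
    d = r.T @ np.array([0.0, 0.0, 1.0])
    p0 = np.stack([x, y, np.zeros_like(x)], axis=-1) - c
    u0 = p0 @ r  # == (R^T p0^T)^T
    half = 0.5 * target.side_mm

    t_lo = np.full(x.shape, -np.inf)
    t_hi = np.full(x.shape, np.inf)
    for i in range(3):
        if abs(d[i]) < 1e-12:
            outside = np.abs(u0[..., i]) > half
            t_lo = np.where(outside, np.inf, t_lo)
            continue
        ta = (-half - u0[..., i]) / d[i]
        tb = (half - u0[..., i]) / d[i]
        t_lo = np.maximum(t_lo, np.minimum(ta, tb))
        t_hi = np.minimum(t_hi, np.maximum(ta, tb))
    hit = t_lo < t_hi - 1e-9
    if scalar:
        if not hit[0]:
            return None
        return float(t_lo[0]), float(t_hi[0])
    return hit, t_lo, t_hi


@dataclass
class PlacedPin:
    """A pin contour plus its compensator offset (extra uniform height)."""

    contour: PinContour
    extra_height_mm: float = 0.0
    proximal_mm: float | None = None
    distal_mm: float | None = None
    #: unnormalized SOBP weight total = fluence through the cell per unit
    #: plateau dose; drives the spot-MU heuristic
    fluence_demand: float = 1.0


@dataclass
class Modulator:
    """Lateral grid of pins on a base layer with protection side walls.

    ``pins`` maps integer cell indices to :class:`PlacedPin`; the cell (i, j)
    spans ``origin + [i*a, (i+1)*a] x [j*a, (j+1)*a]``.  ``column_height``
    returns the full physical material column (base + pin + compensator, or
    wall) along +z per lateral position, with the solid's own frame having
    the base bottom at z = 0.  The modulator's own isocenter is the footprint
    center at the pin-base plane.
    """

    period_mm: float
    base_layer_mm: float
    material: Material
    pins: dict[tuple[int, int], PlacedPin]
    origin_xy: tuple[float, float] = (0.0, 0.0)
    wall_thickness_mm: float = 2.0
    wall_height_override_mm: float | None = None

    def __post_init__(self) -> None:
        if self.base_layer_mm < 0:
            raise ValueError("base layer must be >= 0")
        if not self.pins:
            raise ValueError("modulator needs at least one pin cell")

    @property
    def wall_height_mm(self) -> float:
        if self.wall_height_override_mm is not None:
            return self.wall_height_override_mm
        return max(p.contour.max_height + p.extra_height_mm
                   for p in self.pins.values())

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        a = self.period_mm
        return (self.origin_xy[0] + (i + 0.5) * a,
                self.origin_xy[1] + (j + 0.5) * a)

    def footprint_bounds(self):
        idx = np.array(list(self.pins.keys()))
        a = self.period_mm
        lo = (self.origin_xy[0] + idx[:, 0].min() * a,
              self.origin_xy[1] + idx[:, 1].min() * a)
        hi = (self.origin_xy[0] + (idx[:, 0].max() + 1) * a,
              self.origin_xy[1] + (idx[:, 1].max() + 1) * a)
        return lo, hi

    @property
    def max_column_mm(self) -> float:
        return self.base_layer_mm + max(
            self.wall_height_mm,
            max(p.contour.max_height + p.extra_height_mm
                for p in self.pins.values()))

    def column_height(self, x, y) -> np.ndarray:
        """Physical material column along +z at lateral position(s)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.zeros(x.shape)
        a = self.period_mm
        (x0, y0), (x1, y1) = self.footprint_bounds()

        inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        wt = self.wall_thickness_mm
        in_wall = (~inside & (x >= x0 - wt) & (x < x1 + wt)
                   & (y >= y0 - wt) & (y < y1 + wt))
        out[in_wall] = self.base_layer_mm + self.wall_height_mm

        if inside.any():
            xi = x[inside]
            yi = y[inside]
            ci = np.floor((xi - self.origin_xy[0]) / a).astype(int)
            cj = np.floor((yi - self.origin_xy[1]) / a).astype(int)
            h = np.full(xi.shape, self.base_layer_mm)
            key = np.stack([ci, cj], axis=1)
            # group sample points by cell
            uniq, inv = np.unique(key, axis=0, return_inverse=True)
            for k, (ii, jj) in enumerate(map(tuple, uniq)):
                placed = self.pins.get((int(ii), int(jj)))
                if placed is None:
                    continue
                sel = inv == k
                cx, cy = self.cell_center(int(ii), int(jj))
                u = np.abs(xi[sel] - cx)
                v = np.abs(yi[sel] - cy)
                cum = np.clip((2.0 * np.maximum(u, v) / a) ** 2, 0.0, 1.0)
                h[sel] += (placed.contour.height_at_cum_area(cum)
                           + placed.extra_height_mm)
            out[inside] = h
        return out

    def wet_at(self, x, y) -> np.ndarray:
        """Water-equivalent thickness of the column at lateral position(s)."""
        return self.column_height(x, y) * self.material.relative_stopping_power


def uniform_modulator(contour: PinContour, n_cells: int = 13,
                      base_layer_mm: float = 8.0,
                      wall_thickness_mm: float = 2.0) -> Modulator:
    """A 2D RM: the same pin tiled over an n x n footprint centered on axis."""
    pins = {(i, j): PlacedPin(contour)
            for i in range(n_cells) for j in range(n_cells)}
    a = contour.base_period_mm
    org = -0.5 * n_cells * a
    return Modulator(a, base_layer_mm, contour.material, pins,
                     origin_xy=(org, org), wall_thickness_mm=wall_thickness_mm)


def build_cube_modulator(target: CubeTarget, curve: BraggCurve, *,
                         absorber_wet_mm: float,
                         period_mm: float = 3.0,
                         base_layer_mm: float = 8.0,
                         wet_step_mm: float = 3.0,
                         margin_cells: int = 1,
                         kind: str = "step",
                         material: Material = RIGUR,
                         length_quantum_mm: float = 0.5) -> Modulator:
    """Build the target-conformal 3D RM for the rotated-cube target.

    For every pin cell whose center lies in the target silhouette (dilated by
    ``margin_cells``), solves the per-pin SOBP weights over the pin's own
    depth interval and adds a compensator offset so its deepest Bragg peak
    lands on the pin's distal edge.  Weight solves are cached per quantized
    SOBP length (the pristine curve is shift-invariant, so the solution
    depends on the interval length only).
    """
    rsp = material.relative_stopping_power
    a = period_mm
    # lateral extent of the silhouette: cube support along x/y
    r = target.rotation()
    half_x = 0.5 * target.side_mm * np.abs(r[0]).sum()
    half_y = 0.5 * target.side_mm * np.abs(r[1]).sum()
    ni = int(np.ceil(2 * (half_x + a) / a))
    nj = int(np.ceil(2 * (half_y + a) / a))
    org_x, org_y = -0.5 * ni * a, -0.5 * nj * a

    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    cx = org_x + (ii + 0.5) * a
    cy = org_y + (jj + 0.5) * a
    hit, t_lo, t_hi = target_depth_interval(target, (cx.ravel(), cy.ravel()))
    hit = hit.reshape(ii.shape)
    t_lo = t_lo.reshape(ii.shape)
    t_hi = t_hi.reshape(ii.shape)

    from scipy import ndimage
    dilated = ndimage.binary_dilation(hit, iterations=margin_cells)
    # margin pins inherit the nearest in-silhouette interval
    _, (si, sj) = ndimage.distance_transform_edt(
        ~hit, return_indices=True)
    prox = t_lo[si, sj]
    dist = t_hi[si, sj]

    solve_cache: dict[float, WeightVector] = {}

    def weights_for(length: float) -> WeightVector:
        key = max(1, int(round(length / length_quantum_mm)))
        if key not in solve_cache:
            # solve in a shift-invariant frame anchored at the curve range
            distal = curve.range_80 - absorber_wet_mm
            solve_cache[key] = optimize_sobp_weights(
                curve, distal - key * length_quantum_mm, distal, wet_step_mm)
        return solve_cache[key]

    pins: dict[tuple[int, int], PlacedPin] = {}
    for i in range(ni):
        for j in range(nj):
            if not dilated[i, j]:
                continue
            p, d = float(prox[i, j]), float(dist[i, j])
            w = weights_for(d - p)
            if kind == "step":
                contour = weights_to_step_contour(w, a, material)
            else:
                contour = step_to_stepless(w, base_period_mm=a,
                                           material=material)
            # deepest layer (pin height 0) must be pulled back by the SOBP
            # base pullback; absorber and base layer provide part of it
            need_wet = (sobp_base_pullback(curve, d)
                        - absorber_wet_mm - base_layer_mm * rsp)
            if need_wet < -1e-6:
                raise ValueError(
                    f"pin ({i},{j}): distal depth {d:.1f} mm not reachable "
                    f"(needs negative compensator WET {need_wet:.2f} mm)")
            pins[(i, j)] = PlacedPin(contour, extra_height_mm=need_wet / rsp,
                                     proximal_mm=p, distal_mm=d,
                                     fluence_demand=w.raw_sum)
    return Modulator(a, base_layer_mm, material, pins,
                     origin_xy=(org_x, org_y))


@dataclass
class RasterPlan:
    """Single-energy raster-scan plan: regular spot grid with MU weights."""

    spots: list[ScanSpot]
    field_mm: tuple[float, float] = (80.0, 80.0)
    spacing_mm: float = 5.0
    energy_mev: float = 250.0

    def __post_init__(self) -> None:
        if any(s.mu < 0 for s in self.spots):
            raise ValueError("all MU must be >= 0")

    @property
    def total_mu(self) -> float:
        return sum(s.mu for s in self.spots)

    def shifted(self, dx: float = 0.0, dy: float = 0.0) -> "RasterPlan":
        return RasterPlan([ScanSpot(s.x + dx, s.y + dy, s.mu)
                           for s in self.spots],
                          self.field_mm, self.spacing_mm, self.energy_mev)

    def scaled(self, factor: float) -> "RasterPlan":
        return RasterPlan([ScanSpot(s.x, s.y, s.mu * factor)
                           for s in self.spots],
                          self.field_mm, self.spacing_mm, self.energy_mev)

    def to_csv(self, path) -> None:
        pd.DataFrame({"x_mm": [s.x for s in self.spots],
                      "y_mm": [s.y for s in self.spots],
                      "mu": [s.mu for s in self.spots]}).to_csv(path,
                                                               index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RasterPlan":
        df = pd.read_csv(path)
        spots = [ScanSpot(r.x_mm, r.y_mm, r.mu) for r in df.itertuples()]
        return cls(spots, **kwargs)

    def to_json(self, path) -> None:
        doc = {"energy_mev": self.energy_mev,
               "field_mm": list(self.field_mm),
               "spacing_mm": self.spacing_mm,
               "spots": [[s.x, s.y, s.mu] for s in self.spots]}
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "RasterPlan":
        with open(path) as fh:
            doc = json.load(fh)
        return cls([ScanSpot(*s) for s in doc["spots"]],
                   tuple(doc["field_mm"]), doc["spacing_mm"],
                   doc["energy_mev"])


def uniform_field_plan(field_mm=(80.0, 80.0), spacing_mm: float = 5.0,
                       mu: float = 1.0, energy_mev: float = 250.0
                       ) -> RasterPlan:
    """Regular grid of equal-MU spots in serpentine scan order."""
    fx, fy = field_mm
    nx = int(round(fx / spacing_mm)) + 1
    ny = int(round(fy / spacing_mm)) + 1
    if not (np.isclose((nx - 1) * spacing_mm, fx)
            and np.isclose((ny - 1) * spacing_mm, fy)):
        raise ValueError("spacing must divide the field size")
    xs = (np.arange(nx) - (nx - 1) / 2) * spacing_mm
    ys = (np.arange(ny) - (ny - 1) / 2) * spacing_mm
    spots = []
    for j, y in enumerate(ys):
        row = xs if j % 2 == 0 else xs[::-1]
        spots.extend(ScanSpot(float(x), float(y), mu) for x in row)
    return RasterPlan(spots, (fx, fy), spacing_mm, energy_mev)


def plan_from_layers(layer_plans) -> RasterPlan:
    """Collapse range-shifter layer plans into one single-energy plan.

    ``layer_plans`` is a list of (wet_mm, RasterPlan); the output per-spot MU
    is the sum over layers at each spot position.  All layers must share the
    spot grid (same positions in any order).
    """
    if not layer_plans:
        raise ValueError("need at least one layer")
    _, first = layer_plans[0]
    key0 = sorted((round(s.x, 6), round(s.y, 6)) for s in first.spots)
    acc: dict[tuple[float, float], float] = {k: 0.0 for k in key0}
    for _, plan in layer_plans:
        keys = sorted((round(s.x, 6), round(s.y, 6)) for s in plan.spots)
        if keys != key0:
            raise ValueError("layer plans do not share the spot grid")
        for s in plan.spots:
            acc[(round(s.x, 6), round(s.y, 6))] += s.mu
    spots = [ScanSpot(s.x, s.y, acc[(round(s.x, 6), round(s.y, 6))])
             for s in first.spots]
    return RasterPlan(spots, first.field_mm, first.spacing_mm,
                      first.energy_mev)


def cube_plan(modulator: Modulator, field_mm=(80.0, 80.0),
              spacing_mm: float = 5.0, energy_mev: float = 250.0,
              margin_mm: float | None = None) -> RasterPlan:
    """Raster plan for a cube modulator.

    Per-spot MU follows the per-pin fluence demand (the unnormalized SOBP
    weight total encoded in each pin's stack, proxied by its modulation
    depth), flat laterally inside the pin footprint plus one spacing of
    margin, zero outside.  This documented heuristic stands in for the
    treatment planning system's proprietary spot-MU optimization; none of
    the robustness comparisons depend on the exact MU pattern.
    """
    margin = spacing_mm if margin_mm is None else margin_mm
    base = uniform_field_plan(field_mm, spacing_mm, 1.0, energy_mev)
    (x0, y0), (x1, y1) = modulator.footprint_bounds()
    spots = []
    for s in base.spots:
        inside = (x0 - margin <= s.x <= x1 + margin
                  and y0 - margin <= s.y <= y1 + margin)
        mu = 0.0
        if inside:
            ci = int(np.floor((s.x - modulator.origin_xy[0])
                              / modulator.period_mm))
            cj = int(np.floor((s.y - modulator.origin_xy[1])
                              / modulator.period_mm))
            best = None
            for (i, j), p in modulator.pins.items():
                d2 = (i - ci) ** 2 + (j - cj) ** 2
                if best is None or d2 < best[0]:
                    best = (d2, p)
            mu = best[1].fluence_demand
        spots.append(ScanSpot(s.x, s.y, mu))
    return RasterPlan(spots, field_mm, spacing_mm, energy_mev)
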