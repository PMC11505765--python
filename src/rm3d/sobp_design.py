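"""SOBP weight optimization and pin-contour construction.

A spread-out Bragg peak (SOBP) is a flat dose plateau built by superposing a
pristine Bragg curve pulled back by multiples of a WET step; the layer weights
are solved as a non-negative least-squares problem.  A modulator pin encodes
those weights geometrically: each step of the pin occupies a partial area of
the 3 mm pin cell directly proportional to the weight of its Bragg peak, and
the step height converts the layer's WET pullback to physical material via the
pin material's relative stopping power.  Interpolating the cumulative
area-vs-WET staircase and inverting it yields the quasi-continuous "stepless"
contour that preserves the same modulation function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import nnls

from .beam_model import BraggCurve, Material, MATERIALS

__all__ = [
    "WeightVector",
    "PinContour",
    "optimize_sobp_weights",
    "weights_to_step_contour",
    "step_to_stepless",
    "contour_wet_distribution",
]


@dataclass
class WeightVector:
    """Relative fluence per WET-pullback layer of an SOBP.

    ``pullbacks_mm`` are water-equivalent pullbacks relative to the deepest
    layer (monotone increasing, uniform step); ``weights`` are the relative
    fluence fractions.  ``raw_sum`` keeps the unnormalized NNLS weight total,
    i.e. the fluence needed through one pin cell to reach unit plateau dose.
    """

    pullbacks_mm: np.ndarray
    weights: np.ndarray
    raw_sum: float = 1.0

    def __post_init__(self) -> None:
        self.pullbacks_mm = np.asarray(self.pullbacks_mm, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.pullbacks_mm.shape != self.weights.shape:
            raise ValueError("pullbacks and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        if self.pullbacks_mm.size > 1:
            steps = np.diff(self.pullbacks_mm)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("pullbacks must increase with a uniform step")
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("at least one weight must be positive")
        self.weights = self.weights / s

    @property
    def wet_step(self) -> float:
        if self.pullbacks_mm.size < 2:
            return 0.0
        return float(self.pullbacks_mm[1] - self.pullbacks_mm[0])


@dataclass
class PinContour:
    """One modulator pin as a weight-encoding area/height profile.

    ``kind`` is "step" (discrete levels of (physical height, area fraction))
    or "stepless" (a fine monotone height-vs-cumulative-area profile).  The
    cumulative-area coordinate runs from the pin tip (cell center, tallest
    column) outward, so heights are non-increasing along it.
    """

    base_period_mm: float
    kind: str
    material: Material
    wet_step_mm: float
    # step: parallel arrays, heights descending (tip first)
    levels_height_mm: np.ndarray | None = None
    levels_area_fraction: np.ndarray | None = None
    # stepless: height sampled on a cumulative-area grid in [0, 1]
    profile_cum_area: np.ndarray | None = None
    profile_height_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("step", "stepless"):
            raise ValueError(f"unknown pin kind {self.kind!r}")
        if self.kind == "step":
            self.levels_height_mm = np.asarray(self.levels_height_mm, float)
            self.levels_area_fraction = np.asarray(self.levels_area_fraction, float)
            if np.any(self.levels_height_mm < 0):
                raise ValueError("pin heights must be >= 0")
            if not np.isclose(self.levels_area_fraction.sum(), 1.0):
                raise ValueError("area fractions must sum to 1")
        else:
            self.profile_cum_area = np.asarray(self.profile_cum_area, float)
            self.profile_height_mm = np.asarray(self.profile_height_mm, float)
            if np.any(np.diff(self.profile_height_mm) > 1e-9):
                raise ValueError("stepless profile must be monotone "
                                 "non-increasing from the tip outward")

    @property
    def max_height(self) -> float:
        if self.kind == "step":
            return float(self.levels_height_mm.max())
        return float(self.profile_height_mm.max())

    def height_at_cum_area(self, c) -> np.ndarray:
        """Column height at cumulative area fraction c measured from the tip.

        For a step pin this is the staircase over the concentric-ring layout;
        for a stepless pin the fine profile is interpolated linearly.
        """
        c = np.clip(np.asarray(c, dtype=float), 0.0, 1.0)
        if self.kind == "step":
            edges = np.cumsum(self.levels_area_fraction)
            idx = np.minimum(np.searchsorted(edges - 1e-12, c),
                             len(edges) - 1)
            return self.levels_height_mm[idx]
        return np.interp(c, self.profile_cum_area, self.profile_height_mm)

    def to_json(self) -> str:
        doc = {
            "base_period_mm": self.base_period_mm,
            "kind": self.kind,
            "material": self.material.name,
            "wet_step_mm": self.wet_step_mm,
        }
        if self.kind == "step":
            doc["levels"] = [
                {"height_mm": float(h), "area_fraction": float(a)}
                for h, a in zip(self.levels_height_mm, self.levels_area_fraction)
            ]
        else:
            doc["profile"] = {
                "cum_area": self.profile_cum_area.tolist(),
                "height_mm": self.profile_height_mm.tolist(),
            }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PinContour":
        doc = json.loads(text)
        mat = MATERIALS[doc["material"]]
        if doc["kind"] == "step":
            h = np.array([lv["height_mm"] for lv in doc["levels"]])
            a = np.array([lv["area_fraction"] for lv in doc["levels"]])
            return cls(doc["base_period_mm"], "step", mat, doc["wet_step_mm"],
                       levels_height_mm=h, levels_area_fraction=a)
        return cls(doc["base_period_mm"], "stepless", mat, doc["wet_step_mm"],
                   profile_cum_area=np.array(doc["profile"]["cum_area"]),
                   profile_height_mm=np.array(doc["profile"]["height_mm"]))


#: Extra pullback margin of the deepest layer beyond the distal edge so the
#: composed SOBP's distal 80% falloff lands on the requested distal depth,
#: and the distance before the distal edge where the unit-plateau fit stops
#: (the straggled peak needs ~2.5 mm to roll off the plateau).
DISTAL_OVERSHOOT_MM = 0.5
DISTAL_FIT_MARGIN_MM = 2.5


def sobp_base_pullback(curve: BraggCurve, distal_mm: float) -> float:
    """WET pullback of the deepest layer for a given distal edge depth."""
    return curve.range_80 - distal_mm - DISTAL_OVERSHOOT_MM


def optimize_sobp_weights(curve: BraggCurve, proximal_mm: float,
                          distal_mm: float, wet_step_mm: float = 3.0, *,
                          plateau_sample_mm: float = 0.5,
                          smoothing: float = 0.03) -> WeightVector:
    """Solve layer weights for a flat SOBP on [proximal, distal].

    Layers are pullbacks of ``curve`` at multiples of ``wet_step_mm`` from
    :func:`sobp_base_pullback`, placed so the composed SOBP's distal 80%
    falloff sits at ``distal_mm``.  Weights are the non-negative
    least-squares solution against a unit plateau sampled every
    ``plateau_sample_mm`` on [proximal, distal - fit margin]; the returned
    vector is normalized, with the raw NNLS sum kept as the per-cell fluence
    demand.  The plateau interior (edges excluded by one WET step) comes out
    flat to better than 1%.

    ``smoothing`` adds a small second-difference penalty.  The plain NNLS
    solution is sparse (the straggled peak is wider than the 3 mm layer
    step, so the system is overcomplete and the NNLS vertex zeroes whole
    layers); zero-weight layers translate into double-height pin risers,
    which are both unprintable and needlessly tilt-sensitive.  The default
    is the smallest value that removes the zeros while keeping the plateau
    flat within the 1% contract.
    """
    if not (0 < proximal_mm < distal_mm <= curve.range_80 + 1e-9):
        raise ValueError(
            f"infeasible SOBP interval [{proximal_mm}, {distal_mm}] for a "
            f"curve with range_80 {curve.range_80:.1f} mm")
    if wet_step_mm <= 0:
        raise ValueError("wet_step must be > 0")

    length = distal_mm - proximal_mm
    if length < wet_step_mm:
        return WeightVector(np.array([0.0]), np.array([1.0]), raw_sum=1.0)
    n_layers = int(np.ceil(length / wet_step_mm - 1e-9)) + 1
    pullbacks = np.arange(n_layers) * wet_step_mm
    base_pullback = sobp_base_pullback(curve, distal_mm)

    z = np.arange(proximal_mm, distal_mm - DISTAL_FIT_MARGIN_MM + 1e-9,
                  plateau_sample_mm)
    a_mat = np.empty((z.size, n_layers))
    for j, pb in enumerate(pullbacks):
        a_mat[:, j] = curve.at(z + base_pullback + pb)
    target = np.ones(z.size)
    if smoothing > 0 and n_layers > 2:
        d2 = np.zeros((n_layers - 2, n_layers))
        for i in range(n_layers - 2):
            d2[i, i:i + 3] = (1.0, -2.0, 1.0)
        a_mat = np.vstack([a_mat, smoothing * d2])
        target = np.concatenate([target, np.zeros(n_layers - 2)])
    w, _ = nnls(a_mat, target)
    raw = float(w.sum())
    if raw <= 0:
        raise ValueError("NNLS returned an all-zero weight vector")
    return WeightVector(pullbacks, w, raw_sum=raw)


def weights_to_step_contour(w: WeightVector, base_period_mm: float,
                            material: Material) -> PinContour:
    """Convert layer weights to a step pin.

    Step k removes ``pullback_k`` of WET relative to the deepest layer, hence
    has physical height pullback_k / RSP, and occupies an area fraction equal
    to weight_k.  Zero-weight layers are dropped.  Levels are returned tallest
    first (pin tip at the cell center in the concentric-ring layout).
    """
    keep = w.weights > 0
    heights = w.pullbacks_mm[keep] / material.relative_stopping_power
    areas = w.weights[keep] / w.weights[keep].sum()
    order = np.argsort(heights)[::-1]
    return PinContour(base_period_mm, "step", material,
                      w.wet_step or base_period_mm,
                      levels_height_mm=heights[order],
                      levels_area_fraction=areas[order])


def _cumulative_wet_knots(w: WeightVector):
    """Bin edges in WET and the cumulative area at each edge.

    Layer k holds mass w_k in the WET bin pullback_k +/- step/2; the
    cumulative area through each bin edge is exact by construction, so any
    monotone interpolation through these knots preserves the per-bin masses
    under re-binning at the original step.
    """
    step = w.wet_step
    # Half the deepest layer stays a flat valley floor (printed stepless
    # modulators keep a plateau between the pins); the rest of the cumulative
    # staircase is interpolated through its exact bin-edge knots, so
    # re-binning at the design step recovers every weight exactly.
    floor = 0.5 * w.weights[0]
    edges = np.concatenate([[w.pullbacks_mm[0]],
                            w.pullbacks_mm[:-1] + 0.5 * step,
                            [w.pullbacks_mm[-1]]])
    cum = np.concatenate([[floor], np.cumsum(w.weights)])
    cum[-1] = 1.0
    return edges, cum, floor


def step_to_stepless(w: WeightVector, grid_resolution_mm: float = 0.05,
                     base_period_mm: float = 3.0,
                     material: Material | None = None,
                     n_samples: int = 4096) -> PinContour:
    """Interpolate the discrete weights into a quasi-continuous pin contour.

    The cumulative area-vs-WET staircase is interpolated with a monotone
    (PCHIP) spline through the exact bin-edge knots and inverted, so the WET
    distribution of the resulting contour re-bins to the original weights.
    Sampled heights are quantized to ``grid_resolution_mm`` of WET; at the
    degenerate resolution equal to the WET step this recovers the step
    contour's height set.
    """
    if material is None:
        from .beam_model import RIGUR
        material = RIGUR
    if w.pullbacks_mm.size == 1:
        return PinContour(base_period_mm, "stepless", material,
                          w.wet_step or base_period_mm,
                          profile_cum_area=np.array([0.0, 1.0]),
                          profile_height_mm=np.array([0.0, 0.0]))
    if grid_resolution_mm > w.wet_step + 1e-12:
        raise ValueError("grid_resolution must not exceed the WET step")

    edges, cum, floor = _cumulative_wet_knots(w)
    # strictly increasing cum needed for inversion: zero-weight layers give
    # flat spans, separated by a negligible epsilon so the inverse stays a
    # function (the near-vertical jump keeps their mass at ~1e-4 per bin)
    cum = cum + np.arange(cum.size) * 1e-9
    cum /= cum[-1]
    spline = PchipInterpolator(cum, edges)

    c = np.linspace(0.0, 1.0, n_samples)
    wet = np.clip(spline(np.clip(c, cum[0], 1.0)), edges[0], edges[-1])
    wet[c <= floor] = edges[0]
    wet = np.round(wet / grid_resolution_mm) * grid_resolution_mm
    # tip (largest WET removed) at cumulative area 0
    heights = wet[::-1] / material.relative_stopping_power
    heights = np.minimum.accumulate(heights)  # enforce monotone (rounding)
    return PinContour(base_period_mm, "stepless", material, w.wet_step,
                      profile_cum_area=c,
                      profile_height_mm=heights)


def contour_wet_distribution(pin: PinContour,
                             wet_step_mm: float | None = None) -> WeightVector:
    """Area-weighted histogram of the WET a pin removes, at the design step.

    Inverse of the two contour constructors: a step pin round-trips exactly,
    a stepless pin reproduces the source weights to ~1e-3 per bin.
    """
    step = wet_step_mm or pin.wet_step_mm
    rsp = pin.material.relative_stopping_power
    if pin.kind == "step":
        wets = pin.levels_height_mm * rsp
        areas = pin.levels_area_fraction
    else:
        c = pin.profile_cum_area
        # mass between successive profile samples, WET at interval midpoints
        mid_h = 0.5 * (pin.profile_height_mm[1:] + pin.profile_height_mm[:-1])
        wets = mid_h * rsp
        areas = np.diff(c)
    n_bins = int(np.round(wets.max() / step)) + 1 if step > 0 else 1
    pullbacks = np.arange(max(n_bins, 1)) * (step if step > 0 else 1.0)
    idx = np.clip(np.round(wets / step).astype(int) if step > 0 else 0,
                  0, len(pullbacks) - 1)
    weights = np.bincount(np.atleast_1d(idx), weights=areas,
                          minlength=len(pullbacks))
    return WeightVector(pullbacks, weights)
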