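"""Local gamma-index dose comparison and SOBP profile metrics.

The gamma index combines a dose-difference criterion (percent of the local
reference dose) and a distance-to-agreement (DTA) criterion: for each
reference voxel r,

    gamma(r) = min over evaluated positions e of
               sqrt( (|e - r| / dta)^2 + ((D_eval(e) - D_ref(r)) /
                                          (dd * D_ref(r)))^2 )

with only reference voxels above a low-dose threshold evaluated.  A voxel
passes when gamma <= 1; the passing rate is the headline QA number.  The
evaluated distribution is interpolated on a sub-voxel search grid so the
DTA term is resolved well below the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose_engine import DoseGrid

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "gamma_index",
    "gamma_slices",
    "gamma_nd",
    "sobp_metrics",
]


@dataclass(frozen=True)
class GammaCriteria:
    """2%/2 mm local criteria with a 20% low-dose threshold by default."""

    dose_criterion: float = 0.02
    dta_mm: float = 2.0
    normalization: str = "local"
    low_dose_threshold: float = 0.20
    #: search-grid step as a fraction of dta; search radius = 3 x dta
    search_step_fraction: float = 0.1
    search_radius_factor: float = 3.0

    def __post_init__(self) -> None:
        if not (self.dose_criterion > 0 and self.dta_mm > 0):
            raise ValueError("criteria must be positive")
        if not (0 <= self.low_dose_threshold < 1):
            raise ValueError("low-dose threshold must be in [0, 1)")
        if self.normalization not in ("local", "global"):
            raise ValueError("normalization must be 'local' or 'global'")


@dataclass
class GammaResult:
    gamma_map: np.ndarray  # NaN where not evaluated
    passing_rate: float  # percent
    n_evaluated: int

    @property
    def passing_rate_rounded(self) -> int:
        """Integer percent, the report-table convention."""
        return int(round(self.passing_rate))


def gamma_nd(reference: np.ndarray, evaluated: np.ndarray, spacing,
             criteria: GammaCriteria = GammaCriteria()) -> GammaResult:
    """Gamma index between two dose arrays on a shared grid (1D/2D/3D).

    ``spacing`` is the voxel size per axis in mm.  The evaluated array is
    sampled with linear interpolation at offsets on a grid of
    ``search_step_fraction * dta`` out to ``search_radius_factor * dta``.
    """
    ref = np.asarray(reference, dtype=float)
    ev = np.asarray(evaluated, dtype=float)
    if ref.shape != ev.shape:
        raise ValueError("reference and evaluated grids differ in shape")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (ref.ndim,))

    if ref.max() <= 0:
        raise ValueError("reference distribution carries no dose")
    thr = criteria.low_dose_threshold * ref.max()
    mask = ref >= thr
    if criteria.low_dose_threshold > 0:
        mask &= ref > 0
    if not mask.any():
        raise ValueError("no reference voxels above the low-dose threshold")
    norm_ref = ref[mask] if criteria.normalization == "local" \
        else np.full(int(mask.sum()), ref.max())

    # offsets sorted by radius allow early termination
    step = criteria.search_step_fraction * criteria.dta_mm
    radius = criteria.search_radius_factor * criteria.dta_mm
    axes_off = [np.arange(-radius, radius + step / 2, step)
                for _ in range(ref.ndim)]
    mesh = np.meshgrid(*axes_off, indexing="ij")
    offsets = np.stack([m.ravel() for m in mesh], axis=1)
    r2 = (offsets**2).sum(axis=1)
    keep = r2 <= radius**2 + 1e-9
    offsets, r2 = offsets[keep], r2[keep]
    order = np.argsort(r2)
    offsets, r2 = offsets[order], r2[order]

    idx = np.argwhere(mask).T.astype(float)  # (ndim, nmask)
    ref_vals = ref[mask]
    denom = criteria.dose_criterion * norm_ref
    dta2 = criteria.dta_mm**2

    best = np.full(ref_vals.shape, np.inf)
    for off, rr in zip(offsets, r2):
        spatial = rr / dta2
        if spatial >= best.max():
            break
        coords = idx + (off / spacing)[:, None]
        ev_vals = ndimage.map_coordinates(ev, coords, order=1,
                                          mode="nearest")
        g2 = spatial + ((ev_vals - ref_vals) / denom) ** 2
        np.minimum(best, g2, out=best)

    gamma = np.sqrt(best)
    gmap = np.full(ref.shape, np.nan)
    gmap[mask] = gamma
    passing = 100.0 * float(np.mean(gamma <= 1.0 + 1e-9))
    return GammaResult(gmap, passing, int(mask.sum()))


def gamma_index(reference: DoseGrid, evaluated: DoseGrid,
                criteria: GammaCriteria = GammaCriteria()) -> GammaResult:
    """3D gamma between two dose grids sharing a frame."""
    _check_frames(reference, evaluated)
    return gamma_nd(reference.values, evaluated.values, reference.spacing,
                    criteria)


def gamma_slices(reference: DoseGrid, evaluated: DoseGrid,
                 depths_mm=(110.0, 160.0),
                 criteria: GammaCriteria = GammaCriteria()
                 ) -> dict[float, GammaResult]:
    """2D gamma on transverse slices at the given depths.

    The search is two-dimensional within each slice, matching a
    planar-detector comparison at a proximal and a distal depth.
    """
    _check_frames(reference, evaluated)
    out = {}
    for d in depths_mm:
        rs = reference.depth_slice(d)
        es = evaluated.depth_slice(d)
        out[float(d)] = gamma_nd(rs, es, reference.spacing[:2], criteria)
    return out


def _check_frames(a: DoseGrid, b: DoseGrid) -> None:
    for f in ("x_mm", "y_mm", "depth_mm"):
        if not np.allclose(getattr(a, f), getattr(b, f)):
            raise ValueError(f"dose grids differ in {f}; resample first")


def sobp_metrics(profile: np.ndarray, depth_mm: np.ndarray,
                 plateau: tuple[float, float],
                 reference_profile: np.ndarray | None = None):
    """Flatness and (optionally) deviation-from-reference on a plateau.

    flatness = max |D - mean| / mean over the plateau, in percent;
    max_deviation = max |D - D_ref| / mean(D_ref) over the plateau after
    normalizing both curves to their own plateau means, in percent.
    """
    lo, hi = plateau
    sel = (depth_mm >= lo) & (depth_mm <= hi)
    if not sel.any():
        raise ValueError("plateau interval outside the profile")
    p = np.asarray(profile, dtype=float)[sel]
    mean = p.mean()
    flatness = 100.0 * float(np.max(np.abs(p - mean)) / mean)
    if reference_profile is None:
        return {"flatness_pct": flatness}
    r = np.asarray(reference_profile, dtype=float)[sel]
    dev = 100.0 * float(np.max(np.abs(p / mean - r / r.mean())))
    return {"flatness_pct": flatness, "max_deviation_pct": dev}


def report_table(rows: list[dict], path=None) -> pd.DataFrame:
    """Scenario x {proximal, distal} passing-rate table (CSV/Markdown).

    ``rows`` carry scenario name and the two GammaResults; rates are
    rounded to integer percent in the table, full precision stays with the
    results themselves.
    """
    df = pd.DataFrame([
        {"scenario": r["name"],
         "proximal_gi_pct": int(round(r["proximal"].passing_rate)),
         "distal_gi_pct": int(round(r["distal"].passing_rate))}
        for r in rows
    ])
    if path is not None:
        path = str(path)
        if path.endswith(".md"):
            with open(path, "w") as fh:
                fh.write(df.to_markdown(index=False))
        else:
            df.to_csv(path, index=False)
    return df
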