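"""Matplotlib helpers for pin contours, SOBP curves and dose slices."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_pin_contour", "plot_sobp_curves", "plot_dose_slice"]


def plot_pin_contour(pin, ax=None):
    """Cross-section of a pin through the cell center (height vs x)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 4))
    a = pin.base_period_mm
    u = np.linspace(-a / 2, a / 2, 601)
    c = np.clip((2.0 * np.abs(u) / a) ** 2, 0.0, 1.0)
    h = pin.height_at_cum_area(c)
    ax.fill_between(u, 0, h, step=None, alpha=0.6)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("pin height (mm)")
    ax.set_title(f"{pin.kind} pin, {a:g} mm base")
    return ax


def plot_sobp_curves(depth_mm, curves: dict, plateau=None, ax=None):
    """Overlay normalized SOBP depth-dose curves (label -> dose array)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, dose in curves.items():
        d = np.asarray(dose, dtype=float)
        sel = slice(None)
        if plateau is not None:
            sel = (depth_mm >= plateau[0]) & (depth_mm <= plateau[1])
        ax.plot(depth_mm, d / d[sel].mean(), label=str(label))
    if plateau is not None:
        ax.axvspan(*plateau, alpha=0.1)
    ax.set_xlabel("depth in water (mm)")
    ax.set_ylabel("relative dose")
    ax.legend()
    return ax


def plot_dose_slice(dose, depth_mm: float, ax=None):
    """Transverse isodose slice at a depth (percent of slice max)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sl = dose.depth_slice(depth_mm).T
    m = ax.contourf(dose.x_mm, dose.y_mm, 100 * sl / sl.max(),
                    levels=[10, 20, 40, 60, 80, 90, 95, 100])
    plt.colorbar(m, ax=ax, label="dose (% of slice max)")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"depth {depth_mm:g} mm")
    return ax
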