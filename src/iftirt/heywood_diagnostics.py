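"""Heywood-case detection from information curves.

An improper solution ("Heywood case", "Guttman item") shows up as the
collapse of Fisher information toward a point mass: a spike of the item
information curve at a critical point theta*.  This module locates those
critical points on a grid, computes the item fraction of total information
(IFTI) decomposition, applies the flagging thresholds, and supports the
drop-and-recompute analysis.

Flag semantics (worst flag wins, all triggering criteria reported):

- ``suspect``      — |slope| > 5, equivalently peak information > 6.25 for a
  plain 2PL under a unit-variance latent trait;
- ``troublesome``  — IFTI exceeds 2/J anywhere in the theta window;
- ``problematic``  — IFTI exceeds 4/J anywhere in the theta window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .information import InformationCurve, ThetaGrid, _Curve
from .irt_models import ItemSet, NRMItem

__all__ = [
    "CriticalPointSet",
    "IFTICurve",
    "Thresholds",
    "HeywoodReport",
    "ItemFlag",
    "FLAG_ORDER",
    "find_information_peaks",
    "ifti",
    "drop_and_recompute",
    "flag_items",
]

FLAG_ORDER = ("none", "troublesome", "suspect", "problematic")


@dataclass(frozen=True)
class CriticalPointSet:
    """Local maxima of an information curve.

    ``theta_stars``/``peak_heights`` list interior local maxima (plateau
    runs are reported at their midpoint).  ``boundary_note`` is set when the
    curve's global maximum sits on the grid boundary (not a critical point:
    the derivative need not vanish there), and ``plateau`` when a detected
    maximum was a flat run — including the degenerate constant curve, which
    yields an empty set plus a note.
    """

    label: str
    theta_stars: tuple
    peak_heights: tuple
    boundary_note: str | None = None
    plateau: bool = False

    @property
    def max_height(self) -> float | None:
        return max(self.peak_heights) if self.peak_heights else None


@dataclass(frozen=True)
class IFTICurve(_Curve):
    """Item fraction of total information on a grid.

    Unitless, in [0, 1], summing to 1 across items at every unmasked point.
    ``masked`` marks grid points where total information was 0 (fraction
    undefined, stored as NaN).  ``scaled`` returns the effective-number-of-
    items variant IFTI * J.
    """

    n_items: int = 1
    masked: np.ndarray | None = field(default=None, compare=False)

    @property
    def scaled(self) -> np.ndarray:
        return self.values * self.n_items


@dataclass(frozen=True)
class Thresholds:
    """Flagging cutoffs; defaults follow the unit-variance calibration."""

    slope_cut: float = 5.0
    info_cut: float = 6.25
    ifti_troublesome: float = 2.0  # numerator of 2/J
    ifti_problematic: float = 4.0  # numerator of 4/J

    def __post_init__(self):
        for name in ("slope_cut", "info_cut", "ifti_troublesome", "ifti_problematic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_slope(cls, slope_cut: float, **kw) -> "Thresholds":
        """Derive the information cut jointly as slope_cut**2 / 4."""
        return cls(slope_cut=slope_cut, info_cut=slope_cut**2 / 4.0, **kw)


@dataclass(frozen=True)
class ItemFlag:
    label: str
    flag: str
    criteria: tuple
    theta_star: float | None
    peak_info: float | None
    ifti_max: float | None
    ifti_exceed: tuple | None  # (lo, hi) theta interval above the exceeded cut


@dataclass(frozen=True)
class HeywoodReport:
    """Per-item flags with criteria, peak locations, and IFTI exceedance."""

    items: tuple
    thresholds: Thresholds
    theta_window: tuple | None = None

    def __getitem__(self, label: str) -> ItemFlag:
        for it in self.items:
            if it.label == label:
                return it
        raise KeyError(label)

    @property
    def flagged(self) -> tuple:
        return tuple(it for it in self.items if it.flag != "none")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            lo, hi = it.ifti_exceed if it.ifti_exceed else (np.nan, np.nan)
            rows.append(
                {
                    "item_id": it.label,
                    "flag": it.flag,
                    "criteria": "+".join(it.criteria) if it.criteria else "",
                    "theta_star": np.nan if it.theta_star is None else it.theta_star,
                    "peak_info": np.nan if it.peak_info is None else it.peak_info,
                    "ifti_max": np.nan if it.ifti_max is None else it.ifti_max,
                    "ifti_exceed_lo": lo,
                    "ifti_exceed_hi": hi,
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        J = len(self.items)
        t = self.thresholds
        lines = [
            f"Heywood diagnostics for {J} items "
            f"(cuts: |slope|>{t.slope_cut:g}, info>{t.info_cut:g}, "
            f"IFTI>{t.ifti_troublesome:g}/J={t.ifti_troublesome / J:.4g}, "
            f"IFTI>{t.ifti_problematic:g}/J={t.ifti_problematic / J:.4g})"
        ]
        for it in self.items:
            if it.flag == "none":
                continue
            bits = [f"{it.label}: {it.flag.upper()} [{', '.join(it.criteria)}]"]
            if it.peak_info is not None and it.theta_star is not None:
                bits.append(f"peak info {it.peak_info:.3g} at theta*={it.theta_star:.3g}")
            if it.ifti_exceed is not None:
                bits.append(
                    f"IFTI max {it.ifti_max:.3g} over theta in "
                    f"[{it.ifti_exceed[0]:.3g}, {it.ifti_exceed[1]:.3g}]"
                )
            lines.append("  " + "; ".join(bits))
        if len(lines) == 1:
            lines.append("  no flags")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# critical points
# ---------------------------------------------------------------------------


def find_information_peaks(curve: InformationCurve) -> CriticalPointSet:
    """Locate the interior local maxima of an information curve on its grid.

    A peak is a run of equal values whose immediate neighbors on both sides
    are strictly lower (which implies a sign change of the finite-difference
    first derivative and a non-positive second difference); runs report
    their midpoint.  Boundary maxima are never reported as theta* — the
    derivative need not vanish there — but are noted.
    """
    v = curve.values
    th = curve.grid.values
    n = v.size

    # runs of equal consecutive values
    starts = [0]
    for i in range(1, n):
        if v[i] != v[starts[-1]]:
            starts.append(i)
    starts.append(n)

    stars: list[float] = []
    heights: list[float] = []
    plateau = False
    for idx in range(len(starts) - 1):
        a, b = starts[idx], starts[idx + 1]
        left_lower = a > 0 and v[a - 1] < v[a]
        right_lower = b < n and v[b] < v[a]
        if left_lower and right_lower:
            stars.append(float((th[a] + th[b - 1]) / 2.0))
            heights.append(float(v[a]))
            if b - a > 1:
                plateau = True

    note = None
    if v[0] == v.max() == v[-1] and np.all(v == v[0]):
        note = "curve is constant over the grid (plateau); no interior critical point"
        plateau = True
    elif not stars or max(heights) < v.max():
        side = "left" if v[0] >= v[-1] else "right"
        edge_val = max(v[0], v[-1])
        if edge_val >= v.max():
            note = f"global maximum {edge_val:.6g} lies on the {side} grid boundary"
    return CriticalPointSet(curve.label, tuple(stars), tuple(heights), note, plateau)


# ---------------------------------------------------------------------------
# IFTI
# ---------------------------------------------------------------------------


def ifti(curves: Sequence[InformationCurve]) -> list[IFTICurve]:
    """Item fraction of total information, pointwise on the shared grid.

    Points where the total information is exactly 0 are masked (NaN) rather
    than invented.  Fractions sum to 1 across items everywhere else.
    """
    if not curves:
        raise ValueError("need at least one information curve")
    grid = curves[0].grid
    for c in curves[1:]:
        if c.grid != grid:
            raise ValueError(f"curve {c.label!r} is on a different grid")
    stack = np.vstack([c.values for c in curves])
    total = stack.sum(axis=0)
    zero = total == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = stack / total
    frac[:, zero] = np.nan
    masked = zero if zero.any() else None
    J = len(curves)
    return [
        IFTICurve(c.label, grid, frac[j], n_items=J, masked=masked)
        for j, c in enumerate(curves)
    ]


def drop_and_recompute(curves: Sequence[InformationCurve],
                       drop_labels: Sequence[str]) -> list[IFTICurve]:
    """IFTI renormalized over the items that survive a drop (no refit)."""
    drop = set(drop_labels)
    known = {c.label for c in curves}
    unknown = drop - known
    if unknown:
        raise KeyError(f"unknown labels: {sorted(unknown)}")
    keep = [c for c in curves if c.label not in drop]
    if not keep:
        raise ValueError("cannot drop every item")
    return ifti(keep)


# ---------------------------------------------------------------------------
# flagging
# ---------------------------------------------------------------------------


def _item_slope(item) -> float | None:
    if isinstance(item, NRMItem):
        return None  # no single slope; info/IFTI criteria still apply
    return getattr(item, "slope", getattr(item, "loading", None))


def _exceed_interval(theta: np.ndarray, exceed: np.ndarray) -> tuple | None:
    if not exceed.any():
        return None
    idx = np.nonzero(exceed)[0]
    return (float(theta[idx[0]]), float(theta[idx[-1]]))


def flag_items(
    items: ItemSet,
    curves: Sequence[InformationCurve],
    ifti_curves: Sequence[IFTICurve] | None = None,
    thresholds: Thresholds | None = None,
    theta_window: tuple[float, float] | None = None,
) -> HeywoodReport:
    """Apply the slope/information/IFTI criteria and report per-item flags.

    IFTI criteria are evaluated pointwise inside ``theta_window`` (default:
    the whole grid); an item's flag is the worst across criteria and every
    triggering criterion is listed.
    """
    if thresholds is None:
        thresholds = Thresholds()
    if ifti_curves is None:
        ifti_curves = ifti(list(curves))
    if len(curves) != items.n_items or len(ifti_curves) != items.n_items:
        raise ValueError("items, curves and ifti_curves must align")
    grid = curves[0].grid
    wmask = grid.window_mask(theta_window)
    J = items.n_items
    cut_tr = thresholds.ifti_troublesome / J
    cut_pr = thresholds.ifti_problematic / J

    flags = []
    for item, label, icurve, fcurve in zip(items, items.labels, curves, ifti_curves):
        if icurve.label != label or fcurve.label != label:
            raise ValueError(f"curve labels do not match item {label!r}")
        criteria: list[str] = []
        worst = 0

        slope = _item_slope(item)
        if slope is not None and abs(slope) > thresholds.slope_cut:
            criteria.append("slope")
            worst = max(worst, FLAG_ORDER.index("suspect"))

        cps = find_information_peaks(icurve)
        in_window = [
            (t, h)
            for t, h in zip(cps.theta_stars, cps.peak_heights)
            if theta_window is None or theta_window[0] <= t <= theta_window[1]
        ]
        theta_star, peak = (max(in_window, key=lambda p: p[1]) if in_window else (None, None))
        if peak is not None and peak > thresholds.info_cut:
            criteria.append("info")
            worst = max(worst, FLAG_ORDER.index("suspect"))

        fvals = fcurve.values[wmask]
        finite = np.isfinite(fvals)
        ifti_max = float(np.nanmax(fvals)) if finite.any() else None
        exceed = None
        if ifti_max is not None and ifti_max > cut_tr:
            criteria.append("ifti")
            worst = max(worst, FLAG_ORDER.index("troublesome"))
            cut = cut_tr
            if ifti_max > cut_pr:
                worst = max(worst, FLAG_ORDER.index("problematic"))
                cut = cut_pr
            win_theta = grid.values[wmask]
            with np.errstate(invalid="ignore"):
                exceed = _exceed_interval(win_theta, fvals > cut)

        flags.append(
            ItemFlag(
                label=label,
                flag=FLAG_ORDER[worst],
                criteria=tuple(criteria),
                theta_star=theta_star,
                peak_info=peak,
                ifti_max=ifti_max,
                ifti_exceed=exceed,
            )
        )
    return HeywoodReport(tuple(flags), thresholds, theta_window)
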