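"""Fisher information, optimal scoring weights, and reliability mappings.

Item information is the local curvature of the log-likelihood in theta.  For
binary items it is ``(d pi/d theta)^2 / (pi (1 - pi))``; for the linear family
it is the constant ``xi^2 / psi^2`` (``(1 - h2)/h2`` in the standardized
solution); for the nominal model it is the sum of per-category terms
``(d pi_k)^2 / pi_k - d2 pi_k``.  Under local independence information is
additive across items, which licenses the test information function and the
per-theta reliability mapping ``rel = I / (1 + I)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .irt_models import (
    BINARY_FAMILIES,
    Binary2PLItem,
    Item,
    ItemSet,
    LinearItem,
    NRMItem,
    RHItem,
    irf,
    irf_derivative,
)

__all__ = [
    "ThetaGrid",
    "InformationCurve",
    "CategoryInformationCurve",
    "TestInformationCurve",
    "ReliabilityCurve",
    "WeightCurve",
    "linear_item_information",
    "linear_total_information",
    "binary_item_information",
    "nrm_item_information",
    "item_information",
    "information_curves",
    "test_information",
    "reliability",
    "optimal_weights",
]

# clip for pi(1-pi) denominators at numerically degenerate grid points
_P_EPS = 1e-12


@dataclass(frozen=True)
class ThetaGrid:
    """Uniform, strictly increasing grid of latent-trait values.

    ``standardized`` records the var(Theta) = 1 convention under which the
    information units (1/theta^2) and all default thresholds are calibrated.
    """

    values: np.ndarray
    standardized: bool = True

    def __init__(self, values, standardized: bool = True):
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size < 3:
            raise ValueError("ThetaGrid requires a 1-d grid with at least 3 points")
        steps = np.diff(v)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8, atol=0):
            raise ValueError("ThetaGrid must be strictly increasing with uniform spacing")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "standardized", bool(standardized))

    @classmethod
    def regular(cls, lo: float = -4.0, hi: float = 4.0, step: float = 0.01) -> "ThetaGrid":
        """Default plotting/diagnostic grid: [-4, 4] in steps of 0.01."""
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo and step > 0):
            raise ValueError("invalid grid bounds/step")
        n = int(round((hi - lo) / step)) + 1
        return cls(np.linspace(lo, hi, n))

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ThetaGrid)
            and self.standardized == other.standardized
            and np.array_equal(self.values, other.values)
        )

    def __hash__(self):
        return hash((self.values.tobytes(), self.standardized))

    def window_mask(self, window: tuple[float, float] | None) -> np.ndarray:
        """Boolean mask for a (lo, hi) theta window; full grid when None."""
        if window is None:
            return np.ones(len(self), dtype=bool)
        lo, hi = window
        mask = (self.values >= lo) & (self.values <= hi)
        if not mask.any():
            raise ValueError(f"theta window {window!r} contains no grid points")
        return mask


@dataclass(frozen=True)
class _Curve:
    label: str
    grid: ThetaGrid
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError("curve values must match the grid length")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class InformationCurve(_Curve):
    """Item information I_j(theta) on a grid; ``flagged`` marks grid points
    where pi(1-pi) was numerically degenerate and clipping was applied."""

    flagged: np.ndarray | None = field(default=None, compare=False)


@dataclass(frozen=True)
class CategoryInformationCurve(_Curve):
    """Per-category information share of a nominal item; sums to the item
    curve over categories."""

    category: int = 0


@dataclass(frozen=True)
class TestInformationCurve(_Curve):
    """Test information: the item-wise sum under local independence."""


@dataclass(frozen=True)
class ReliabilityCurve(_Curve):
    """Reliability rel(theta) = I/(1+I) at item or test level."""


@dataclass(frozen=True)
class WeightCurve(_Curve):
    """Optimal scoring weights w(theta) = dpi / (pi (1-pi)); constant and
    equal to the slope for the plain 2PL."""


# ---------------------------------------------------------------------------
# linear family
# ---------------------------------------------------------------------------


def linear_item_information(item: LinearItem, label: str = "item") -> float:
    """Constant information of a linear item: ``xi^2/psi^2``.

    In the standardized solution this is ``(1 - h2)/h2``.  Items with
    non-positive unique variance cannot be constructed at all, but the label
    is still threaded through for diagnostics raised here.
    """
    if item.unique_variance <= 0:  # unreachable via the constructor; belt and braces
        raise ValueError(f"item {label!r}: unique variance <= 0 is a Heywood case")
    if item.communality is not None:
        h2 = item.communality
        return (1.0 - h2) / h2
    return item.loading**2 / item.unique_variance


def linear_total_information(items: ItemSet, standardized: bool = True) -> float:
    """Total information of a linear item set.

    For a standardized set with communalities h2 this is ``sum(1/h2) - V``;
    otherwise the plain sum of ``xi^2/psi^2``.
    """
    if items.family != "linear":
        raise ValueError(f"expected linear items, got family {items.family!r}")
    if standardized:
        h2s = []
        for it, lb in zip(items, items.labels):
            if it.communality is None:
                raise ValueError(f"item {lb!r} has no communality; pass standardized=False")
            if not 0.0 < it.communality < 1.0:
                raise ValueError(f"item {lb!r}: communality outside (0,1)")
            h2s.append(it.communality)
        return float(sum(1.0 / h for h in h2s) - items.n_items)
    return float(sum(linear_item_information(it, lb) for it, lb in zip(items, items.labels)))


# ---------------------------------------------------------------------------
# binary and nominal families
# ---------------------------------------------------------------------------


def binary_item_information(item: Binary2PLItem | RHItem, grid: ThetaGrid,
                            label: str = "item") -> InformationCurve:
    """Information curve ``(dpi)^2 / (pi(1-pi))`` for a binary item.

    Grid points where pi(1-pi) underflows are computed with pi clipped to
    [1e-12, 1-1e-12] and marked in ``flagged``.
    """
    if getattr(item, "family", None) not in BINARY_FAMILIES:
        raise ValueError(f"item {label!r} is not from a binary family")
    th = grid.values
    p = irf(item, th)
    d1 = irf_derivative(item, th, order=1)
    degenerate = (p < _P_EPS) | (p > 1.0 - _P_EPS)
    pc = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    info = d1**2 / (pc * (1.0 - pc))
    return InformationCurve(label, grid, info, flagged=degenerate if degenerate.any() else None)


def nrm_item_information(
    item: NRMItem, grid: ThetaGrid, label: str = "item"
) -> tuple[InformationCurve, list[CategoryInformationCurve]]:
    """Item and per-category information for a nominal item.

    The category term is ``(dpi_k)^2/pi_k - d2pi_k``; summed over categories
    the second-derivative parts cancel (they sum to 0 pointwise), so the
    total equals ``sum_k (dpi_k)^2/pi_k`` — both routes agree to 1e-10 by
    the module's guard test.
    """
    th = grid.values
    p = irf(item, th)  # (n, K)
    d1 = irf_derivative(item, th, order=1)
    d2 = irf_derivative(item, th, order=2)
    pc = np.clip(p, _P_EPS, None)
    cat_vals = d1**2 / pc - d2
    cats = [
        CategoryInformationCurve(label, grid, cat_vals[:, k], category=k + 1)
        for k in range(item.n_categories)
    ]
    total = InformationCurve(label, grid, cat_vals.sum(axis=1))
    return total, cats


def item_information(item: Item, grid: ThetaGrid, label: str = "item") -> InformationCurve:
    """Information curve for any supported family (constant for linear)."""
    if isinstance(item, LinearItem):
        const = linear_item_information(item, label)
        return InformationCurve(label, grid, np.full(len(grid), const))
    if isinstance(item, NRMItem):
        return nrm_item_information(item, grid, label)[0]
    return binary_item_information(item, grid, label)


def information_curves(items: ItemSet, grid: ThetaGrid) -> list[InformationCurve]:
    """Per-item information curves for a whole set, labels preserved."""
    return [item_information(it, grid, lb) for it, lb in zip(items, items.labels)]


def test_information(curves: Sequence[InformationCurve]) -> TestInformationCurve:
    """Pointwise sum of item information curves sharing one grid."""
    if not curves:
        raise ValueError("need at least one information curve")
    grid = curves[0].grid
    for c in curves[1:]:
        if c.grid != grid:
            raise ValueError(f"curve {c.label!r} is on a different grid")
    total = np.sum([c.values for c in curves], axis=0)
    return TestInformationCurve("TEST", grid, total)


def reliability(info, label: str = "rel"):
    """Map information to reliability via ``rel = I / (1 + I)``.

    Accepts a scalar, an array, or an information curve; negative
    information is rejected.
    """
    if isinstance(info, _Curve):
        vals = reliability(info.values)
        return ReliabilityCurve(info.label, info.grid, vals)
    arr = np.asarray(info, dtype=float)
    if np.any(arr < 0):
        raise ValueError("information must be nonnegative")
    out = arr / (1.0 + arr)
    return float(out) if out.ndim == 0 else out


def optimal_weights(item: Binary2PLItem | RHItem, grid: ThetaGrid,
                    label: str = "item") -> WeightCurve:
    """Optimal scoring weights ``w = dpi / (pi (1-pi))`` for binary items."""
    if getattr(item, "family", None) not in BINARY_FAMILIES:
        raise ValueError(f"item {label!r} is not from a binary family")
    th = grid.values
    p = np.clip(irf(item, th), _P_EPS, 1.0 - _P_EPS)
    d1 = irf_derivative(item, th, order=1)
    return WeightCurve(label, grid, d1 / (p * (1.0 - p)))
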