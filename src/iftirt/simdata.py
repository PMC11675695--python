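"""Seeded synthetic item sets and response matrices.

Everything downstream is testable offline: latent traits are standard
Gaussian draws, responses are independent Bernoulli/categorical draws from
the family's IRF (local independence), and :func:`make_fixture_suite`
provides the canonical deterministic fixtures, including one with a planted
near-Guttman (slope 8) item and the published 16-item RH parameter set used
as generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .irt_models import (
    Binary2PLItem,
    ItemSet,
    LinearItem,
    NRMItem,
    RHItem,
    irf,
)
from .scoring import ResponseMatrix

__all__ = [
    "SimConfig",
    "RH_TABLE1_PARAMS",
    "rh_table1_itemset",
    "simulate_thetas",
    "simulate_responses",
    "make_fixture_suite",
    "Fixture",
]

#: Published RH point estimates for the 16-item set (label, eta, xi, delta);
#: two mental-rotation items carry extreme negative delta and act as the
#: canonical real-world-like Heywood exemplars.
RH_TABLE1_PARAMS = (
    ("RE4", 0.94, 0.47, -0.12),
    ("RE16", 0.84, 0.69, 0.28),
    ("RE17", 1.02, 0.77, 0.44),
    ("RE19", 0.82, 0.47, 0.94),
    ("LT7", 0.91, 0.39, 0.56),
    ("LT33", 0.79, 0.27, 0.44),
    ("LT34", 0.94, 0.50, 1.05),
    ("LT58", 0.84, -0.18, 0.20),
    ("MX45", 0.62, 0.13, 0.55),
    ("MX46", 0.65, 0.17, 0.26),
    ("MX47", 0.78, 0.38, 0.23),
    ("MX55", 0.52, -0.40, -0.29),
    ("MR3", 1.03, -1.29, -2.45),
    ("MR4", 1.12, -1.29, -2.64),
    ("MR6", 0.91, -0.84, -1.27),
    ("MR8", 0.94, -1.27, -1.53),
)


def rh_table1_itemset() -> ItemSet:
    """The 16-item RH set with the published point estimates as parameters."""
    return ItemSet(
        [RHItem(eta, xi, delta) for _, eta, xi, delta in RH_TABLE1_PARAMS],
        [label for label, *_ in RH_TABLE1_PARAMS],
    )


@dataclass(frozen=True)
class SimConfig:
    """Generative settings: person count, item set, latent distribution, seed."""

    n_persons: int
    items: ItemSet
    seed: int
    theta_mean: float = 0.0
    theta_var: float = 1.0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.theta_var <= 0:
            raise ValueError("theta_var must be positive")


def simulate_thetas(config: SimConfig) -> np.ndarray:
    """N seeded Gaussian latent-trait draws, Theta ~ N(mean, var)."""
    rng = np.random.default_rng(config.seed)
    return config.theta_mean + np.sqrt(config.theta_var) * rng.standard_normal(config.n_persons)


def simulate_responses(items: ItemSet, thetas, seed: int) -> ResponseMatrix:
    """Independent response draws per person-item from the family's IRF."""
    th = np.asarray(thetas, dtype=float)
    rng = np.random.default_rng(seed)
    N, V = th.size, items.n_items
    if items.family in ("2pl", "3pl", "4pl", "rh"):
        P = np.column_stack([irf(it, th) for it in items])
        data = (rng.random((N, V)) < P).astype(int)
    elif items.family == "nrm":
        data = np.empty((N, V), dtype=int)
        u = rng.random((N, V))
        for v, it in enumerate(items):
            probs = irf(it, th)  # (N, K)
            cum = np.cumsum(probs, axis=1)
            data[:, v] = 1 + (u[:, v : v + 1] > cum).sum(axis=1)
    elif items.family == "linear":
        mu = np.array([it.easiness for it in items])
        xi = np.array([it.loading for it in items])
        sd = np.sqrt([it.unique_variance for it in items])
        data = mu + np.outer(th, xi) + rng.standard_normal((N, V)) * sd
    else:
        raise ValueError(f"unsupported family {items.family!r}")
    return ResponseMatrix(data, item_labels=items.labels)


@dataclass(frozen=True)
class Fixture:
    name: str
    items: ItemSet
    thetas: dict = field(default_factory=dict)  # N -> theta vector
    responses: dict = field(default_factory=dict)  # N -> ResponseMatrix


def _clean_2pl_itemset() -> ItemSet:
    # moderate slopes in a narrow band: with etas spread over [-1.5, 1.5] no
    # item's IFTI reaches the 4/J problematic cut anywhere on the default grid
    etas = np.linspace(-1.5, 1.5, 16)
    xis = np.tile([0.9, 1.0, 1.1, 1.2], 4)
    return ItemSet(
        [Binary2PLItem(e, x) for e, x in zip(etas, xis)],
        [f"C{i + 1:02d}" for i in range(16)],
    )


def _planted_guttman_itemset(slope: float = 8.0) -> ItemSet:
    base = _clean_2pl_itemset()
    items = list(base.items)
    labels = list(base.labels)
    items[8] = Binary2PLItem(items[8].intercept, slope)
    labels[8] = "G09"
    return ItemSet(items, labels)


def _nrm_small_itemset(rng: np.random.Generator, n_items: int = 8, k: int = 5) -> ItemSet:
    items = []
    for _ in range(n_items):
        a = rng.normal(0.0, 0.8, size=k)
        g = rng.normal(0.0, 0.7, size=k)
        items.append(NRMItem.from_baseline(a, g))
    return ItemSet(items, [f"N{i + 1:02d}" for i in range(n_items)])


def make_fixture_suite(seed: int, sizes=(200, 2000)) -> dict:
    """Deterministic named fixtures covering every supported family.

    Returns ``{name: Fixture}`` for "clean_2pl", "planted_guttman",
    "rh_table1", and "nrm_small", each with latent traits and responses at
    the requested sample sizes.  Identical seeds reproduce every array
    bit-for-bit.
    """
    ss = np.random.SeedSequence(seed)
    names = ("clean_2pl", "planted_guttman", "rh_table1", "nrm_small")
    children = {n: s for n, s in zip(names, ss.spawn(len(names)))}

    nrm_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    itemsets = {
        "clean_2pl": _clean_2pl_itemset(),
        "planted_guttman": _planted_guttman_itemset(),
        "rh_table1": rh_table1_itemset(),
        "nrm_small": _nrm_small_itemset(nrm_rng),
    }

    suite = {}
    for name in names:
        sub = children[name].spawn(2 * len(sizes))
        thetas, responses = {}, {}
        for i, n in enumerate(sizes):
            th_seed, y_seed = sub[2 * i], sub[2 * i + 1]
            th = np.random.default_rng(th_seed).standard_normal(n)
            thetas[n] = th
            responses[n] = simulate_responses(
                itemsets[name], th, seed=y_seed.generate_state(1)[0]
            )
        suite[name] = Fixture(name, itemsets[name], thetas, responses)
    return suite
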