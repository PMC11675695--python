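"""Latent-trait scoring: Bartlett (linear family) and EAP (all families).

EAP sets a Gaussian prior on theta and updates it with the observed
responses by Bayes' rule; the posterior mean and SD are obtained by
fixed-node quadrature (61 equally spaced nodes on [-6, 6] by default — a
rectangular rule on the prior-weighted likelihood, which for smooth,
decaying integrands is extremely accurate).  Unlike maximum likelihood, EAP
stays finite for perfect response patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .irt_models import (
    BINARY_FAMILIES,
    Item,
    ItemSet,
    LinearItem,
    NRMItem,
    irf,
)

__all__ = ["ResponseMatrix", "ScoreTable", "bartlett_scores", "eap_scores",
           "score_volatility_summary"]


@dataclass(frozen=True)
class ResponseMatrix:
    """N x V integer-coded responses with an observed-data mask.

    Binary families use codes 0/1; the nominal family uses 1..K.  ``mask``
    is True where a response was observed.  Persons with no observed
    responses are tolerated (EAP returns the prior for them) but reported
    by :meth:`validate`.
    """

    data: np.ndarray
    mask: np.ndarray
    item_labels: tuple | None = None

    def __init__(self, data, mask=None, item_labels=None):
        d = np.asarray(data)
        if d.ndim != 2:
            raise ValueError("responses must be a 2-d (persons x items) array")
        if mask is None:
            if np.issubdtype(d.dtype, np.floating):
                mask = ~np.isnan(d)
            else:
                mask = np.ones(d.shape, dtype=bool)
        m = np.asarray(mask, dtype=bool)
        if m.shape != d.shape:
            raise ValueError("mask shape must match data shape")
        out = np.where(m, d, 0).astype(float)
        object.__setattr__(self, "data", out)
        object.__setattr__(self, "mask", m)
        if item_labels is not None:
            item_labels = tuple(str(x) for x in item_labels)
            if len(item_labels) != d.shape[1]:
                raise ValueError("item_labels length must match the item axis")
        object.__setattr__(self, "item_labels", item_labels)

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    def validate(self, family: str) -> None:
        obs = self.data[self.mask]
        if family in BINARY_FAMILIES or family == "linear":
            if family != "linear" and not np.all(np.isin(obs, (0.0, 1.0))):
                raise ValueError("binary families require 0/1 response codes")
        elif family == "nrm":
            if not np.all((obs >= 1) & (obs == np.round(obs))):
                raise ValueError("nominal responses must be integer codes 1..K")
        empty = ~self.mask.any(axis=1)
        if empty.any():
            import warnings

            warnings.warn(
                f"{int(empty.sum())} person(s) have no observed responses",
                stacklevel=2,
            )

    def number_correct(self) -> np.ndarray:
        """Per-person sum of observed binary responses."""
        return (self.data * self.mask).sum(axis=1)


@dataclass(frozen=True)
class ScoreTable:
    """Per-person predicted score, its standard error, and sum-score info."""

    theta: np.ndarray
    se: np.ndarray
    number_correct: np.ndarray
    proportion_correct: np.ndarray
    method: str = "eap"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta_hat": self.theta,
                "se": self.se,
                "number_correct": self.number_correct,
                "proportion_correct": self.proportion_correct,
            }
        )


def bartlett_scores(items: ItemSet, responses: ResponseMatrix) -> ScoreTable:
    """Closed-form Bartlett scores for the linear family.

    theta_hat = (sum xi^2/psi^2)^(-1) * sum(xi * y / psi^2), with the sums
    restricted to each person's observed items; SE = 1/sqrt(total info).
    Near-zero unique variances make single items dominate the score — the
    Heywood pathology — and psi^2 <= 0 is rejected at item construction.
    """
    if items.family != "linear":
        raise ValueError(f"Bartlett scoring requires linear items, got {items.family!r}")
    if responses.n_items != items.n_items:
        raise ValueError("response matrix width must match the item set")
    responses.validate("linear")
    xi = np.array([it.loading for it in items])
    psi2 = np.array([it.unique_variance for it in items])
    w = xi / psi2
    info = xi**2 / psi2
    m = responses.mask
    tot_info = (m * info).sum(axis=1)
    if np.any(tot_info <= 0):
        raise ValueError("some persons have zero total information (no observed items)")
    theta = (m * responses.data * w).sum(axis=1) / tot_info
    se = 1.0 / np.sqrt(tot_info)
    nc = (responses.data * m).sum(axis=1)
    n_obs = m.sum(axis=1)
    return ScoreTable(theta, se, nc, nc / np.maximum(n_obs, 1), method="bartlett")


def _log_likelihood_at_nodes(items: ItemSet, responses: ResponseMatrix,
                             nodes: np.ndarray) -> np.ndarray:
    """(N, Q) log-likelihood of each person's pattern at each quadrature node."""
    Y, M = responses.data, responses.mask
    if items.family in BINARY_FAMILIES:
        P = np.vstack([irf(it, nodes) for it in items])  # (V, Q)
        P = np.clip(P, 1e-300, 1.0 - 1e-16)
        logP, log1mP = np.log(P), np.log1p(-P)
        return (Y * M) @ logP + ((1.0 - Y) * M) @ log1mP
    if items.family == "nrm":
        N, Q = Y.shape[0], nodes.size
        ll = np.zeros((N, Q))
        for v, it in enumerate(items):
            probs = np.clip(irf(it, nodes), 1e-300, 1.0)  # (Q, K)
            obs = M[:, v]
            codes = Y[obs, v].astype(int) - 1
            ll[obs] += np.log(probs[:, codes]).T
        return ll
    if items.family == "linear":
        var = np.array([it.unique_variance for it in items])
        mu = np.array([it.easiness for it in items])
        xi = np.array([it.loading for it in items])
        pred = mu[None, :, None] + xi[None, :, None] * nodes[None, None, :]
        resid = (Y[:, :, None] - pred) ** 2 / var[None, :, None]
        logdens = -0.5 * (resid + np.log(2 * np.pi * var)[None, :, None])
        return (logdens * responses.mask[:, :, None]).sum(axis=1)
    raise ValueError(f"unsupported family {items.family!r}")


def eap_scores(
    items: ItemSet,
    responses: ResponseMatrix,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
    n_nodes: int = 61,
    node_range: tuple[float, float] = (-6.0, 6.0),
) -> ScoreTable:
    """Expected-a-posteriori scores: posterior mean and SD of theta.

    Missing responses are skipped in the likelihood; a person with no
    observed responses gets the (discretized) prior back.  Finite for every
    pattern, including all-correct/all-incorrect.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    if n_nodes < 3:
        raise ValueError("n_nodes must be at least 3")
    if responses.n_items != items.n_items:
        raise ValueError("response matrix width must match the item set")
    responses.validate(items.family)
    nodes = np.linspace(node_range[0], node_range[1], n_nodes)
    log_prior = norm.logpdf(nodes, loc=prior_mean, scale=prior_sd)
    ll = _log_likelihood_at_nodes(items, responses, nodes)
    if np.all(np.isneginf(ll), axis=1).any():
        raise ValueError("non-finite likelihood at every node for some person")
    logpost = ll + log_prior
    lz = logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost - lz)
    theta = post @ nodes
    var = post @ nodes**2 - theta**2
    se = np.sqrt(np.maximum(var, 0.0))
    m = responses.mask
    if items.family in BINARY_FAMILIES:
        nc = (responses.data * m).sum(axis=1)
    else:
        nc = np.full(responses.n_persons, np.nan)
    n_obs = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = nc / n_obs
    return ScoreTable(theta, se, nc, pc, method="eap")


def score_volatility_summary(scores: ScoreTable) -> pd.DataFrame:
    """Dispersion of scores and SEs within each number-correct group.

    The signature volatility of a Heywood-affected test: wide spread of
    theta_hat among persons sharing a (high) number-correct.
    """
    df = scores.to_frame()
    def iqr(x):
        return np.subtract(*np.percentile(x, [75, 25]))

    g = df.groupby("number_correct")
    out = g.agg(
        n=("theta_hat", "size"),
        theta_iqr=("theta_hat", iqr),
        theta_min=("theta_hat", "min"),
        theta_max=("theta_hat", "max"),
        se_iqr=("se", iqr),
        se_min=("se", "min"),
        se_max=("se", "max"),
    ).reset_index()
    out["theta_range"] = out["theta_max"] - out["theta_min"]
    return out
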