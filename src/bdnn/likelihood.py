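"""Birth-death and fossil-preservation likelihoods.

The birth-death component scores each lineage's origination time ``s`` and
extinction time ``e`` (Ma before present, ``s > e``) under piecewise-constant
lineage-specific rates defined on a decreasing grid of bin boundaries:

* extinct lineage:  ``log lam(s) + log mu(e) - integral_e^s (lam + mu) dt``
* extant lineage (``e = 0``):  ``log lam(s) - integral_0^s (lam + mu) dt``

The integral is computed exactly as a sum over bin overlaps, so refining the
bin grid leaves the likelihood unchanged.

The preservation component models fossil occurrences as a time-variable
Poisson process with baseline rate ``q`` per preservation bin and a
lineage-specific gamma multiplier with shape ``alpha`` (mean 1), marginalized
over a discrete set of quantile categories.  The likelihood is conditioned on
observing at least one occurrence per lineage, since unsampled lineages never
enter a fossil dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

__all__ = [
    "PreservationModel",
    "bin_indices",
    "interval_bin_overlap",
    "bd_lineage_loglik",
    "bd_total_loglik",
    "preservation_loglik",
    "preservation_total_loglik",
    "gamma_category_multipliers",
    "expected_occurrences",
]


def bin_indices(ages, edges) -> np.ndarray:
    """Bin index for each age on a decreasing edge grid.

    Bin ``b`` covers ``(edges[b+1], edges[b]]``; age 0 maps to the youngest
    bin and ``edges[0]`` to the oldest.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    edges = np.asarray(edges, dtype=float)
    if np.any(ages < edges[-1] - 1e-12) or np.any(ages > edges[0] + 1e-12):
        raise ValueError("age outside the bin grid")
    asc = edges[::-1]
    n_bins = len(edges) - 1
    i = np.clip(np.searchsorted(asc, ages, side="left"), 1, n_bins)
    return (n_bins - i).astype(int)


def interval_bin_overlap(lo, hi, edges) -> np.ndarray:
    """Overlap durations of intervals ``[lo, hi]`` with each bin.

    ``lo``/``hi`` may be scalars or arrays of shape (n,); returns (n, n_bins)
    (or (n_bins,) for scalars) on the decreasing ``edges`` grid.
    """
    scalar = np.ndim(lo) == 0 and np.ndim(hi) == 0
    lo = np.atleast_1d(np.asarray(lo, dtype=float))
    hi = np.atleast_1d(np.asarray(hi, dtype=float))
    edges = np.asarray(edges, dtype=float)
    top = edges[None, :-1]
    bottom = edges[None, 1:]
    ov = np.minimum(hi[:, None], top) - np.maximum(lo[:, None], bottom)
    ov = np.clip(ov, 0.0, None)
    return ov[0] if scalar else ov


def bd_lineage_loglik(s, e, lam, mu, edges, extant: bool = False) -> float:
    """Log-probability of one lineage's (s, e) under its piecewise rates.

    ``lam``/``mu`` hold one rate per bin of the decreasing ``edges`` grid.
    For extant lineages ``e`` must be 0 and the extinction term drops.
    """
    s, e = float(s), float(e)
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if extant and e != 0.0:
        raise ValueError("extant lineages must have e = 0")
    if s <= e:
        raise ValueError(f"origination {s} must precede extinction {e} in age")
    if np.any(lam <= 0) or np.any(mu <= 0):
        raise ValueError("rates must be strictly positive")
    ov = interval_bin_overlap(np.array([e]), np.array([s]), edges)[0]
    total = -np.sum((lam + mu) * ov)
    total += np.log(lam[bin_indices(s, edges)[0]])
    if not extant:
        total += np.log(mu[bin_indices(e, edges)[0]])
    return float(total)


def bd_total_loglik(s, e, lam, mu, edges, extant) -> float:
    """Sum of lineage birth-death log-likelihoods, vectorized.

    ``lam``/``mu`` are (n_species, n_bins) rate matrices; ``s``, ``e`` and the
    boolean ``extant`` mask are (n_species,).
    """
    s = np.asarray(s, dtype=float)
    e = np.asarray(e, dtype=float)
    extant = np.asarray(extant, dtype=bool)
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(s <= e):
        raise ValueError("every origination must precede its extinction in age")
    if np.any(extant & (e != 0.0)):
        raise ValueError("extant lineages must have e = 0")
    ov = interval_bin_overlap(e, s, edges)
    total = -np.sum((lam + mu) * ov)
    rows = np.arange(len(s))
    total += np.sum(np.log(lam[rows, bin_indices(s, edges)]))
    ext = ~extant
    if np.any(ext):
        total += np.sum(np.log(mu[rows[ext], bin_indices(e[ext], edges)]))
    return float(total)


# ---------------------------------------------------------------------------
# preservation


@dataclass
class PreservationModel:
    """Time-variable Poisson preservation with gamma lineage heterogeneity.

    ``q`` holds one baseline rate (occurrences / lineage / Myr) per bin of the
    decreasing ``edges`` grid; ``alpha`` is the shape of the mean-1 gamma
    distribution of per-lineage multipliers (``alpha = inf`` switches
    heterogeneity off); the gamma is discretized into ``n_categories``
    equal-probability categories.
    """

    q: np.ndarray
    edges: np.ndarray
    alpha: float = np.inf
    n_categories: int = 4

    def __post_init__(self):
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.edges = np.asarray(self.edges, dtype=float)
        if len(self.q) != len(self.edges) - 1:
            raise ValueError("one q per preservation bin required")
        if np.any(self.q <= 0):
            raise ValueError("preservation rates must be positive")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    def multipliers(self) -> np.ndarray:
        return gamma_category_multipliers(self.alpha, self.n_categories)


def gamma_category_multipliers(alpha: float, n: int) -> np.ndarray:
    """Discrete mean-1 gamma multipliers (quantile medians, renormalized).

    With ``alpha = inf`` or ``n = 1`` heterogeneity collapses to a single
    multiplier of 1.
    """
    if not np.isfinite(alpha) or n == 1:
        return np.ones(max(n, 1))
    probs = (np.arange(n) + 0.5) / n
    m = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    return m / m.mean()


def _log1mexp(x):
    """log(1 - exp(-x)) for x > 0, numerically stable."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        small = x < 0.693
        out = np.where(
            small,
            np.log(-np.expm1(-np.where(small, x, 1.0))),
            np.log1p(-np.exp(-np.where(small, 1.0, x))),
        )
    return out


def preservation_total_loglik(counts, s, e, model: PreservationModel) -> float:
    """Joint preservation log-likelihood of all lineages.

    ``counts`` is the (n_species, n_preservation_bins) matrix of occurrence
    counts per bin; ``s``/``e`` are the current origination/extinction ages.
    Each lineage's Poisson likelihood is conditioned on >= 1 occurrence over
    its lifespan and marginalized over the discrete gamma categories with
    equal weights.
    """
    counts = np.asarray(counts, dtype=float)
    s = np.asarray(s, dtype=float)
    e = np.asarray(e, dtype=float)
    ov = interval_bin_overlap(e, s, model.edges)  # (S, nb)
    r = ov @ model.q  # expected occurrences at multiplier 1
    if np.any(r <= 0):
        return -np.inf
    k_tot = counts.sum(axis=1)
    log_q_term = counts @ np.log(model.q)
    m = model.multipliers()  # (C,)
    # (S, C): k log m - m r - log(1 - exp(-m r))
    mr = r[:, None] * m[None, :]
    ll = (
        k_tot[:, None] * np.log(m)[None, :]
        - mr
        - _log1mexp(mr)
    )
    marg = logsumexp(ll, axis=1) - np.log(len(m))
    return float(np.sum(marg + log_q_term))


def preservation_loglik(ages, s, e, model: PreservationModel) -> float:
    """Preservation log-likelihood of a single lineage.

    ``ages`` are the (point) occurrence ages, all of which must lie within
    ``[e, s]`` -- the sampler never proposes lifespans excluding an
    occurrence.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if len(ages) < 1:
        raise ValueError("a sampled lineage needs at least one occurrence")
    if np.any(ages > s + 1e-12) or np.any(ages < e - 1e-12):
        raise ValueError("occurrence ages must lie within [e, s]")
    counts = np.array([_bin_counts(ages, model.edges)])
    return preservation_total_loglik(
        counts, np.array([s]), np.array([e]), model
    )


def _bin_counts(ages, edges) -> np.ndarray:
    idx = bin_indices(ages, edges)
    return np.bincount(idx, minlength=len(edges) - 1).astype(float)


def occurrence_count_matrix(dataset, edges) -> np.ndarray:
    """Occurrence counts per (taxon, preservation bin), using point ages."""
    counts = np.zeros((dataset.n_taxa, len(edges) - 1))
    for i, t in enumerate(dataset.taxa):
        counts[i] = _bin_counts(t.ages, edges)
    return counts


def expected_occurrences(s, e, model: PreservationModel) -> float:
    """Expected occurrence count of a lineage at multiplier 1."""
    ov = interval_bin_overlap(np.array([e]), np.array([s]), model.edges)[0]
    return float(ov @ model.q)
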