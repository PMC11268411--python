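"""Post-hoc predictor-effect estimation and importance ranking.

Everything here consumes a :class:`bdnn.mcmc.PosteriorTrace` together with the
predictor tensor used for the fit and re-runs the rate networks, so all
effects are posterior quantities:

* partial dependence (PD): the marginal rate as one predictor sweeps a grid
  while all others keep their observed values, averaged over the
  species-by-time cells, one curve per MCMC sample;
* permutation importance: the drop in birth-death log-likelihood when a
  predictor's values are shuffled (across species for lineage-level
  predictors, across time bins for shared series such as time itself);
* PD posterior rate difference: how often, across MCMC samples, the rate at
  the mean-curve maximum exceeds the rate at its minimum;
* SHAP values: additive per-row attributions of the rate, computed exactly by
  coalition enumeration (small predictor counts) or through a 2-additive
  (pairwise Moebius) approximation;
* consensus ranking: a single ordering aggregated from the three metrics by
  minimizing the summed Spearman footrule displacement (solved exactly as a
  linear assignment).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import forward_baseline
from .data_io import PredictorTensor
from .likelihood import bd_total_loglik
from .mcmc import PosteriorTrace

__all__ = [
    "PDCurve",
    "ShapResult",
    "partial_dependence",
    "pd_fold_change",
    "pd_posterior_difference",
    "permutation_importance",
    "shap_values",
    "consensus_rank",
    "build_importance_table",
]

PredictorName = Union[str, Tuple[str, str]]


# ---------------------------------------------------------------------------
# helpers shared by the metrics


def _sample_indices(n: int, max_samples: Optional[int]) -> np.ndarray:
    if max_samples is None or max_samples >= n:
        return np.arange(n)
    return np.unique(np.linspace(0, n - 1, max_samples).round().astype(int))


def _columns_of(predictors: PredictorTensor, name: str) -> List[int]:
    if name in predictors.groups:
        return list(predictors.groups[name])
    return [predictors.column_index(name)]


def _is_shared_series(predictors: PredictorTensor, name: str) -> bool:
    """True for predictors that vary over time but are identical across
    species (time itself and environmental series)."""
    cols = _columns_of(predictors, name)
    kinds = {predictors.predictor_kinds[c] for c in cols}
    return bool(kinds & {"time", "series"})


def _reg_constants(weights, t_reg, X):
    """Normalizing constants of the regularizer, frozen at the observed grid.

    The fitted model's rate map is ``x -> f(x)**t_reg * E(f)/E(f**t_reg)``
    with the expectations taken over the observed species-by-time cells; when
    probing the model with modified inputs the constants stay fixed, so the
    model itself is held constant.
    """
    base = forward_baseline(weights, X)
    return float(base.mean()), float((base**t_reg).mean())


def _rates_from(weights, t_reg, values, c_num, c_den):
    """Regularized rates on arbitrary predictor rows, model held fixed."""
    flat = values.reshape(-1, values.shape[-1])
    base = forward_baseline(weights, flat).reshape(values.shape[:-1])
    return base**t_reg * (c_num / c_den)


# ---------------------------------------------------------------------------
# partial dependence


@dataclass
class PDCurve:
    """Posterior partial-dependence curve of one predictor (or a pair)."""

    predictor: PredictorName
    grid: List
    samples: np.ndarray  # (n_samples, n_grid) marginal rates

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def ci(self, level: float = 0.95):
        a = (1 - level) / 2
        return (
            np.quantile(self.samples, a, axis=0),
            np.quantile(self.samples, 1 - a, axis=0),
        )


def _grid_for(predictors: PredictorTensor, name: str, n_grid: int):
    """Grid values (in the tensor's standardized space) and the column setter.

    Returns (grid_labels, list of (columns, per-grid-point values)).
    """
    if name in predictors.groups:
        cols = predictors.groups[name]
        states = [predictors.predictor_names[c] for c in cols]
        settings = [np.eye(len(cols))[i] for i in range(len(cols))]
        return states, cols, settings
    c = predictors.column_index(name)
    kind = predictors.predictor_kinds[c]
    observed = predictors.values[:, :, c]
    if kind == "binary":
        grid = [0.0, 1.0]
    elif kind == "time":
        grid = list(np.unique(predictors.values[0, :, c]))
        if len(grid) > n_grid:
            grid = list(np.linspace(min(grid), max(grid), n_grid))
    else:
        lo, hi = float(observed.min()), float(observed.max())
        grid = list(np.linspace(lo, hi, n_grid)) if hi > lo else [lo]
    return grid, [c], [np.array([v]) for v in grid]


def partial_dependence(
    trace: PosteriorTrace,
    predictors: PredictorTensor,
    target: str = "lambda",
    predictor: PredictorName = "time",
    grid=None,
    n_grid: int = 50,
    max_samples: Optional[int] = None,
) -> PDCurve:
    """Marginal effect of one predictor (or an ordered pair) on a rate.

    For every grid value and every posterior sample the predictor is set to
    that value in all (species, bin) cells, rates are recomputed through the
    network and regularizer, and averaged over cells.  One-hot groups are
    swept over their states with the indicator columns toggled jointly.
    """
    if isinstance(predictor, tuple):
        g1, c1, s1 = _grid_for(predictors, predictor[0], int(math.isqrt(n_grid)) + 1)
        g2, c2, s2 = _grid_for(predictors, predictor[1], int(math.isqrt(n_grid)) + 1)
        labels = [(a, b) for a in g1 for b in g2]
        cols = list(c1) + list(c2)
        settings = [np.concatenate([u, v]) for u in s1 for v in s2]
    else:
        labels, cols, settings = _grid_for(predictors, predictor, n_grid)
        if grid is not None:
            labels = list(grid)
            settings = [np.atleast_1d(np.asarray(v, dtype=float)) for v in grid]

    X = predictors.matrix  # (S*B, J)
    G = len(labels)
    stack = np.repeat(X[None, :, :], G, axis=0)
    for g, vals in enumerate(settings):
        stack[g][:, cols] = vals

    idx = _sample_indices(trace.n_samples, max_samples)
    out = np.empty((len(idx), G))
    for row, i in enumerate(idx):
        w = trace.network(target, i)
        c_num, c_den = _reg_constants(w, trace.t_reg[i], X)
        rates = _rates_from(w, trace.t_reg[i], stack, c_num, c_den)
        out[row] = rates.mean(axis=1)
    return PDCurve(predictor, labels, out)


def pd_fold_change(pd: PDCurve) -> float:
    """Ratio of the mean-curve maximum to its minimum (>= 1)."""
    m = pd.mean
    return float(m.max() / m.min())


def pd_posterior_difference(pd: PDCurve) -> float:
    """Fraction of MCMC samples in which the rate at the mean curve's argmax
    exceeds the rate at its argmin; exact ties count half, so a flat curve
    scores 0.5 ('no effect')."""
    if pd.samples.shape[1] < 2:
        raise ValueError("need at least 2 grid points")
    m = pd.mean
    i_max = int(np.argmax(m))
    i_min = int(np.argmin(m))
    hi = pd.samples[:, i_max]
    lo = pd.samples[:, i_min]
    return float(np.mean(hi > lo) + 0.5 * np.mean(hi == lo))


# ---------------------------------------------------------------------------
# permutation importance


def _permuted(values, cols, perm, shared_series: bool):
    out = values.copy()
    if shared_series:
        out[:, :, cols] = out[:, perm, :][:, :, cols]
    else:
        out[:, :, cols] = out[perm, :, :][:, :, cols]
    return out


def _bd_loglik_of(trace, i, lam, mu):
    return bd_total_loglik(
        trace.s[i], trace.e[i], lam, mu, trace.bin_edges, trace.extant
    )


def _single_drop(trace, predictors, name, target, perms, idx):
    cols = _columns_of(predictors, name)
    shared = _is_shared_series(predictors, name)
    drops = []
    for i in idx:
        w = trace.network(target, i)
        c_num, c_den = _reg_constants(w, trace.t_reg[i], predictors.matrix)
        ll0 = _bd_loglik_of(trace, i, trace.lam[i], trace.mu[i])
        for perm in perms[name]:
            vals = _permuted(predictors.values, cols, perm, shared)
            rates = _rates_from(
                w, trace.t_reg[i], vals.reshape(1, -1, vals.shape[-1]), c_num, c_den
            )
            rates = rates.reshape(vals.shape[0], vals.shape[1])
            lam, mu = (rates, trace.mu[i]) if target == "lambda" else (trace.lam[i], rates)
            drops.append(ll0 - _bd_loglik_of(trace, i, lam, mu))
    return float(np.mean(drops))


def permutation_importance(
    trace: PosteriorTrace,
    dataset,
    predictors: PredictorTensor,
    predictor: PredictorName,
    target: str = "lambda",
    n_permutations: int = 10,
    max_samples: Optional[int] = 20,
    seed: int = 0,
) -> float:
    """Mean decrease in birth-death log-likelihood after permutation.

    Lineage-level predictors are shuffled across species (one-hot groups as a
    block, constant within a species' time rows); predictors shared by all
    species (time, environmental series) are shuffled across time bins.  For
    a pair the score is the joint-permutation drop minus the two single
    drops, i.e. the interaction surplus.
    """
    rng = np.random.default_rng(seed)
    S, B, _ = predictors.values.shape
    idx = _sample_indices(trace.n_samples, max_samples)
    names = list(predictor) if isinstance(predictor, tuple) else [predictor]
    perms = {
        n: [
            rng.permutation(B if _is_shared_series(predictors, n) else S)
            for _ in range(n_permutations)
        ]
        for n in names
    }
    if not isinstance(predictor, tuple):
        return _single_drop(trace, predictors, predictor, target, perms, idx)

    a, b = predictor
    drop_a = _single_drop(trace, predictors, a, target, perms, idx)
    drop_b = _single_drop(trace, predictors, b, target, perms, idx)
    cols_a, cols_b = _columns_of(predictors, a), _columns_of(predictors, b)
    shared_a, shared_b = (_is_shared_series(predictors, n) for n in (a, b))
    joint = []
    for i in idx:
        w = trace.network(target, i)
        c_num, c_den = _reg_constants(w, trace.t_reg[i], predictors.matrix)
        ll0 = _bd_loglik_of(trace, i, trace.lam[i], trace.mu[i])
        for pa, pb in zip(perms[a], perms[b]):
            vals = _permuted(predictors.values, cols_a, pa, shared_a)
            vals = _permuted(vals, cols_b, pb, shared_b)
            rates = _rates_from(
                w, trace.t_reg[i], vals.reshape(1, -1, vals.shape[-1]), c_num, c_den
            )
            rates = rates.reshape(S, B)
            lam, mu = (rates, trace.mu[i]) if target == "lambda" else (trace.lam[i], rates)
            joint.append(ll0 - _bd_loglik_of(trace, i, lam, mu))
    return float(np.mean(joint) - drop_a - drop_b)


# ---------------------------------------------------------------------------
# SHAP values


@dataclass
class ShapResult:
    """Additive per-row attributions of the model rate.

    ``base + phi.sum(axis=1)`` equals the model rate for every row (local
    accuracy).  ``interactions[j, k]`` holds the mean |pairwise Moebius mass|
    (kernel method only), the interaction analogue used for pair ranking.
    """

    predictor_names: List[str]
    rows: np.ndarray
    phi: np.ndarray  # (n_rows, J)
    base: np.ndarray  # (n_rows,)
    rates: np.ndarray  # (n_rows,)
    interactions: Optional[np.ndarray] = None

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.phi).mean(axis=0)


def _coalition_values(f, rows_x, background, masks):
    """v(S) = E_background f(x_S, b_notS) for every row and coalition mask."""
    n_rows, J = rows_x.shape
    n_bg = background.shape[0]
    n_coal = masks.shape[0]
    # (rows, coal, bg, J)
    x = np.broadcast_to(rows_x[:, None, None, :], (n_rows, n_coal, n_bg, J))
    b = np.broadcast_to(background[None, None, :, :], (n_rows, n_coal, n_bg, J))
    m = np.broadcast_to(masks[None, :, None, :], (n_rows, n_coal, n_bg, J))
    inputs = np.where(m, x, b).reshape(-1, J)
    vals = f(inputs).reshape(n_rows, n_coal, n_bg)
    return vals.mean(axis=2)


def _exact_shapley(v, masks, J):
    """Shapley values from the full 2^J coalition table."""
    sizes = masks.sum(axis=1)
    fact = np.array([math.factorial(i) for i in range(J + 1)], dtype=float)
    lookup = {tuple(m): i for i, m in enumerate(masks.astype(int))}
    n_rows = v.shape[0]
    phi = np.zeros((n_rows, J))
    for i, m in enumerate(masks.astype(bool)):
        sz = int(sizes[i])
        for j in range(J):
            if m[j]:
                continue
            w = fact[sz] * fact[J - sz - 1] / fact[J]
            m2 = m.copy()
            m2[j] = True
            i2 = lookup[tuple(m2.astype(int))]
            phi[:, j] += w * (v[:, i2] - v[:, i])
    return phi


def shap_values(
    trace: PosteriorTrace,
    predictors: PredictorTensor,
    target: str = "lambda",
    method: str = "kernel",
    rows: Optional[np.ndarray] = None,
    n_rows: int = 50,
    background_size: int = 100,
    max_samples: Optional[int] = 10,
    kappa: int = 2,
    seed: int = 0,
) -> ShapResult:
    """Per-(species, bin, predictor) rate attributions, posterior-averaged.

    ``method='exact'`` enumerates all 2^J coalitions (J <= 12) and yields the
    exact Shapley values under the marginal-expectation value function
    (absent predictors are imputed from a random background of observed
    rows).  ``method='kernel'`` evaluates only the empty, singleton and pair
    coalitions and reconstructs attributions from the resulting kappa=2
    (pairwise) Moebius representation; the efficiency residual is spread
    proportionally to |phi| so that dummy predictors keep an attribution of
    exactly zero while local accuracy is preserved.
    """
    X = predictors.matrix
    J = X.shape[1]
    if kappa > J:
        raise ValueError(f"kappa={kappa} exceeds the {J} available predictors")
    if method == "exact" and J > 12:
        raise ValueError("exact enumeration is limited to J <= 12 predictors")
    if method not in ("exact", "kernel"):
        raise ValueError("method must be 'exact' or 'kernel'")
    rng = np.random.default_rng(seed)
    if rows is None:
        rows = rng.choice(X.shape[0], size=min(n_rows, X.shape[0]), replace=False)
    rows = np.asarray(rows)
    rows_x = X[rows]
    background = X[rng.choice(X.shape[0], size=min(background_size, X.shape[0]), replace=False)]

    if method == "exact":
        masks = np.array(list(itertools.product([0, 1], repeat=J)), dtype=bool)
    else:
        masks = [np.zeros(J, dtype=bool)]
        for j in range(J):
            m = np.zeros(J, dtype=bool)
            m[j] = True
            masks.append(m)
        pair_index = {}
        for j, k in itertools.combinations(range(J), 2):
            m = np.zeros(J, dtype=bool)
            m[[j, k]] = True
            pair_index[(j, k)] = len(masks)
            masks.append(m)
        masks = np.array(masks)

    idx = _sample_indices(trace.n_samples, max_samples)
    phi_acc = np.zeros((len(rows), J))
    base_acc = np.zeros(len(rows))
    rate_acc = np.zeros(len(rows))
    inter_acc = np.zeros((J, J)) if method == "kernel" else None

    for i in idx:
        w = trace.network(target, i)
        t_reg = trace.t_reg[i]
        base_grid = forward_baseline(w, X)
        c_num = base_grid.mean()
        c_den = (base_grid**t_reg).mean()

        def f(rows_in):
            b = forward_baseline(w, rows_in)
            return b**t_reg * (c_num / c_den)

        v = _coalition_values(f, rows_x, background, masks)
        fx = f(rows_x)
        v0 = v[:, 0]
        if method == "exact":
            phi = _exact_shapley(v, masks, J)
            # efficiency holds against v(N) = f(x); base + sum(phi) = f(x)
            base = fx - phi.sum(axis=1)
        else:
            m1 = v[:, 1 : 1 + J] - v0[:, None]  # (rows, J)
            m2 = np.zeros((len(rows), J, J))
            for (j, k), ci in pair_index.items():
                mjk = v[:, ci] - v[:, 1 + j] - v[:, 1 + k] + v0
                m2[:, j, k] = m2[:, k, j] = mjk
            phi = m1 + 0.5 * m2.sum(axis=2)
            resid = (fx - v0) - phi.sum(axis=1)
            absw = np.abs(phi)
            tot = absw.sum(axis=1)
            uniform = np.full(J, 1.0 / J)
            shares = np.where(
                tot[:, None] > 1e-12, absw / np.maximum(tot[:, None], 1e-300), uniform
            )
            phi = phi + resid[:, None] * shares
            base = v0
            inter_acc += np.abs(m2).mean(axis=0)
        phi_acc += phi
        base_acc += base
        rate_acc += fx

    n = len(idx)
    return ShapResult(
        list(predictors.predictor_names),
        rows,
        phi_acc / n,
        base_acc / n,
        rate_acc / n,
        None if inter_acc is None else inter_acc / n,
    )


# ---------------------------------------------------------------------------
# consensus ranking


def consensus_rank(importance: pd.DataFrame) -> List[str]:
    """Aggregate metric-wise rankings into one ordering (footrule median).

    ``importance`` holds one row per predictor and one column per metric,
    larger = more important.  The consensus minimizes the summed Spearman
    footrule displacement to the metric rankings, solved exactly as a linear
    assignment; ties are broken by mean rank, then by name.
    """
    if importance.shape[1] < 1:
        raise ValueError("need at least one metric column")
    ranks = importance.rank(ascending=False, method="average")
    n = len(importance)
    mean_rank = ranks.mean(axis=1).to_numpy()
    positions = np.arange(1, n + 1)
    cost = np.abs(ranks.to_numpy()[:, :, None] - positions[None, None, :]).sum(axis=1)
    # deterministic tie-breaks: prefer low mean rank, then table order (name)
    cost = cost + 1e-7 * positions[None, :] * mean_rank[:, None]
    cost = cost + 1e-10 * positions[None, :] * np.arange(n)[:, None]
    row, col = linear_sum_assignment(cost)
    order = np.empty(n, dtype=int)
    order[col] = row
    return [importance.index[i] for i in order]


def build_importance_table(
    trace: PosteriorTrace,
    dataset,
    predictors: PredictorTensor,
    target: str = "lambda",
    n_grid: int = 20,
    n_permutations: int = 5,
    max_samples: Optional[int] = 10,
    n_shap_rows: int = 40,
    background_size: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-predictor importance metrics and their consensus ranking.

    Individual predictors only (one-hot groups collapse to the group); pair
    interactions are ranked separately via :func:`permutation_importance`
    with a tuple argument and the SHAP interaction masses.
    """
    names = _rankable_predictors(predictors)
    perm = {
        n: permutation_importance(
            trace,
            dataset,
            predictors,
            n,
            target=target,
            n_permutations=n_permutations,
            max_samples=max_samples,
            seed=seed,
        )
        for n in names
    }
    pdprob = {}
    for n in names:
        curve = partial_dependence(
            trace, predictors, target, n, n_grid=n_grid, max_samples=max_samples
        )
        pdprob[n] = pd_posterior_difference(curve) if len(curve.grid) > 1 else 0.5
    shap = shap_values(
        trace,
        predictors,
        target=target,
        method="kernel" if predictors.n_predictors > 12 else "exact",
        n_rows=n_shap_rows,
        background_size=background_size,
        max_samples=max_samples,
        seed=seed,
    )
    mean_abs = shap.mean_abs()
    shap_score = {
        n: float(sum(mean_abs[c] for c in _columns_of(predictors, n))) for n in names
    }
    table = pd.DataFrame(
        {
            "permutation": pd.Series(perm),
            "pd_probability": pd.Series(pdprob),
            "mean_abs_shap": pd.Series(shap_score),
        }
    )
    order = consensus_rank(table)
    table["consensus_rank"] = pd.Series(
        {name: i + 1 for i, name in enumerate(order)}
    )
    return table.sort_values("consensus_rank")


def _rankable_predictors(predictors: PredictorTensor) -> List[str]:
    names = []
    grouped = {c for cols in predictors.groups.values() for c in cols}
    for j, n in enumerate(predictors.predictor_names):
        if j not in grouped:
            names.append(n)
    names.extend(predictors.groups.keys())
    return names
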