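"""Metropolis-Hastings sampler for the birth-death neural network model.

The sampled state consists of the two networks' weights, the shared
regularizer ``t_reg``, every taxon's origination and extinction ages, and the
preservation parameters (per-bin baseline rates ``q`` and the gamma
heterogeneity shape ``alpha``).  Priors: standard normal on every weight, a
truncated Exp(1) on ``t_reg`` over [0, 1] (placing most prior mass on the
constant-rate end), and Exp(1) on each preservation parameter.

Proposals are simple symmetric kernels (normal jitter on a small random
subset of one network's weights, sliding windows on times and ``t_reg`` with
reflection at the boundaries) plus log-multiplier moves on ``q``/``alpha``
whose Hastings ratio is ``log m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    BDNNParams,
    DEFAULT_HIDDEN,
    NetworkWeights,
    forward_baseline,
    regularize_rates,
)
from .data_io import (
    OccurrenceDataset,
    PredictorTensor,
    build_predictor_tensor,
    phylo_eigenvectors,
)
from .likelihood import (
    PreservationModel,
    bd_total_loglik,
    bin_indices,
    occurrence_count_matrix,
    preservation_total_loglik,
)

__all__ = [
    "MCMCConfig",
    "PosteriorTrace",
    "ProposalContext",
    "log_prior",
    "propose",
    "run_mcmc",
    "fit_bdnn",
    "save_trace",
    "load_trace",
]

LOG_TRUNC_EXP1 = -math.log1p(-math.exp(-1.0))  # normalizer of Exp(1) on [0, 1]


@dataclass
class MCMCConfig:
    """Sampler settings; defaults are desk-scale, not publication-scale."""

    n_iterations: int = 100_000
    sampling_freq: int = 100
    burnin_fraction: float = 0.25
    seed: int = 0
    hidden_layers: Tuple[int, int] = DEFAULT_HIDDEN
    use_bias: bool = True
    n_preservation_bins: int = 5
    gamma_categories: int = 4
    # proposal scales
    scale_weights: float = 0.15
    weight_update_fraction: float = 0.05
    scale_times: float = 0.5
    # taxa moved per time proposal: a small fixed block keeps the joint
    # acceptance probability workable regardless of dataset size
    time_updates_per_move: int = 2
    scale_q: float = 1.2  # window width of the log-multiplier
    scale_treg: float = 0.1
    # probabilities of the update blocks: times, weights, preservation, t_reg
    update_mix: Tuple[float, float, float, float] = (0.40, 0.40, 0.15, 0.05)
    init_weight_scale: float = 0.1
    prior_only: bool = False
    regularization_mask: str = "all"  # or "alive": restrict E() to lifespans

    def __post_init__(self):
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must lie in [0, 1)")
        if abs(sum(self.update_mix) - 1.0) > 1e-9:
            raise ValueError("update_mix must sum to 1")
        if self.regularization_mask not in ("all", "alive"):
            raise ValueError("regularization_mask must be 'all' or 'alive'")


@dataclass
class ProposalContext:
    """Hard constraints for time moves: each taxon's sampled lifespan must
    bracket all of its occurrences and stay inside the rate grid."""

    max_occ: np.ndarray
    min_occ: np.ndarray
    extant: np.ndarray
    s_upper: float


def log_prior(params: BDNNParams) -> float:
    """Joint log-prior: N(0,1) weights, truncated Exp(1) t_reg, Exp(1) q/alpha."""
    if not 0.0 <= params.t_reg <= 1.0:
        return -np.inf
    total = _log_prior_weights(params.weights_lambda)
    total += _log_prior_weights(params.weights_mu)
    total += _log_prior_treg(params.t_reg)
    total += _log_prior_preservation(params.q, params.alpha)
    return float(total)


def _log_prior_weights(w: NetworkWeights) -> float:
    flat = w.to_flat()
    return float(-0.5 * np.sum(flat**2) - 0.5 * flat.size * math.log(2 * math.pi))


def _log_prior_treg(t: float) -> float:
    if not 0.0 <= t <= 1.0:
        return -np.inf
    return -t + LOG_TRUNC_EXP1


def _log_prior_preservation(q, alpha) -> float:
    total = 0.0
    if q is not None:
        if np.any(np.asarray(q) <= 0):
            return -np.inf
        total -= float(np.sum(q))
    if alpha is not None:
        if alpha <= 0:
            return -np.inf
        total -= float(alpha)
    return total


def _reflect(x: np.ndarray, lo, hi) -> np.ndarray:
    """Fold values into [lo, hi]; symmetric for sliding-window proposals."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    span = hi - lo
    out = np.where(span <= 0, lo, x)
    with np.errstate(invalid="ignore", divide="ignore"):
        period = np.where(span > 0, 2 * span, 1.0)
        y = np.mod(out - lo, period)
        y = np.where(y > span, period - y, y)
    return np.where(span > 0, lo + y, lo)


def propose(
    params: BDNNParams,
    config: MCMCConfig,
    rng: np.random.Generator,
    context: Optional[ProposalContext] = None,
) -> Tuple[BDNNParams, float, str]:
    """Draw one update block; returns (new state, log Hastings ratio, block).

    Blocks: ``times`` (sliding windows on s/e respecting each taxon's
    occurrence bracket), ``weights_lambda``/``weights_mu`` (normal jitter on a
    random subset of one layer), ``q``/``alpha`` (log multiplier), ``t_reg``
    (window reflected into [0, 1]).
    """
    u = rng.random()
    mix = np.cumsum(config.update_mix)
    new = params.copy()
    if u < mix[0] and params.s is not None and context is not None:
        return _propose_times(new, config, rng, context)
    if u < mix[1] or params.s is None or context is None:
        return _propose_weights(new, config, rng)
    if u < mix[2] and params.q is not None:
        return _propose_preservation(new, config, rng)
    return _propose_treg(new, config, rng)


def _propose_weights(new, config, rng):
    which = "weights_lambda" if rng.random() < 0.5 else "weights_mu"
    w = getattr(new, which)
    layer = [w.w1, w.w2, w.w3][rng.integers(3)]
    flat = layer.ravel()
    n_upd = max(1, int(round(config.weight_update_fraction * flat.size)))
    idx = rng.choice(flat.size, size=min(n_upd, flat.size), replace=False)
    flat[idx] += rng.normal(0.0, 1.0, len(idx)) * config.scale_weights
    return new, 0.0, which


def _propose_times(new, config, rng, ctx):
    n = len(new.s)
    n_upd = max(1, int(config.time_updates_per_move))
    idx = rng.choice(n, size=min(n_upd, n), replace=False)
    d = config.scale_times
    s_new = new.s[idx] + rng.uniform(-d, d, len(idx))
    s_new = _reflect(s_new, ctx.max_occ[idx], ctx.s_upper)
    e_new = new.e[idx].copy()
    ext = ~ctx.extant[idx]
    if np.any(ext):
        prop = new.e[idx][ext] + rng.uniform(-d, d, int(ext.sum()))
        e_new[ext] = _reflect(prop, 0.0, ctx.min_occ[idx][ext])
    ok = s_new > e_new
    new.s[idx[ok]] = s_new[ok]
    new.e[idx[ok]] = e_new[ok]
    return new, 0.0, "times"


def _propose_preservation(new, config, rng):
    m = math.exp(config.scale_q * (rng.random() - 0.5))
    if rng.random() < 0.5 or new.alpha is None:
        j = rng.integers(len(new.q))
        new.q[j] *= m
        return new, math.log(m), "q"
    new.alpha *= m
    return new, math.log(m), "alpha"


def _propose_treg(new, config, rng):
    t = new.t_reg + rng.uniform(-config.scale_treg, config.scale_treg)
    new.t_reg = float(_reflect(np.array([t]), 0.0, 1.0)[0])
    return new, 0.0, "t_reg"


# ---------------------------------------------------------------------------
# posterior trace


@dataclass
class PosteriorTrace:
    """Thinned posterior samples plus the derived lineage-time rate matrices."""

    species: List[str]
    bin_edges: np.ndarray
    extant: np.ndarray
    t_reg: np.ndarray  # (n,)
    alpha: np.ndarray  # (n,)
    q: np.ndarray  # (n, n_prez_bins)
    s: np.ndarray  # (n, S)
    e: np.ndarray  # (n, S)
    lam: np.ndarray  # (n, S, B)
    mu: np.ndarray  # (n, S, B)
    log_posterior: np.ndarray
    log_lik_bd: np.ndarray
    log_lik_prez: np.ndarray
    weights_lambda: np.ndarray  # (n, n_weights) flattened
    weights_mu: np.ndarray
    n_predictors: int
    hidden_layers: Tuple[int, int]
    use_bias: bool
    prez_edges: np.ndarray
    acceptance: Dict[str, float] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.t_reg)

    def network(self, target: str, i: int) -> NetworkWeights:
        flat = {"lambda": self.weights_lambda, "mu": self.weights_mu}[target][i]
        return NetworkWeights.from_flat(
            flat, self.n_predictors, self.hidden_layers, self.use_bias
        )

    def posterior_mean_rates(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.lam.mean(axis=0), self.mu.mean(axis=0)

    def rate_ci(self, target: str = "lambda", level: float = 0.95):
        arr = self.lam if target == "lambda" else self.mu
        a = (1 - level) / 2
        return np.quantile(arr, a, axis=0), np.quantile(arr, 1 - a, axis=0)

    def rates_at_event_times(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-sample speciation rate at each lineage's sampled origination
        and extinction rate at its sampled extinction (age 0 for extant)."""
        n, S = self.s.shape
        lam_ev = np.empty((n, S))
        mu_ev = np.empty((n, S))
        rows = np.arange(S)
        for i in range(n):
            lam_ev[i] = self.lam[i, rows, bin_indices(self.s[i], self.bin_edges)]
            mu_ev[i] = self.mu[i, rows, bin_indices(self.e[i], self.bin_edges)]
        return lam_ev, mu_ev


# ---------------------------------------------------------------------------
# main sampler


def _alive_mask(s, e, edges):
    from .likelihood import interval_bin_overlap

    return interval_bin_overlap(e, s, edges) > 0


def run_mcmc(
    dataset: OccurrenceDataset,
    predictors: PredictorTensor,
    config: Optional[MCMCConfig] = None,
) -> PosteriorTrace:
    """Sample the joint posterior of the BDNN model.

    Targets prior x birth-death likelihood x preservation likelihood; with
    ``config.prior_only`` both likelihood terms are dropped, which is useful
    to validate the proposal machinery against the known priors.  Reproducible
    bit-for-bit given ``config.seed``.
    """
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)
    edges = predictors.bin_edges
    S, B, J = predictors.values.shape
    if S != dataset.n_taxa:
        raise ValueError("predictor tensor does not match the dataset")
    X = predictors.matrix

    extant = np.array([t.extant for t in dataset.taxa])
    max_occ = np.array([t.ages.max() for t in dataset.taxa])
    min_occ = np.array([t.ages.min() for t in dataset.taxa])
    s_upper = float(edges[0])
    if np.any(max_occ > s_upper + 1e-9):
        raise ValueError("time bins do not cover the oldest occurrence")
    ctx = ProposalContext(max_occ, min_occ, extant, s_upper)

    prez_edges = np.linspace(s_upper, 0.0, config.n_preservation_bins + 1)
    counts = occurrence_count_matrix(dataset, prez_edges)

    # initialization near the prior bulk, guaranteed-finite
    init_scale = config.init_weight_scale
    for attempt in range(10):
        params = BDNNParams(
            weights_lambda=NetworkWeights.random(
                J, config.hidden_layers, config.use_bias, rng, init_scale
            ),
            weights_mu=NetworkWeights.random(
                J, config.hidden_layers, config.use_bias, rng, init_scale
            ),
            t_reg=0.5,
            s=np.minimum(max_occ + 0.01, s_upper),
            e=np.where(extant, 0.0, np.maximum(min_occ - 0.01, 0.0)),
            q=np.ones(config.n_preservation_bins),
            alpha=1.0,
        )
        bad = ~(params.s > params.e)
        params.s[bad] = np.minimum(params.e[bad] + 0.005, s_upper)
        state = _State.compute(params, X, S, B, counts, prez_edges, edges, extant, config)
        if np.isfinite(state.log_posterior):
            break
        init_scale *= 0.5
    else:
        raise RuntimeError("could not find a finite starting state")

    burnin_iter = int(config.burnin_fraction * config.n_iterations)
    n_samples = (config.n_iterations - burnin_iter) // config.sampling_freq

    rec = _Recorder(n_samples, S, B, params, config)
    tries: Dict[str, int] = {}
    accepts: Dict[str, int] = {}

    for it in range(config.n_iterations):
        proposal, log_h, block = propose(params, config, rng, ctx)
        new_state = state.update(
            proposal, block, X, S, B, counts, prez_edges, edges, extant, config
        )
        tries[block] = tries.get(block, 0) + 1
        delta = new_state.log_posterior - state.log_posterior + log_h
        if np.isfinite(new_state.log_posterior) and math.log(rng.random()) < delta:
            params, state = proposal, new_state
            accepts[block] = accepts.get(block, 0) + 1
        if it >= burnin_iter and (it - burnin_iter) % config.sampling_freq == (
            config.sampling_freq - 1
        ):
            rec.record(params, state)

    acceptance = {k: accepts.get(k, 0) / v for k, v in tries.items()}
    return rec.build(
        dataset.names, edges, extant, prez_edges, J, config, acceptance
    )


@dataclass
class _State:
    """Cached likelihood/prior pieces of the current parameter state."""

    lam_b: np.ndarray
    mu_b: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    ll_bd: float
    ll_prez: float
    lp_w_lam: float
    lp_w_mu: float
    lp_treg: float
    lp_prez: float

    @property
    def log_posterior(self) -> float:
        return (
            self.ll_bd
            + self.ll_prez
            + self.lp_w_lam
            + self.lp_w_mu
            + self.lp_treg
            + self.lp_prez
        )

    @classmethod
    def compute(cls, p, X, S, B, counts, prez_edges, edges, extant, config):
        lam_b = forward_baseline(p.weights_lambda, X).reshape(S, B)
        mu_b = forward_baseline(p.weights_mu, X).reshape(S, B)
        mask = _alive_mask(p.s, p.e, edges) if config.regularization_mask == "alive" else None
        lam = regularize_rates(lam_b, p.t_reg, mask=mask)
        mu = regularize_rates(mu_b, p.t_reg, mask=mask)
        ll_bd, ll_prez = cls._likelihoods(
            p, lam, mu, counts, prez_edges, edges, extant, config
        )
        return cls(
            lam_b,
            mu_b,
            lam,
            mu,
            ll_bd,
            ll_prez,
            _log_prior_weights(p.weights_lambda),
            _log_prior_weights(p.weights_mu),
            _log_prior_treg(p.t_reg),
            _log_prior_preservation(p.q, p.alpha),
        )

    @staticmethod
    def _likelihoods(p, lam, mu, counts, prez_edges, edges, extant, config):
        if config.prior_only:
            return 0.0, 0.0
        ll_bd = bd_total_loglik(p.s, p.e, lam, mu, edges, extant)
        model = PreservationModel(
            p.q, prez_edges, p.alpha, config.gamma_categories
        )
        ll_prez = preservation_total_loglik(counts, p.s, p.e, model)
        return ll_bd, ll_prez

    def update(self, p, block, X, S, B, counts, prez_edges, edges, extant, config):
        """Recompute only the pieces the proposal block touched."""
        if config.regularization_mask == "alive":
            # the averaging mask couples rates to lifespans: full recompute
            return _State.compute(p, X, S, B, counts, prez_edges, edges, extant, config)
        new = replace(self)
        if block in ("weights_lambda", "weights_mu"):
            if block == "weights_lambda":
                new.lam_b = forward_baseline(p.weights_lambda, X).reshape(S, B)
                new.lam = regularize_rates(new.lam_b, p.t_reg)
                new.lp_w_lam = _log_prior_weights(p.weights_lambda)
            else:
                new.mu_b = forward_baseline(p.weights_mu, X).reshape(S, B)
                new.mu = regularize_rates(new.mu_b, p.t_reg)
                new.lp_w_mu = _log_prior_weights(p.weights_mu)
            if not config.prior_only:
                new.ll_bd = bd_total_loglik(p.s, p.e, new.lam, new.mu, edges, extant)
        elif block == "t_reg":
            new.lam = regularize_rates(self.lam_b, p.t_reg)
            new.mu = regularize_rates(self.mu_b, p.t_reg)
            new.lp_treg = _log_prior_treg(p.t_reg)
            if not config.prior_only:
                new.ll_bd = bd_total_loglik(p.s, p.e, new.lam, new.mu, edges, extant)
        elif block == "times":
            if not config.prior_only:
                new.ll_bd = bd_total_loglik(p.s, p.e, self.lam, self.mu, edges, extant)
                model = PreservationModel(
                    p.q, prez_edges, p.alpha, config.gamma_categories
                )
                new.ll_prez = preservation_total_loglik(counts, p.s, p.e, model)
        elif block in ("q", "alpha"):
            new.lp_prez = _log_prior_preservation(p.q, p.alpha)
            if not config.prior_only and np.isfinite(new.lp_prez):
                model = PreservationModel(
                    p.q, prez_edges, p.alpha, config.gamma_categories
                )
                new.ll_prez = preservation_total_loglik(counts, p.s, p.e, model)
        else:  # pragma: no cover
            raise ValueError(f"unknown block {block}")
        return new


class _Recorder:
    def __init__(self, n_samples, S, B, params, config):
        nq = len(params.q)
        nw_l = params.weights_lambda.n_weights
        nw_m = params.weights_mu.n_weights
        self.i = 0
        self.t_reg = np.empty(n_samples)
        self.alpha = np.empty(n_samples)
        self.q = np.empty((n_samples, nq))
        self.s = np.empty((n_samples, S))
        self.e = np.empty((n_samples, S))
        self.lam = np.empty((n_samples, S, B))
        self.mu = np.empty((n_samples, S, B))
        self.log_posterior = np.empty(n_samples)
        self.ll_bd = np.empty(n_samples)
        self.ll_prez = np.empty(n_samples)
        self.w_lam = np.empty((n_samples, nw_l))
        self.w_mu = np.empty((n_samples, nw_m))

    def record(self, params, state):
        i = self.i
        self.t_reg[i] = params.t_reg
        self.alpha[i] = params.alpha
        self.q[i] = params.q
        self.s[i] = params.s
        self.e[i] = params.e
        self.lam[i] = state.lam
        self.mu[i] = state.mu
        self.log_posterior[i] = state.log_posterior
        self.ll_bd[i] = state.ll_bd
        self.ll_prez[i] = state.ll_prez
        self.w_lam[i] = params.weights_lambda.to_flat()
        self.w_mu[i] = params.weights_mu.to_flat()
        self.i += 1

    def build(self, species, edges, extant, prez_edges, J, config, acceptance):
        return PosteriorTrace(
            species=list(species),
            bin_edges=np.asarray(edges, dtype=float),
            extant=extant,
            t_reg=self.t_reg,
            alpha=self.alpha,
            q=self.q,
            s=self.s,
            e=self.e,
            lam=self.lam,
            mu=self.mu,
            log_posterior=self.log_posterior,
            log_lik_bd=self.ll_bd,
            log_lik_prez=self.ll_prez,
            weights_lambda=self.w_lam,
            weights_mu=self.w_mu,
            n_predictors=J,
            hidden_layers=tuple(config.hidden_layers),
            use_bias=config.use_bias,
            prez_edges=prez_edges,
            acceptance=acceptance,
        )


# ---------------------------------------------------------------------------
# convenience pipeline and trace persistence


def fit_bdnn(
    dataset: OccurrenceDataset,
    traits=None,
    time_series=None,
    tree=None,
    eigenvectors=None,
    n_eigenvectors: int = 2,
    time_bins=None,
    categorical=(),
    config: Optional[MCMCConfig] = None,
):
    """Assemble the predictor tensor and run the sampler; returns
    ``(trace, predictors)``."""
    if tree is not None and eigenvectors is None:
        eigenvectors = phylo_eigenvectors(tree, n_eigenvectors)
    predictors = build_predictor_tensor(
        dataset,
        traits=traits,
        time_series=time_series,
        eigenvectors=eigenvectors,
        time_bins=time_bins,
        categorical=categorical,
    )
    trace = run_mcmc(dataset, predictors, config)
    return trace, predictors


def save_trace(trace: PosteriorTrace, prefix: str) -> None:
    """Write ``PREFIX.trace.tsv`` (scalar samples), ``PREFIX.rates.tsv``
    (posterior mean and 95% CI per species-bin) and ``PREFIX.trace.npz``
    (full arrays, for reloading)."""
    scalars = pd.DataFrame(
        {
            "sample": np.arange(trace.n_samples),
            "log_posterior": trace.log_posterior,
            "log_lik_bd": trace.log_lik_bd,
            "log_lik_prez": trace.log_lik_prez,
            "t_reg": trace.t_reg,
            "alpha": trace.alpha,
        }
    )
    for j in range(trace.q.shape[1]):
        scalars[f"q_{j}"] = trace.q[:, j]
    scalars.to_csv(f"{prefix}.trace.tsv", sep="\t", index=False)

    lam_mean, mu_mean = trace.posterior_mean_rates()
    lam_lo, lam_hi = trace.rate_ci("lambda")
    mu_lo, mu_hi = trace.rate_ci("mu")
    mids = (trace.bin_edges[:-1] + trace.bin_edges[1:]) / 2
    rows = []
    for i, sp in enumerate(trace.species):
        for b, mid in enumerate(mids):
            rows.append(
                (
                    sp,
                    mid,
                    lam_mean[i, b],
                    lam_lo[i, b],
                    lam_hi[i, b],
                    mu_mean[i, b],
                    mu_lo[i, b],
                    mu_hi[i, b],
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "species",
            "bin_mid_age",
            "lambda_mean",
            "lambda_lo",
            "lambda_hi",
            "mu_mean",
            "mu_lo",
            "mu_hi",
        ],
    ).to_csv(f"{prefix}.rates.tsv", sep="\t", index=False)

    np.savez_compressed(
        f"{prefix}.trace.npz",
        species=np.array(trace.species),
        bin_edges=trace.bin_edges,
        extant=trace.extant,
        t_reg=trace.t_reg,
        alpha=trace.alpha,
        q=trace.q,
        s=trace.s,
        e=trace.e,
        lam=trace.lam,
        mu=trace.mu,
        log_posterior=trace.log_posterior,
        log_lik_bd=trace.log_lik_bd,
        log_lik_prez=trace.log_lik_prez,
        weights_lambda=trace.weights_lambda,
        weights_mu=trace.weights_mu,
        n_predictors=trace.n_predictors,
        hidden_layers=np.array(trace.hidden_layers),
        use_bias=trace.use_bias,
        prez_edges=trace.prez_edges,
    )


def load_trace(prefix: str) -> PosteriorTrace:
    z = np.load(f"{prefix}.trace.npz", allow_pickle=False)
    return PosteriorTrace(
        species=[str(s) for s in z["species"]],
        bin_edges=z["bin_edges"],
        extant=z["extant"],
        t_reg=z["t_reg"],
        alpha=z["alpha"],
        q=z["q"],
        s=z["s"],
        e=z["e"],
        lam=z["lam"],
        mu=z["mu"],
        log_posterior=z["log_posterior"],
        log_lik_bd=z["log_lik_bd"],
        log_lik_prez=z["log_lik_prez"],
        weights_lambda=z["weights_lambda"],
        weights_mu=z["weights_mu"],
        n_predictors=int(z["n_predictors"]),
        hidden_layers=tuple(int(x) for x in z["hidden_layers"]),
        use_bias=bool(z["use_bias"]),
        prez_edges=z["prez_edges"],
    )
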