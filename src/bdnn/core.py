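"""Deterministic forward computation of lineage-time-specific birth-death rates.

A small feed-forward network maps each predictor row ``x(i, t)`` (time, traits,
phylogenetic eigenvectors, environmental series) to a strictly positive
baseline rate.  Two independent networks with identical architecture emit
speciation and extinction baselines, which are then shrunk toward their grand
mean by a single regularizing parameter ``t_reg`` shared between the two rate
types: ``t_reg = 0`` collapses the model to constant rates, ``t_reg = 1``
leaves the network output untouched, and the transform never changes the mean
rate across the species-by-time grid.

The network is never trained by gradient descent; its weights are sampled by
MCMC (see :mod:`bdnn.mcmc`), so everything here is a pure function of the
current parameter state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "NetworkWeights",
    "BDNNParams",
    "activation_tanh",
    "activation_softplus",
    "forward_baseline",
    "regularize_rates",
    "lineage_time_rates",
]

DEFAULT_HIDDEN = (16, 8)


def activation_tanh(z):
    """Hyperbolic tangent activation, the identity ``1 - 2 / (exp(2z) + 1)``."""
    return np.tanh(z)


def activation_softplus(z):
    """Softplus ``log(exp(z) + 1)``, overflow-safe for large ``|z|``.

    Implemented as ``logaddexp(0, z)`` so that ``softplus(50) ~= 50`` and
    ``softplus(-50) ~= exp(-50)`` without intermediate overflow.
    """
    return np.logaddexp(0.0, z)


@dataclass
class NetworkWeights:
    """Weights of one rate network: two tanh hidden layers and a softplus output.

    ``w3`` carries the output weights; when ``bias`` is true its last entry is
    the intercept added in the last hidden layer (the only bias node in the
    network).
    """

    w1: np.ndarray  # (J, L1)
    w2: np.ndarray  # (L1, L2)
    w3: np.ndarray  # (L2,) or (L2 + 1,) when bias
    bias: bool = True

    def __post_init__(self):
        self.w1 = np.atleast_2d(np.asarray(self.w1, dtype=float))
        self.w2 = np.atleast_2d(np.asarray(self.w2, dtype=float))
        self.w3 = np.asarray(self.w3, dtype=float).ravel()
        l1, l2 = self.w1.shape[1], self.w2.shape[1]
        if self.w2.shape[0] != l1:
            raise ValueError(
                f"layer shape mismatch: w1 is {self.w1.shape}, w2 is {self.w2.shape}"
            )
        expected = l2 + 1 if self.bias else l2
        if self.w3.shape[0] != expected:
            raise ValueError(
                f"output layer expects {expected} weights (bias={self.bias}), "
                f"got {self.w3.shape[0]}"
            )
        if not (
            np.all(np.isfinite(self.w1))
            and np.all(np.isfinite(self.w2))
            and np.all(np.isfinite(self.w3))
        ):
            raise ValueError("network weights must be finite")

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]

    @property
    def hidden(self) -> Tuple[int, int]:
        return (self.w1.shape[1], self.w2.shape[1])

    @classmethod
    def zeros(cls, n_inputs, hidden=DEFAULT_HIDDEN, bias=True):
        l1, l2 = hidden
        return cls(
            np.zeros((n_inputs, l1)),
            np.zeros((l1, l2)),
            np.zeros(l2 + 1 if bias else l2),
            bias=bias,
        )

    @classmethod
    def random(cls, n_inputs, hidden=DEFAULT_HIDDEN, bias=True, rng=None, scale=0.1):
        rng = np.random.default_rng(rng)
        l1, l2 = hidden
        return cls(
            rng.normal(0.0, scale, (n_inputs, l1)),
            rng.normal(0.0, scale, (l1, l2)),
            rng.normal(0.0, scale, l2 + 1 if bias else l2),
            bias=bias,
        )

    # flat views used by the sampler and the posterior trace -----------------

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.w2.ravel(), self.w3])

    @classmethod
    def from_flat(cls, flat, n_inputs, hidden=DEFAULT_HIDDEN, bias=True):
        flat = np.asarray(flat, dtype=float)
        l1, l2 = hidden
        n1 = n_inputs * l1
        n2 = l1 * l2
        n3 = l2 + 1 if bias else l2
        if flat.size != n1 + n2 + n3:
            raise ValueError("flat weight vector has wrong length")
        return cls(
            flat[:n1].reshape(n_inputs, l1),
            flat[n1 : n1 + n2].reshape(l1, l2),
            flat[n1 + n2 :].copy(),
            bias=bias,
        )

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.w1.copy(), self.w2.copy(), self.w3.copy(), self.bias)

    @property
    def n_weights(self) -> int:
        return self.w1.size + self.w2.size + self.w3.size


@dataclass
class BDNNParams:
    """Full sampled state: two rate networks, shared ``t_reg``, latent times
    and preservation parameters.

    ``s`` and ``e`` are origination and extinction ages in Ma before present
    (``s > e >= 0`` for extinct taxa, ``e = 0`` for extant ones); ``q`` is the
    vector of per-bin baseline preservation rates and ``alpha`` the gamma shape
    of the among-lineage preservation multipliers.
    """

    weights_lambda: NetworkWeights
    weights_mu: NetworkWeights
    t_reg: float = 1.0
    s: Optional[np.ndarray] = None
    e: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None
    alpha: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.t_reg <= 1.0:
            raise ValueError(f"t_reg must lie in [0, 1], got {self.t_reg}")

    def copy(self) -> "BDNNParams":
        return BDNNParams(
            self.weights_lambda.copy(),
            self.weights_mu.copy(),
            self.t_reg,
            None if self.s is None else self.s.copy(),
            None if self.e is None else self.e.copy(),
            None if self.q is None else self.q.copy(),
            self.alpha,
        )


def forward_baseline(weights: NetworkWeights, x) -> np.ndarray:
    """Baseline rate ``softplus(tanh(tanh(x W1) W2) w3)`` for row(s) ``x``.

    ``x`` may be a single predictor row of length J or an array whose last
    axis has length J; the output drops that axis.  Strictly positive.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if x.shape[-1] != weights.n_inputs:
        raise ValueError(
            f"predictor row has {x.shape[-1]} entries, network expects {weights.n_inputs}"
        )
    h = np.tanh(x @ weights.w1)
    h = np.tanh(h @ weights.w2)
    l2 = weights.w2.shape[1]
    z = h @ weights.w3[:l2]
    if weights.bias:
        z = z + weights.w3[-1]
    out = activation_softplus(z)
    return float(out) if single else out


def regularize_rates(baseline, t_reg: float, mask=None) -> np.ndarray:
    """Shrink positive rates toward their grand mean.

    ``phi(x) = x**t_reg * E(x) / E(x**t_reg)`` where ``E`` averages over the
    whole species-by-time grid (or over ``mask`` when given, e.g. restricting
    to bins in which a lineage is extant).  Mean-preserving by construction;
    ``t_reg = 0`` yields a constant matrix, ``t_reg = 1`` is the identity.
    """
    if not 0.0 <= t_reg <= 1.0:
        raise ValueError(f"t_reg must lie in [0, 1], got {t_reg}")
    x = np.asarray(baseline, dtype=float)
    if np.any(x <= 0):
        raise ValueError("baseline rates must be strictly positive")
    xt = x**t_reg
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        mean_x = x[mask].mean()
        mean_xt = xt[mask].mean()
    else:
        mean_x = x.mean()
        mean_xt = xt.mean()
    return xt * (mean_x / mean_xt)


def lineage_time_rates(params: BDNNParams, predictors, mask=None):
    """Speciation and extinction rate matrices (species x time bin).

    Applies each network to every predictor row and regularizes both rate
    types with the shared ``t_reg``.  ``predictors`` is a
    :class:`bdnn.data_io.PredictorTensor` or a plain array of shape
    ``(n_species, n_bins, J)``.
    """
    values = getattr(predictors, "values", predictors)
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("predictor tensor must have shape (species, bins, predictors)")
    s, b, j = values.shape
    rows = values.reshape(s * b, j)
    lam_b = forward_baseline(params.weights_lambda, rows).reshape(s, b)
    mu_b = forward_baseline(params.weights_mu, rows).reshape(s, b)
    lam = regularize_rates(lam_b, params.t_reg, mask=mask)
    mu = regularize_rates(mu_b, params.t_reg, mask=mask)
    return lam, mu
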