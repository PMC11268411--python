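import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bdnn.core import NetworkWeights
from bdnn.data_io import (
    OccurrenceDataset,
    TaxonRecord,
    build_predictor_tensor,
)
from bdnn.mcmc import PosteriorTrace

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dataset():
    """Three taxa, point occurrence ages, 10-1 Ma, on a 10-Myr bin grid."""
    taxa = [
        TaxonRecord("a", [(8.0, 8.0), (5.5, 5.5), (4.0, 4.0)], extant=False),
        TaxonRecord("b", [(6.0, 6.0), (1.0, 1.0)], extant=True),
        TaxonRecord("c", [(9.0, 9.0), (7.0, 7.0)], extant=False),
    ]
    return OccurrenceDataset(taxa, time_bins=np.linspace(10.0, 0.0, 11))


@pytest.fixture
def tiny_traits():
    return pd.DataFrame(
        {"size": [1.0, 2.0, 3.5], "state": [0, 1, 1]}, index=["a", "b", "c"]
    )


@pytest.fixture
def tiny_tensor(tiny_dataset, tiny_traits):
    return build_predictor_tensor(tiny_dataset, traits=tiny_traits)


def make_trace(predictors, networks_lambda, networks_mu, t_regs, s, e, extant):
    """Hand-assemble a PosteriorTrace from explicit networks and times.

    Used by the explainability and evaluation tests to probe post-processing
    against known rate functions without running the sampler.
    """
    from bdnn.core import BDNNParams, lineage_time_rates

    n = len(networks_lambda)
    S, B, J = predictors.values.shape
    lam = np.empty((n, S, B))
    mu = np.empty((n, S, B))
    wl = np.stack([w.to_flat() for w in networks_lambda])
    wm = np.stack([w.to_flat() for w in networks_mu])
    for i in range(n):
        params = BDNNParams(networks_lambda[i], networks_mu[i], t_regs[i])
        lam[i], mu[i] = lineage_time_rates(params, predictors)
    s = np.asarray(s, dtype=float)
    e = np.asarray(e, dtype=float)
    return PosteriorTrace(
        species=list(predictors.species),
        bin_edges=predictors.bin_edges,
        extant=np.asarray(extant, dtype=bool),
        t_reg=np.asarray(t_regs, dtype=float),
        alpha=np.ones(n),
        q=np.ones((n, 2)),
        s=np.tile(s, (n, 1)),
        e=np.tile(e, (n, 1)),
        lam=lam,
        mu=mu,
        log_posterior=np.zeros(n),
        log_lik_bd=np.zeros(n),
        log_lik_prez=np.zeros(n),
        weights_lambda=wl,
        weights_mu=wm,
        n_predictors=J,
        hidden_layers=networks_lambda[0].hidden,
        use_bias=networks_lambda[0].bias,
        prez_edges=np.array([predictors.bin_edges[0], 0.0]),
    )


@pytest.fixture
def tiny_trace(tiny_dataset, tiny_tensor, rng):
    """Three posterior samples of small random networks on the tiny fixture."""
    hidden = (4, 3)
    J = tiny_tensor.n_predictors
    nets_l = [NetworkWeights.random(J, hidden, True, rng, 0.4) for _ in range(3)]
    nets_m = [NetworkWeights.random(J, hidden, True, rng, 0.4) for _ in range(3)]
    s = np.array([8.5, 6.5, 9.5])
    e = np.array([3.5, 0.0, 6.5])
    extant = np.array([False, True, False])
    return make_trace(tiny_tensor, nets_l, nets_m, [0.8, 0.9, 1.0], s, e, extant)
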