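# bdnn — birth-death neural network models for fossil diversification

`bdnn` infers lineage- and time-specific speciation and extinction rates from
fossil occurrence data, and identifies which traits, environments and times
drive them. It is aimed at paleobiologists and macroevolution researchers
with a richly sampled fossil clade who want to move beyond single-predictor,
monotone birth-death models.

## The model

A fossil dataset is a set of taxa with dated occurrences. Their latent
origination and extinction ages (s_i, e_i, in Ma) follow a birth-death
process whose rates vary by lineage and time,

    λ(i, t) = φ( softplus(W³ tanh(W² tanh(W¹ x(i, t)))), t_reg ),

where x(i, t) stacks time, traits, environmental series and phylogenetic
eigenvectors, and an independent network with the same two-hidden-layer
architecture (16 and 8 tanh nodes) emits μ(i, t). The output layer

    φ(x; t_reg) = x^t_reg · E(x) / E(x^t_reg),   t_reg ∈ [0, 1]

shrinks rates toward their grand mean without changing it: t_reg = 0 is the
constant-rate model, t_reg = 1 no shrinkage. An extinct lineage contributes
λ(i, s_i) · μ(i, e_i) · exp(−∫ λ+μ dt) to the likelihood (extant lineages
drop the μ factor), and fossil sampling follows a time-variable Poisson
process with gamma rate heterogeneity among lineages, conditioned on each
taxon being sampled at least once. Network weights (standard normal priors),
t_reg (truncated Exp(1), favouring constant rates), all s/e ages and the
preservation parameters are sampled jointly by Metropolis-Hastings.

Because the networks are unsupervised — never trained on labelled rates —
predictor effects are read off the posterior with explainable-AI tools:
partial-dependence curves, permutation importance on the birth-death
likelihood, SHAP attributions, and a consensus ranking across the three
metrics. A coefficient-of-variation test calibrated on constant-rate
simulations decides whether rate variation is significant at all.

The package also ships the nine-scenario benchmark simulator (constant,
time-shifted, trait-, temperature- and interaction-driven rates, with
cladogenetic trait evolution and realistic preservation) and the evaluation
metrics (MARE, CI coverage, sensitivity/specificity calibration) used to
validate the method. See `docs/methods.md` for the full model description.

## Worked example

Simulate a clade in which a binary trait confers 5-fold higher speciation
and extinction (benchmark scenario 5), fit the model, and ask what drives
extinction:

```python
import numpy as np
from bdnn import (MCMCConfig, ScenarioSpec, simulate_dataset, fit_bdnn,
                  evaluate_against_truth, partial_dependence, pd_fold_change)

sim = simulate_dataset(ScenarioSpec(5, target_richness=(100, 200)), seed=11)
print(f"{sim.dataset.n_taxa} sampled species,"
      f" {len(sim.dataset.to_frame())} occurrences")

cfg = MCMCConfig(n_iterations=100_000, sampling_freq=150,
                 burnin_fraction=0.4, seed=1, scale_weights=0.2,
                 update_mix=(0.35, 0.40, 0.10, 0.15))
trace, predictors = fit_bdnn(sim.dataset, traits=sim.traits,
                             eigenvectors=sim.eigenvectors,
                             time_bins=sim.dataset.time_bins, config=cfg)

report = evaluate_against_truth(trace, sim.true_lambda, sim.true_mu)
print({k: round(v, 3) for k, v in report.items()})

pd_mu = partial_dependence(trace, predictors, "mu", "state")
print("extinction at state 0/1:", np.round(pd_mu.mean, 3),
      "fold change:", round(pd_fold_change(pd_mu), 2))
```

Output (a few minutes on one CPU):

```
133 sampled species, 1108 occurrences
{'mare_lambda': 0.251, 'mare_mu': 0.286, 'coverage_lambda': 0.925,
 'coverage_mu': 0.925, 'cv_lambda': 0.708, 'cv_mu': 0.688}
extinction at state 0/1: [0.104 0.253] fold change: 2.43
```

`mare_*` are median absolute relative errors of the inferred lineage rates
against the simulated truth (0.2 = typically 20% off), `coverage_*` the
share of lineages whose 95% credible interval contains the truth, and
`cv_*` the rate heterogeneity the variation test consumes. The partial
dependence shows the marginal extinction rate at each trait state: the model
recovers the direction of the simulated 5-fold effect with a diluted
magnitude, part of the signal being absorbed by the correlated phylogenetic
eigenvectors — the behaviour the benchmark quantifies.

The same pipeline is available from the shell:

```bash
bdnn simulate --scenario 5 --replicates 1 --seed 11 --out sims/
bdnn run --occurrences sims/rep0/occurrences.tsv --traits sims/rep0/traits.tsv \
         --tree sims/rep0/tree.nwk --iterations 100000 --seed 1 --out fit
bdnn explain --trace fit --what rank --target mu \
         --occurrences sims/rep0/occurrences.tsv --traits sims/rep0/traits.tsv \
         --tree sims/rep0/tree.nwk --out rank.tsv
bdnn evaluate --truth sims/rep0/true_rates.tsv --trace fit --out report.tsv
```

## Layout

| Path | Contents |
| --- | --- |
| `src/bdnn/data_io.py` | occurrence/trait/series/tree I/O, age resampling, predictor tensor, phylogenetic eigenvectors |
| `src/bdnn/core.py` | rate networks, regularizing output layer |
| `src/bdnn/likelihood.py` | birth-death and preservation likelihoods |
| `src/bdnn/mcmc.py` | sampler, priors, posterior traces |
| `src/bdnn/xai.py` | partial dependence, permutation importance, SHAP, consensus ranking |
| `src/bdnn/simulator.py` | nine-scenario benchmark simulator |
| `src/bdnn/evaluation.py` | MARE, coverage, CV test, rate trajectories |
| `src/bdnn/cli.py` | `bdnn simulate / run / explain / evaluate` |
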