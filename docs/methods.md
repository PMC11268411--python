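# Methods

## Model

`bdnn` estimates lineage- and time-specific speciation rates λ(i, t) and
extinction rates μ(i, t) from fossil occurrence data under a birth-death
process coupled with a fossil preservation process. Instead of positing a
parametric link between rates and their putative drivers, each rate is the
output of a small feed-forward neural network applied to a predictor row

    x(i, t) = { t, c1(i), c2(i), …, env(t), phylo-eigenvectors(i) }

containing time itself, continuous and categorical traits (categoricals with
more than two states one-hot encoded with the full indicator set), optional
environmental time series, and the leading eigenvectors of the Gower-centered
patristic distance matrix as a proxy for phylogenetic relatedness. Continuous
predictors, eigenvectors, environmental series and time are z-transformed to
mean 0 / SD 1 over the species-by-bin cells; 0/1 indicators stay on their
natural scale; zero-variance columns are kept (as all-zero) so predictor
indices remain stable for the importance machinery.

Each network has two tanh hidden layers (16 and 8 nodes by default,
configurable) with a bias node in the last hidden layer, and a softplus
output guaranteeing positive baseline rates. Two independent networks emit
the speciation and extinction baselines. A single regularizing output layer
shrinks both toward their grand mean:

    φ(x; t_reg) = x^t_reg · E(x) / E(x^t_reg),  t_reg ∈ [0, 1]

where E(·) averages over all species-by-bin cells. φ preserves the mean
exactly, returns a constant matrix at t_reg = 0 (the constant-rate model) and
the identity at t_reg = 1. Whether E(·) pools the full grid or only bins
within lineage lifespans is genuinely open; the full grid is the default and
`MCMCConfig.regularization_mask="alive"` exposes the alternative (at the cost
of full likelihood recomputation on every move).

Given rates, an extinct lineage with origination age s and extinction age e
(Ma before present) contributes

    log λ(i, s) + log μ(i, e) − ∫_e^s [λ(i,t) + μ(i,t)] dt,

extant lineages (e = 0) drop the extinction factor. Rates are piecewise
constant on the bin grid (1-Myr bins by default for simulated data), so the
integral is an exact sum over bin overlaps and the likelihood is invariant
under refinement of the grid.

Fossil occurrences follow a time-variable Poisson process: baseline rate q_b
per preservation bin (5 equal-width bins by default — deliberately coarser
than the rate grid to keep the sampled parameter count modest) times a
lineage-specific multiplier drawn from a mean-1 gamma distribution with shape
α, discretized into 4 equal-probability categories (quantile medians,
renormalized to mean 1) and marginalized with equal weights. Each lineage's
likelihood is conditioned on having been sampled at least once, category by
category, since a taxon with zero fossils never enters a dataset.

## Priors and MCMC

Standard normal priors on every network weight act as the regularizer of the
otherwise overparameterized networks; t_reg has a truncated Exp(1) prior on
[0, 1], placing the most prior mass on the constant-rate end; q and α carry
Exp(1) priors. The joint posterior over weights, t_reg, all origination and
extinction ages, q and α is sampled by Metropolis-Hastings with four update
blocks (default mix 40% times, 40% weights, 15% preservation, 5% t_reg):

* normal jitter on a random 5% of one layer of one network (scale 0.15);
* sliding windows (±0.5 Myr) on the s and e of a small fixed block of taxa
  (2 per move — a fixed block rather than a fraction keeps the joint
  acceptance probability workable regardless of dataset size), reflected so
  each lifespan keeps bracketing all of the taxon's occurrence ages and stays
  inside the rate grid;
* log-multiplier moves on one q bin or on α (Hastings ratio log m);
* a ±0.1 window on t_reg reflected into [0, 1].

The proposal scales and mix are tuning surfaces; the defaults were chosen for
workable acceptance rates (~0.3–0.6 for times/preservation) on datasets of
50–150 species. Chains initialize at s = oldest occurrence + 0.01 Myr,
e = youngest occurrence − 0.01 Myr (0 for extant taxa), weights ~ N(0, 0.1),
t_reg = 0.5, q = 1, α = 1 — a guaranteed-finite start near the prior bulk,
with automatic weight shrinkage and retry should the posterior still be
non-finite. A `prior_only` switch drops both likelihood terms; the test suite
uses it to verify that the proposal machinery reproduces the priors
(Kolmogorov-Smirnov on weights, χ² on t_reg at 10⁴ samples).

The thinned trace stores, per sample, the scalar parameters, all s/e ages,
both flattened weight vectors and the derived rate matrices, so every
post-processing step can re-run the networks.

## Predictor effects and importance

All explainability quantities hold the fitted model fixed: within each
posterior sample the regularizer's normalizing constants E(x) and E(x^t_reg)
are frozen at their observed-tensor values while inputs are modified.

* **Partial dependence.** For each grid value (100 points over a continuous
  predictor's observed range; the states of a one-hot group toggled jointly;
  bin midpoints for time) the predictor is set to that value in every cell,
  rates are recomputed and averaged over cells — one curve per MCMC sample.
  The *PD fold change* is max/min of the posterior-mean curve.
* **PD posterior difference.** The fraction of samples in which the rate at
  the mean curve's argmax exceeds the rate at its argmin; exact ties count
  one half, so a flat (no-effect) curve scores 0.5.
* **Permutation importance.** The mean drop in birth-death log-likelihood
  after permuting a predictor, averaged over posterior samples and 10
  permutations. Lineage-level predictors permute across species (one-hot
  groups as a block, constant within a species' bins). Predictors identical
  across species within a bin — time and environmental series — would be
  left unchanged by an across-species shuffle, so they permute across time
  bins instead. Pair scores are the joint-permutation drop minus the two
  single drops.
* **SHAP values.** Additive per-cell attributions under the
  marginal-expectation value function (absent predictors imputed from a
  background sample of observed rows; 100 rows by default). For J ≤ 12 the
  exact Shapley value by full coalition enumeration is available and serves
  as the oracle. The default estimator evaluates only empty, singleton and
  pair coalitions, forms the pairwise (2-additive) Moebius masses
  m_j, m_jk and returns φ_j = m_j + ½ Σ_k m_jk, with the efficiency
  residual spread proportionally to |φ_j|. This keeps the dummy axiom exact
  (a predictor the networks ignore gets exactly zero) and local accuracy
  exact (base + Σφ equals the rate per cell); what is approximate is the
  allocation among interacting predictors when interactions of order > 2 are
  present. |m_jk| doubles as the pair-interaction mass.
* **Consensus ranking.** The three metric-wise rankings are aggregated by
  minimizing the summed Spearman footrule displacement — solved exactly as a
  linear assignment problem — with ties broken by mean rank, then input
  order. For ≤ 6 predictors the tests cross-check the result against a
  brute-force Kemeny search on near-consistent inputs. Individual effects
  and pair interactions are ranked separately.

## Detecting rate variation

The coefficient of variation (sd/mean) of the posterior-mean lineage-time
rate matrix, separately for λ and μ, is compared against thresholds
calibrated on constant-rate simulations: the threshold is the order statistic
of the calibration CVs leaving exactly 1 − specificity of them above it
(95% specificity by default). By default the CV pools all species-by-bin
cells; `cells="alive"` restricts to bins overlapping each lineage's
posterior-mean lifespan.

## Benchmark simulator

Nine generating scenarios (constant; logistic time trends; instantaneous
shifts; a Gaussian temperature link interacting with a binary state; a
5-fold state effect interacting with time; a Gaussian bell over a continuous
trait; its state-inverted variant; its time-inverted variant; and a variant
whose causal trait is withheld from the analysis) are simulated forward in
time at 0.01-Myr steps from a 35-Ma root. Per step, each living lineage
speciates with probability λ·dt and dies with probability μ·dt; the
continuous trait follows an unbiased random walk (σ² = 0.02/Myr) with a
cladogenetic jump (SD 0.2) for the daughter, which also switches its binary
state with probability 0.1 (no anagenetic switching). Whole clades are
rejection-sampled until the total species count lands in a target window
(200–300 by default).

Two calibration sentences in the scenario definitions are mutually
inconsistent with a single Gaussian, so the widths are pinned to one stated
point each: the temperature bell uses SD 1.2 on the SD-1-scaled curve, and
the trait bell is calibrated so the rate at 1 trait-SD is 30% of the
baseline (the "reach 20% at 2 SD" alternative is a config switch). "Trait
SD" is the expected SD after the full random walk, √(σ²·root age).

Preservation sampling draws a baseline rate per 1-Myr stage from a
log-uniform on [0.5, 5] and per-species mean-1 gamma multipliers whose shape
is itself log-uniform on [0.5, 5]; occurrence counts are Poisson on
stage-lifespan overlaps with uniform ages inside the overlap; unsampled
species are dropped. The observable continuous trait is the average of the
true trajectory at the sampled occurrence ages — mimicking what morphology
measured on fossils can deliver — while the categorical state is known
exactly. The species tree of the sampled taxa (budding speciation; the
parent persists through the event) is emitted as Newick and decomposed into
phylogenetic eigenvectors.

The bundled temperature curve is a synthetic stand-in: a Gaussian-smoothed
random walk rescaled to SD 1 (lag-1 autocorrelation > 0.9), reproducible by
seed; empirical curves load from TSV. What the simulator does **not**
emulate: spatially structured sampling, taxonomic error, age-model error
beyond interval uniformity, anagenetic state change, and diversity-dependent
feedbacks — conclusions from passing benchmarks transfer to real data only
insofar as those features are second-order.

## Evaluation metrics

Accuracy is the median absolute relative error (MARE) of species-specific
rates — the inferred λ at each lineage's sampled origination against the
parental (generating) rate at the true origination, and the inferred μ at
the sampled extinction against the lineage's own rate at its true end (the
present, for extant species) — with the even-length midpoint rule and
zero-truth entries excluded with a warning. Coverage is the share of
lineages whose equal-tailed 95% credible interval contains the truth.
Rate-through-time trajectories average, per sample and bin, over lineages
whose sampled lifespan overlaps the bin.

## Problem sizes used in the shipped analyses

Publication-scale replication of the benchmark (100 replicates × 10⁶
iterations per scenario, 200–300 species) is cluster-scale. The package's
own acceptance analyses (`scripts/acceptance.py`, `tests/test_acceptance.py`)
run the identical machinery at reduced scale, chosen once as the package's
desk-scale study conditions: the scenario-5 effect-size benchmark uses 4–5
replicates of paper-sized clades (200–300 species before preservation) with
10⁵-iteration chains; the detection study uses clades targeted at 50–150
species with 3 × 10⁴-iteration chains — 20 constant-rate fits for threshold
calibration, two fits per variable-rate scenario for sensitivity, and
consensus importance rankings on the first 8 constant-rate fits for the
false-positive rate. Detection chains use an update mix of
(times .35, weights .40, preservation .10, t_reg .15) — more t_reg moves
than the default, since the regularizer is the slowest-relaxing direction at
these chain lengths. At this scale the Monte-Carlo spread of all reported
quantities is materially wider than in the full-scale study; the test
tolerances account for that.

## Numerical choices

* softplus via `logaddexp(0, z)`; log(1 − e⁻ˣ) via `expm1`/`log1p` branches;
  gamma-category marginalization via `logsumexp`.
* Bin lookup treats bin b as the half-open interval (lower, upper]; an age
  exactly on a boundary belongs to the younger bin.
* Eigenvector signs are fixed by making each axis's largest-|loading|
  positive; coordinates are scaled by √eigenvalue (principal-coordinate
  convention). Gower centering is applied to −D/2, which is positive
  semidefinite for additive tree metrics and reconstructs patristic
  distances exactly at full rank.
* PD tie-breaks: argmax/argmin of the mean curve take the lowest grid index.
* Time moves that would produce s ≤ e (possible only for point-degenerate
  occurrence ranges) retain the previous values for that taxon.

## Known limitations

* The sampler is a plain random-walk Metropolis scheme; mixing over network
  weights is slow for large architectures, and desk-scale chains trade some
  coverage for runtime. No parallel tempering or gradient-informed moves.
* The κ = 2 SHAP estimator misallocates attributions in the presence of
  strong third-order interactions (the exact enumerator is available for
  J ≤ 12).
* The preservation model is the time-variable Poisson process with gamma
  heterogeneity; hump-shaped within-lineage profiles are out of scope.
* Rates outside a lineage's lifespan are extrapolations of the network and
  enter the pooled CV test; the lifespan-restricted variant is exposed but
  not default.
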