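# Methods

## The model

A case-control study records, for subject *i*, the disease status
*D<sub>i</sub>* ∈ {0,1}, an environmental exposure *E<sub>i</sub>* (binary or
continuous), optional covariates *X<sub>i</sub>*, and the multilocus genotype
**G**<sub>i</sub> — the vector of minor-allele counts (0/1/2) at *J* SNPs in
one candidate region. The *H* distinct multilocus genotypes observed in the
sample are the elementary units. A latent allocation vector
**z** = (z<sub>1</sub>, …, z<sub>H</sub>), z<sub>h</sub> ∈ {1..K}, partitions
them into *K* risk clusters ("genetic profiles"), and each cluster carries
its own logistic model:

    logit P(D_i = 1) = alpha_{z(c_i)} + beta_{z(c_i)} E_i + gamma' X_i

where c<sub>i</sub> is subject *i*'s genotype id. A shared slope beta gives
the no-interaction form; gene–environment interaction means the
beta<sub>k</sub> differ. The prospective likelihood is used for the
retrospectively sampled data, which is valid for odds-ratio inference;
intercept *levels* are not identified, only their contrasts.

**Genotype geometry.** Distance between genotypes h, h′ is the
variance-standardised squared Euclidean distance
d(h,h′) = Σ<sub>j</sub> (g<sub>hj</sub> − g<sub>h′j</sub>)² / s<sub>j</sub>²,
with s<sub>j</sub>² the (divide-by-n) sample variance of SNP *j*'s code over
all subjects. Each genotype's 4 nearest distinct genotypes define
neighbour weights: w = 2 for mutual 4-NN pairs, 1 for one-way pairs, 0
otherwise. Ties at the k-th nearest distance break by ascending genotype id,
so the graph is deterministic. SNPs should be pruned to low pairwise LD
upstream so no tight LD block dominates the metric.

**Priors.** **z** follows the Potts model
p(**z** | ψ) ∝ exp{ψ U(**z**)}, U(**z**) = Σ<sub>h&lt;h′</sub> w<sub>hh′</sub>
1{z<sub>h</sub> = z<sub>h′</sub>}, with coupling ψ ~ Uniform[0, ψ_max].
Coefficients get independent N(0, 4) priors (a Uniform[−10, 10] alternative
is available). ψ_max defaults to 1.2; because the co-assignment-versus-ψ
curve depends on the neighbourhood graph, `potts.calibrate_psi_max` finds,
by bisection on equilibrium Gibbs estimates, the ψ at which the average
neighbour co-assignment probability reaches a target (0.97 by convention) —
beyond that point the Potts model approaches its phase transition, nearly
all sites collapse into one cluster, and the sampler sticks.

## The sampler

Each iteration sweeps three blocks:

1. **Coefficients** — Gaussian random-walk Metropolis–Hastings on each
   scalar (default SD 0.1), with only the affected subjects' likelihood
   terms recomputed. An optional burn-in tuner nudges each scale toward a
   20–45% acceptance rate and freezes at burn-in's end.
2. **Allocations** — one Metropolized-Gibbs pass over all genotypes. The
   full conditional for site h is ∝ exp{ψ u<sub>hk</sub>} × (likelihood of
   h's subjects under cluster k), u<sub>hk</sub> the summed weight from h
   into cluster k. The Metropolized variant proposes from the conditional
   restricted to non-current clusters and accepts with the ratio
   (1 − p<sub>cur</sub>)/(1 − p<sub>prop</sub>), which strictly improves
   mixing over plain Gibbs on discrete spaces. When the proposal's
   conditional probability is numerically 1 the move is accepted outright.
3. **ψ** — Monte Carlo Metropolis–Hastings (MCMH). A random-walk proposal is
   reflected into [0, ψ_max]; the intractable normalizing-constant ratio
   Z(ψ)/Z(ψ′) is replaced by the importance-sampling estimate
   (1/m) Σ<sub>i</sub> exp{(ψ′−ψ) U(z<sub>i</sub>)} with z<sub>i</sub> drawn
   fresh from Potts(ψ) by single-site Gibbs (m = 50 by default, each from a
   uniform start advanced 20 full sweeps; fresh starts avoid carry-over
   between auxiliary draws). Too few sweeps underestimates E[U] at large ψ
   and biases ψ upward — the desk presets keep enough sweeps to hold this
   bias small over [0, ψ_max].

Three further choices matter for mixing on small datasets and are this
package's own design decisions:

* **ψ warm-up.** ψ is held at 0 for the first quarter of burn-in, then
  released. Starting with active spatial coupling freezes whatever
  configuration the chain starts in before the coefficients carry any
  information; with ψ = 0 the allocations first organise around the
  likelihood, and the coupling then smooths them.
* **Cluster-swap move.** Every 10th iteration a symmetric MH move proposes
  exchanging two clusters' (alpha, beta) pairs with **z** unchanged
  (accepted on the likelihood ratio — the prior is exchangeable). Single-site
  updates mix poorly between "patchwork" modes in which two clusters' roles
  are locally interchanged; this global move jumps between them.
* **Initialisation.** **z** starts from k-means on per-genotype risk
  profiles (logit of the shrunken case rate among low- and high-exposure
  subjects); coefficients start at crude per-cluster moment estimates
  (clipped to ±3). Alternatives — PAM on genotype distance, or uniform
  random — are available by flag but allowed clusters to evaporate early on
  small datasets. ψ-chain and coefficient starting points only affect
  transient behaviour; all reported checks are posterior summaries after
  burn-in.

Full-scale presets follow the original study sizes (200,000 iterations,
half burn-in, thinning 10; 300,000/200,000 for bootstrap replicates). The
desk preset used in tests is 500–4,000 iterations with m = 10–15 and 5–20
auxiliary sweeps; problem sizes per experiment are listed below.

## Choosing K and the consensus partition

Deviance D = −2 log-likelihood. DIC = 2 D̄ − D̂, where D̄ averages D over
stored draws and D̂ evaluates D at *per-subject posterior means* of the
assigned intercept and slope (and the posterior mean gamma). The
per-subject plug-in makes D̂ — hence DIC and pD = D̄ − D̂ — exactly invariant
under cluster relabelling, with no post-hoc label alignment. Negative pD is
reported with a warning rather than hidden.

With repeated runs per K, the **+1 SE rule** selects the smallest K whose
mean DIC is within one Monte-Carlo SE (SD/√runs at the minimising K) of the
minimum mean. With single runs the **+1 rule** selects the smallest K whose
DIC is within 1 of the minimum; both rules never select past the argmin.

The consensus partition computes π<sub>hh′</sub>, the fraction of stored
draws allocating h and h′ together (label-permutation invariant), and runs
PAM on 1 − π. PAM is in-package — greedy BUILD seeding plus
best-improvement SWAP, with 4 seeded random restarts to escape the rare
deep local optimum — because no installed library accepts precomputed
dissimilarities for k-medoids. Exact ties break toward the lowest medoid
id; the whole procedure is deterministic given its seed.

## The interaction test

The nominal test fits, by MLE, logistic models with the consensual profile
L (categorical), E, X, with and without L×E, and refers
2Δloglik to χ² with K*−1 df. Because L is estimated from the same data this
nominal p (p_obs) overstates significance, so it is treated as the test
statistic and calibrated by parametric bootstrap: fit the no-interaction
Bayesian model, select K₀* by the +1 rule, fit the null logistic model with
L₀ + E + X, regenerate every subject's outcome from its fitted probability
B times, rerun the full interaction pipeline per replicate (re-selecting
K within the same grid, which starts at 2 — the test is undefined at K = 1)
to get T_b, and report p = (1 + #{T_b ≤ p_obs})/(B + 1). The add-one
estimator is standard, strictly valid, and never returns 0. Replicates that
fail to converge are flagged and excluded, with the effective B reported.

## Benchmarks

*minP-SNP*: per SNP, a 2-df LRT of SNP×E with the SNP as a three-level
categorical (df reduced if a level is absent; monomorphic SNPs excluded);
the statistic is the minimum nominal p. *minP-PC*: the same over principal
components of the centred (unscaled) 0/1/2 matrix, 1 df each; loading signs
are fixed so each component's largest-absolute loading is positive. Both
minima are calibrated by parametric bootstrap under a fitted
G-main-effects + E + X logistic null — the same resampling construction as
the primary test, chosen for comparability. PC scores depend only on
genotypes, which the bootstrap leaves unchanged, so they are computed once.

## The simulator

Genotypes are sums of two independent haplotypes (Hardy–Weinberg at the
haplotype level) drawn from (a) an explicit haplotype pool with given
frequencies, (b) independent per-SNP MAFs, or (c) a Gaussian-copula model
with exchangeable within-block correlation. The default MAF vector is the
15-SNP reference panel (0.32, 0.22, 0.38, 0.23, 0.39, 0.17, 0.12, 0.24,
0.36, 0.37, 0.29, 0.41, 0.30, 0.35, 0.24). The built-in three-region
partition counts risk (minor) alleles at three functional SNPs — regions
with ≤1, exactly 2, and >2 alleles; a two-cluster variant merges regions II
and III. Exposure is Bernoulli given the cluster: P(E=1) = 0.3 in region I
and 0.6 elsewhere, making E and **G** dependent in the population.

Case-control sampling draws (G, E), computes the disease probability under
a working baseline intercept (bisected to a ~10% marginal prevalence — the
baseline is not identified under case-control sampling and only affects
rejection efficiency), draws D, and retains subjects until the case and
control quotas are exactly filled. Everything is deterministic given the
seed.

**What the generator does not emulate:** real LD structure beyond
block-exchangeable correlation, genotyping error and missingness, covariate
confounding, and population stratification. Passing recovery tests
therefore show that the machinery works under clean, correctly specified
cluster-structured risk; they do not certify performance on real cohorts.

## Desk-scale problem sizes used by the test suite

* Potts calibration: a ~250-genotype graph from 300 subjects at the
  reference MAFs; 10,000 Gibbs draws at ψ = 0, K = 2.
* Type-I calibration: 28 null datasets (600 cases/600 controls, 6 SNPs at
  the leading reference MAFs, G main-effect OR 4 for regions II+III vs I,
  E OR 4), B = 39 bootstrap replicates, 500-iteration chains; nominal 0.05
  and 0.10 checked against the Clopper–Pearson 95% interval.
* Oracle equivalences: H = 5 graphs (ψ posterior, MCMH vs enumerated
  normalizer), n = 1500 (K = 1 vs logistic MLE), H = 8 (PAM vs exhaustive),
  relabelling invariance of DIC (exact).
* Parameter recovery: 20 replicates of 1500 cases/1500 controls, intercept
  contrast log 2 and exposure log-OR contrast log 4, K grid {1,2,3},
  2,500-iteration chains.
* Power ordering: 16 datasets of 600 cases/600 controls under the same
  two-cluster interaction (not expressible by any single SNP), proposed
  test at B = 39 vs minP-SNP/minP-PC at B = 99.

## Numerical notes and limitations

* Bernoulli log-likelihoods use D·η − log(1+e^η) via `logaddexp`; extreme
  linear predictors cannot produce NaN.
* Reflection keeps ψ proposals in [0, ψ_max]; the reflected random walk is
  symmetric, so no proposal correction is needed.
* Monomorphic SNPs are rejected at load time (the distance would divide by
  zero); missing codes can be imputed to the per-SNP rounded mean by an
  explicit helper, never silently.
* Draw counts follow ⌊(iterations − burn-in)/thinning⌋ exactly; two runs
  with the same seed are bit-identical.
* The Potts prior and the likelihood compete on different scales: the prior
  term grows with the edge weight of the genotype graph, the likelihood
  with the number of subjects. On small studies (≲1,000 subjects with a
  ~300-genotype graph) the posterior can genuinely favour near-collapsed
  allocations once ψ drifts to its upper bound, smearing cluster-specific
  effect estimates; partition recovery at the scale the method is designed
  for (≈3,000 subjects) is accurate. For small studies, lower ψ_max (see
  `calibrate_psi_max`) or interpret the selected K conservatively.
* Single-site allocation updates remain the mixing bottleneck at large ψ;
  for regions yielding many thousands of distinct genotypes,
  `regroup_genotypes` coarsens the space to a few hundred pseudo-genotypes
  by PAM medoids before fitting.
* K is selected over a user grid, not sampled; reversible-jump over K and
  Swendsen–Wang-type cluster flips are out of scope.
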