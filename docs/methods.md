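# Methods

## The problem

In smallholder dairy systems, herds hold one to three cows and most
matings use a village bull rather than national AI, so genetic
connectedness across herds is weak. Standard genetic evaluation —
an animal model with an independent herd effect — then struggles to
separate genetic from environmental variation: a village with good
feed looks like a village with good genes. The package implements a
simulation study of this setting and a family of Bayesian evaluation
models that add a *spatial* environmental effect with distance-decaying
covariance between herd locations, which lets nearby herds share
environmental information and frees the genetic effect from absorbing it.

## Data-generating model

Phenotypes are simulated as

    y_i = mu + g_i + h_i + s_i + e_i

with `mu = 0` (the evaluation models carry a free intercept, so a mean
shift is unidentifiable and simulating one would only obscure
comparisons), `g` the true breeding value rescaled in the phenotyped
cohort to mean 0 and variance sigma_g^2 = 0.1, `h ~ N(0, 0.25)` a herd
effect shared by herd-mates, `s` the herd's total spatial effect
(variance 0.4 after rescaling), and `e ~ N(0, 0.25)` i.i.d. Total
phenotypic variance is 1.0.

### Geography and demography

- A unit-square country with `n_villages` village centres ~ U(0,1)^2;
  each village has `herds_per_village` herds at bivariate-normal offsets
  with isotropic location variance 3.5e-4 by default (1.0e-4 = strong,
  9.0e-4 = weak clustering).
- Herd sizes are zero-truncated Poisson(1.5): mean 1.93 cows, so the
  default 100 x 20 geography carries ~3860 cows.
- Founder genomes: 10 chromosomes of 1 Morgan, 5000 SNP + 1000 QTL per
  chromosome at full scale. The default founder backend draws per-site
  allele frequencies from a U-shaped Beta(0.5, 0.5) spectrum and founder
  haplotypes as independent Bernoulli draws; every site is checked to
  segregate. An optional msprime coalescent backend adds linkage
  disequilibrium at extra cost. The evaluation models consume only SNP
  dosages and pedigree, so founder LD mostly matters for how much the
  genomic model can exceed the pedigree model (see Limitations).
- An additive trait: QTL substitution effects ~ N(0,1); gametes are
  formed with Poisson(length) crossovers per chromosome (Haldane, no
  interference) and independent chromosome assortment.
- Selection phenotypes with h^2 = 0.8 (bulls) and 0.3 (cows) drive bull
  choice. At founding the best males are ranked on true breeding value
  (configurable to the phenotype); in later generations bull candidates
  are ranked on the h^2 = 0.8 phenotype (configurable to TBV).

### Mating regimes (genetic connectedness)

- *weak*: every village uses its own natural-mating bull;
- *intermediate*: 75% of herds use the village bull, the rest draw from
  a 10-bull national AI pool (the AI herds are fixed at scenario setup);
- *strong*: all cows are mated to a national AI pool of one bull per
  village (100 at full scale), keeping diversity high and the
  separation problem hard.

Each generation every cow has one calf. Female calves replace their
dams in the same herd; dams of male calves are retained and re-bred, so
herd sizes never change. Male calves are bull candidates for their
herd's service type. If a village produces no male calf in a round
(possible only in small scaled-down villages), the sitting bull serves
another generation. After 11 generations the standing cows are the
phenotyped cohort; their TBVs are affinely rescaled to mean 0, variance
exactly 0.1, the same map is applied to generation-12 calves, and a
random subset of the generation-12 females (200 by default) forms the
prediction cohort. The exported pedigree keeps generations 8 onward
(earlier parents unknown), plus any retained dams that are themselves
phenotyped.

### Spatial environment

Eight independent Gaussian random fields with Matérn covariance

    C(d) = sigma^2 (2^(1-nu)/Gamma(nu)) (kappa d)^nu K_nu(kappa d),
    kappa = sqrt(8 nu)/rho,  nu = 1

are simulated at the herd coordinates (range rho ~ U(0.1, 0.5),
marginal variance 0.2 or 0.3 equiprobably) by dense Cholesky with
escalating diagonal jitter (1e-10 sigma^2 up to 1e-6 sigma^2). The total
effect is the weighted sum: processes 1-3 with weight 1, 4-6 with
(1 + alpha_k), 7-8 with (1 + alpha_k + beta_k), alpha, beta ~
U(-0.5, 0.5), affinely rescaled to mean 0 and variance sigma_s^2
exactly. Observed covariates: v1-v3 exact; v4-v6 plus N(0, 0.1 sigma_k^2)
noise; v7 dichotomised at a U(mean +/- 1 sd) threshold; v8 trichotomised
at U(mean - 2 sd, mean) and U(mean, mean + 2 sd) thresholds; two extra
Matérn null processes are observed exactly (a threshold may leave a
factor level empty; this is recorded, not repaired). Scenario studies
vary the spatial share of the herd-level environmental variance with
sigma_s^2 + sigma_h^2 = 0.65 held fixed.

## Evaluation models

Five models are fitted to y: G (intercept + genetic + residual), GH
(+ herd), GS (+ spatial), GHS (both), GHSC (both + observed
environmental covariates). The genetic covariance is sigma_a^2 A
(pedigree numerator relationship, tabular method; sparse inverse by
Henderson's rules with inbreeding) or sigma_a^2 G with VanRaden's
G = ZZ'/k, Z column-centred by 2q_l and k = 2 sum q_l(1-q_l), allele
frequencies from the genotyped set (training + prediction animals
jointly) and a 1e-6 ridge for factorisation. The spatial effect has the
exact dense Matérn (nu = 1) covariance over unique herd locations — no
SPDE/GMRF approximation is used. Fixed effects (intercept, covariates)
get N(0, 1000) priors; continuous covariates are standardised and the
two factors dummy-coded against their first level.

Hyper-parameters carry penalised complexity priors stated as tail
probabilities: for a standard deviation P(sigma > u) = alpha gives
sigma ~ Exp(-ln(alpha)/u); for the range P(rho < u) = alpha gives
p(rho) = (lambda/rho^2) exp(-lambda/rho), lambda = -u ln(alpha). The
per-model (u, alpha) settings for the simulated-data analyses live in
`inference.TABLE1_PRIORS`; GHSC reuses the GHS settings.

## Inference

All location effects (beta, a, h, s) are Gaussian given the
hyper-parameters, so they are integrated out analytically and the chain
runs only over the 2-5 hyper-parameters: adaptive random-walk
Metropolis on the log scale against the marginal likelihood
N(y; 0, V(theta)) with

    V = sigma_a^2 K_obs + sigma_h^2 W W' + sigma_s^2 C(rho)_obs
        + sigma_beta^2 X X' + sigma_e^2 I.

Working on this collapsed posterior removes the strong location/scale
coupling that makes effect-by-effect Gibbs mix slowly in exactly the
confounded settings this study targets, so short chains give usable
posteriors. For each retained hyper-parameter sample, all location
effects are then drawn *jointly and exactly* in one multivariate
Gaussian solve by conditioning a prior realisation on the data
(Matheron's rule): draw beta0, a0, h0, s0, e0 from their priors, form
y0, and correct with Cov(effect, y) V^{-1} (y - y0). Prediction-cohort
animals receive breeding-value draws through the joint prior — for the
pedigree model this uses the A-submatrix over phenotyped + prediction
animals, whose implied posterior is identical to the full all-ancestor
system by Gaussian marginalisation.

Numerical choices:

- chains start from a within/between-herd moment decomposition of y
  rather than the prior median; with diffuse starting points the
  sigma_a^2/sigma_e^2 ridge can take thousands of iterations to reach
  the bulk of the posterior;
- proposal adaptation: Robbins-Monro scale tuning toward 30%
  acceptance plus a running empirical covariance (Haario-style), frozen
  after burn-in; a chain with acceptance < 5% aborts with diagnostics;
- inside the sampler the nu=1 Matérn correlation x K_1(x) is evaluated
  from a 4096-point interpolation table (max error ~1e-6); field
  *simulation* always uses the exact Bessel function;
- Cholesky factorisations reuse escalating jitter (1e-10 to 1e-4 of the
  mean diagonal); duplicate hyper samples (Metropolis rejections) share
  factorisations;
- default chain: 5000 iterations, 1000 burn-in, thin 4. The desk
  profile uses 900/350/6 (and 30% shorter chains for the 2-3 parameter
  non-spatial models), chosen for single-CPU study runs.
- DIC = mean deviance + p_D with p_D = mean deviance minus the deviance
  at the posterior means of the effects and of sigma_e^2.

A deterministic Henderson mixed-model-equations solver
(`blup_given_variances`) provides the independent oracle: with
hyper-parameters fixed, the sampler's posterior means must match its
solutions to Monte Carlo error. A random effect with variance zero is
dropped (infinite-shrinkage limit), which also gives the model-nesting
identities used in tests.

## Evaluation metrics

Accuracy is the Pearson correlation of true and posterior-mean breeding
values (EBV for phenotyped animals, PBV for the prediction cohort).
Ranking quality is Spearman's correlation over the top-100 animals,
selected on the *true* values (configurable to the inferred side).
CRPS uses the standard sample estimator mean|X - y| - 1/2 mean|X - X'|
over all ordered sample pairs (its small-sample value on {0,1} vs 0.5
is 0.25, which fixes the pair convention; the O(1/m) bias is negligible
at the sample counts used), averaged over animals within a replicate
and then over replicates. The confounding correlation corr(EBV, true
spatial effect) is near zero when a model separates genetic and spatial
effects cleanly.

## Problem sizes

The package's defaults are the full study conditions (100 villages x 20
herds, 5000 SNP + 1000 QTL per chromosome, 60 replicates at full
scale). The test suite and the replicate studies it runs use the *desk
profile*: 100 villages x 4 herds (~790 records), 1000 SNP + 100 QTL per
chromosome, 100 prediction calves, 5-10 replicates, and the shorter
chains above. The desk geometry keeps all 100 village locations — the
spatial field's effective sample size, which is what lets GS/GHS beat
GH — while cutting records per village. One replicate-set (simulation
plus nine model fits) runs in ~2-3 minutes on one CPU.

What the desk scale preserves, and what it does not: per-herd structure,
the confounding mechanism, model orderings and the confounding-
correlation contrast all transfer. Absolute accuracies of the
*spatial* models sit below the full-scale values, because EBV accuracy
grows with the number of records and the desk profile has a fifth of
them: mixed-model solutions at the true variances (the ceiling any
inference can reach) give roughly 0.44 for pedigree GHS and ~0.48 for
genomic GHS at this size versus 0.54/0.63 at full scale. The genomic
edge over pedigree is also compressed: with the LD-free default founder
backend, G captures realised relatedness but not marker-QTL LD.

## Known limitations

- The default founder backend has no linkage disequilibrium or
  demography; use the msprime backend where LD matters.
- Dense-covariance inference scales as n^3 per likelihood evaluation;
  beyond a few thousand records a sparse-precision (GMRF) spatial
  representation would be needed.
- Single trait, no genotype-by-environment interaction, homogeneous
  residual variance, non-overlapping generations, no mortality or
  culling policy.
- The spatial model assumes stationarity and isotropy; the simulated
  total effect (a weighted sum of eight Matérn fields) deliberately
  violates the single-field form the models fit, which is part of the
  test: the evaluation model never sees the true generative structure.
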