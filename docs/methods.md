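# Methods

## Model

All three marker-effect methods share the linear model

    y = mu * 1 + X beta + e,    e ~ N(0, sigma2_e * I)

with a flat prior on the overall mean `mu` and the scale-invariant prior
`p(sigma2_e) ∝ 1/sigma2_e` on the residual variance.  Effects are
conditionally normal, `beta_j | v_j ~ N(0, v_j)`, and the methods differ
only in the second hierarchy level:

* **Bayes-A** — `v_j ~ scaled-Inv-chi2(nu, s2)` with both hyperparameters
  fixed.  The marginal prior on each effect is a Student t whose tails are
  set in advance, so the degree of shrinkage is a modelling choice.
* **Student-t** — the same inverse-chi-square layer with `nu` and `s2`
  estimated: `1/nu ~ Uniform(0, 1]` (so `nu >= 1`) and
  `s ~ Uniform(0, A]` with A large.  The data decide how heavy the prior
  tails are, i.e. how aggressively small effects are shrunk.
* **Bayesian Lasso** — `v_j = tau2_j ~ Exponential(lambda2/2)` and
  `lambda2 ~ Gamma(a, b)` with a = 0.05, b = 1.0, making the prior on
  `lambda` essentially flat over a wide range.  Marginally each effect is
  Laplace; the per-marker variances are *not* scaled by `sigma2_e`, which
  follows the QTL-mapping formulation of this hierarchy rather than the
  Park–Casella one, and therefore does not guarantee a unimodal joint
  posterior.  This is a documented property of the model, not a defect to
  be corrected.

Only additive effects are modelled; the genotype codes 0/1/2 count copies
of an arbitrary per-marker reference allele.

## Gibbs sampler

One iteration draws, in order:

1. `mu` from its normal full conditional (via the residual vector);
2. every `beta_j`, j = 1..m in fixed map order, from
   `N(C_j^-1 r_j, C_j^-1)` with `C_j = x_j'x_j/sigma2_e + 1/v_j` and
   `r_j = x_j' e_partial / sigma2_e` — Gauss–Seidel with residual update,
   so no m × m system is ever assembled; a random update order is
   available by flag but off by default for reproducibility;
3. `sigma2_e ~ scaled-Inv-chi2(n, e'e/n)`;
4. the variance layer: `v_j ~ scaled-Inv-chi2(nu + 1, (nu s2 + beta_j^2)/(nu + 1))`
   for the inverse-chi-square methods, or
   `1/tau2_j ~ InvGauss(sqrt(lambda2)/|beta_j|, lambda2)` followed by
   `lambda2 ~ Gamma(a + m, b + sum(tau2_j)/2)` for the lasso;
5. Student-t only: `s2` from its truncated-Gamma full conditional
   (shape `m nu/2 + 1/2`, the 1/2 coming from the uniform-on-s prior),
   sampled by inverse CDF; then one Metropolis update of `nu` as a
   reflecting Gaussian random walk on `u = 1/nu` in (0, 1] (the prior is
   uniform in u, so the u-space target is the likelihood alone).

Default protocol: one chain of 15 000 iterations, 5 500 burn-in, every
30th state stored (317 stored states); posterior summaries are plain
averages of the stored post-burn-in states.  Convergence is monitored by
initial-positive-sequence (Geyer) effective sample size on the stored
variances, with the initial-monotone correction, plus the Metropolis
acceptance rate for `nu`.

### Numerical choices

* Residuals are maintained incrementally by every update and re-synced
  from `y - mu - X beta` every 1000 iterations to shed rounding drift
  (the identity is verified to < 1e-8 in tests).
* The marker sweep is a numba kernel; the normal deviates for a sweep are
  pre-drawn from the chain's single `numpy` Generator, so chains are
  bit-reproducible given the seed.
* `|beta_j|` is floored at 1e-8 before forming the inverse-Gaussian mean
  (the conditional degenerates as `beta_j -> 0`); inverse-Gaussian draws
  use the Michael–Schucany–Haas transformation.
* `sigma2_e` and variance draws are floored at 1e-12 for the degenerate
  zero-residual case.
* A zero-variance genotype column reduces the effect conditional to its
  prior (handled explicitly in the kernel).
* Initialisation: `mu = mean(y)`, `beta = 0`, `sigma2_e = var(y)/2`,
  `v_j = 0.01 var(y)/m`, `nu = 4`, `s2` at its prior scale,
  `lambda2 = a/b`.  These are neutral; with the default protocol the
  burn-in dwarfs any transient.

### Hyperparameter defaults

* Bayes-A: `nu = 4.012`; `s2` is derived so that the prior mean of `v_j`
  equals an expected per-marker variance, by default half the phenotypic
  variance divided by `2 * sum_j p_j(1 - p_j)` computed from the observed
  codes — the standard conversion between a genetic variance and a
  per-marker effect variance.  Both are exposed in `ChainConfig`; the
  historical choice this emulates is data-dependent and not recoverable,
  so the heuristic is the package's own default.
* Student-t: `A = 1000 * sd(y)` (units of the trait), Metropolis step
  0.05 on the 1/nu scale (acceptance rates in the 0.6–0.9 range at the
  default scale; configurable).
* Lasso: `a = 0.05`, `b = 1.0`.

A consequence of the Bayes-A heuristic worth knowing: the adaptive
Student-t model typically *estimates* heavier shrinkage than the fixed
Bayes-A prior provides on architectures with a few large QTL, so
Student-t shrinks small effects hardest of the three while the Lasso
shrinks them least.  The test suite asserts the robust part of this
ordering (Lasso retains the most small-QTL signal).

### Proper-prior surrogates

For simulation-based calibration testing (forward prior-predictive draws
versus a Gibbs chain coupled with data regeneration), the improper priors
on `mu` and `sigma2_e` are replaced by `N(0, sigma2_mu)` and
`scaled-Inv-chi2(nu0, s0^2)` surrogates via `ChainConfig.mu_prior_var`
and `ChainConfig.sigma2_e_prior`; the production defaults remain
improper.

## Synthetic populations

The generator emulates the livestock method-comparison design the
analysis assumes:

* **Pedigree** — 5 sires, 20 dams, 2000 offspring by default; each dam is
  mated to exactly one sire, dams split evenly over sires and offspring
  evenly over dams, giving 20 full-sib families of 100 nested in 5
  half-sib sire groups.  (The counts are configurable; the mating design
  produces the full/half-sib mixture the low-density analysis relies on.)
* **Genome** — 453 SNPs approximately equally spaced on five 1-Morgan
  chromosomes.  Founders draw Hardy–Weinberg genotypes at configurable
  allele frequencies (default 0.5) in linkage equilibrium; gametes
  recombine by Haldane's map function (no interference), chromosomes
  independent.  There is no mutation, selection, or historical LD — the
  low between-marker LD matches the assumption under which evenly spaced
  sparse panels are expected to predict poorly.
* **Trait** — ten QTL by default, at random marker positions, with
  effects drawn from a reflected gamma (shape 0.4: a few large, many
  small) and rescaled so that the true-breeding-value standard deviation
  is 10 % of the base asymptote.  Effects act on the Gompertz asymptote,
  so the five time points (t0, t132, t265, t397, t530) are genetically
  correlated measures of one architecture.  I.i.d. Gaussian noise per
  time point is sized to hit the target heritability (default 0.5) at the
  last time point.  True breeding values satisfy
  `TBV_i = sum_q effect_q * code_iq` exactly and are recorded for all
  individuals.
* **Phenotyping** — alternate offspring within each family form the
  phenotyped (training) half, so training and prediction sets both span
  every family.

What passing tests on these populations do **not** show: behaviour under
real ascertained SNP panels, historical LD, multi-generation selection,
non-additive architectures, or the particular generating model of any
external dataset.  The qualitative contrasts (effect-selected versus
evenly spaced panels, genotype-probability fill-in, the EBV-confounding
artifact below) are structural and transfer; exact accuracy values are
specific to the generator settings.

## Growth curves

Each phenotyped individual's five measurements are fitted by bounded
nonlinear least squares (analytic Jacobians) to

* Gompertz: `y(t) = A exp(-b exp(-k t))`
* logistic: `y(t) = A / (1 + b exp(-k t))`

from a deterministic start grid — `A in {max(y), 1.5 max(y)}`,
`k in {0.005, 0.01, 0.02}` per day, `b` solved from `y(0)` — keeping the
best of six starts (early exit on an essentially perfect fit).  The
winner by AIC (ties: BIC, then parameter count, then candidate order)
supplies the t600 extrapolation.  AIC/BIC use the Gaussian-likelihood
forms `n ln(RSS/n) + 2k` and `n ln(RSS/n) + k ln n` with k = 4 (three
curve parameters plus the residual variance) and are recomputable from
the stored RSS; an RSS of exactly zero maps both criteria to -inf.
Non-convergence after all starts returns a flagged fit, not an
exception.  Each individual is fitted independently; no hierarchical
borrowing.

## Pedigree BLUP

The numerator relationship matrix comes from the tabular method
(founders unrelated and non-inbred); its inverse is built directly by
Henderson's rules with Mendelian-sampling variances
`0.5 - 0.25 (F_s + F_d)` using inbreeding from the tabular diagonal.
The animal model has the overall mean as its only fixed effect and is
solved densely through the mixed-model equations with variance ratio
`(1 - h2)/h2`; `h2` defaults to 0.5 from config, with an optional
one-dimensional REML grid search (profiled total variance) when it is
unknown.  Dense solves are adequate to a few thousand individuals.
Solutions are verified against direct GLS on
`V = Z A Z' s2a + I s2e` in the tests.

## Genotype probabilities

Single-locus iterative peeling: each marker is processed independently,
combining anterior information (parents, and full sibs through them) and
posterior information (mates and offspring) in repeated passes over the
nuclear families until the largest probability change is below 1e-8
(cap 50 rounds).  Founders carry Hardy–Weinberg priors at per-marker
allele frequencies estimated from genotyped founders when at least ten
are available, otherwise from all genotyped individuals, clamped to
[0.01, 0.99].  Observed individuals are exact point masses; observed
data that are Mendelian-impossible raise an error naming the trio.
The contract is defined by exhaustive enumeration: on loop-free
pedigrees the iterated probabilities match the brute-force marginal to
1e-6 (tested up to 6 unobserved members, where enumeration is cheap).
With inbreeding loops iterative peeling is an approximation — a known
limitation, acceptable here because the simulated design is loop-free.

Ungenotyped entries enter GEBV as expected dosages
`P(het) + 2 P(hom)`; observed entries keep their integer codes.

## Low-density scenarios

Twelve scenarios cross panel choice (EVEN: evenly spaced; SIG: largest
absolute posterior effects, per method and trait), panel size
(19, 38, 76) and genotype-probability fill-in (off: only the panel's
effects are used; on: all 453 effects are used, with expected dosages
for the 434/415/377 non-panel markers).  "Evenly spaced" is defined as
the nearest markers to the quantile centres `(i - 0.5)/m` of cumulative
map length (ties to the lower index, duplicates stepping to the next
unused marker); an index-stride rule is available by flag.  Effect
selection breaks ties by lower marker index.  GEBV omit the intercept —
all downstream metrics are location-invariant.  Scenario GEBV always
reuse the full-density training effects; retraining on a subset is
rejected by construction.

## Evaluation

Accuracy is the Pearson correlation of GEBV with a reference (pedigree
EBV, or TBV when truth is available); bias is the slope of the
regression of the reference on the GEBV.  Cross-validation retrains on
random 90 % splits of the phenotyped set (10 replicates by default,
same chain settings as the main run) and scores the held-out tenth.
One tidy CSV (method × trait × scenario × metric) plus a JSON summary
form the report; deltas against the full panel are stored explicitly
and recompute exactly from the stored accuracies.

A structural artifact the pipeline reproduces and that users should
expect: with full-sib families and sparse evenly spaced panels filled by
genotype probabilities, prediction-set GEBV collapse toward family means
and therefore correlate far better with pedigree EBV (which are also
family-level for unphenotyped animals) than with true breeding values.
Accuracy against EBV overstates accuracy against truth in exactly the
scenarios where genotype probabilities carry most of the design — the
reason the evaluation reports both references.

## Problem sizes

Default study conditions (and the sizes `scripts/acceptance.py` runs):
2025 individuals, 1000 training records, 453 markers, full
15 000-iteration chains for three methods and two traits.  The test
suite uses smaller populations (40–800 offspring, 20–453 markers) and
shorter chains for the distributional oracles, sized so each check's
Monte-Carlo error is well below the tolerance it asserts.

## Known limitations

* Single trait, single chain; no multi-trait models, no Bayes-B/C-style
  variable selection, no GBLUP comparator.
* Variance components for the reference EBV are taken from config (or
  the grid REML), not jointly estimated with the marker models.
* Iterative peeling is single-marker and approximate under inbreeding
  loops; no haplotype or LD-based imputation.
* The lasso posterior may be multimodal (unscaled variance hierarchy);
  posterior means remain well-defined and are what the GEBV use.
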