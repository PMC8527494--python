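# Methods

## Model

All five models are instances of the linear mixed model for a single
continuous trait measured once per animal:

    y_i = x_i' b + g_i + e_i,        e_i ~ N(0, sigma2_e)

with `x_i` an intercept plus reference-coded dummies for herd and sex
(permanent-environment effects are not modeled because animals are
measured once). The genetic value is parameterized either through marker
effects, `g_i = sum_j w_ij alpha_j` with `w_ij = dosage_ij - 2 p_j`
(centering by twice the counted-allele frequency of the analyzed sample),
or through individual breeding values `u ~ N(0, G sigma2_a)` with the
VanRaden (method 1) relationship matrix

    G = W W' / (2 sum_f p_f (1 - p_f)).

The scalar denominator puts `sigma2_a` on the scale of additive genetic
variance in the base defined by the sample frequencies; the package keeps
it on the GRM object so marker-effect and breeding-value variances can be
converted exactly (`sigma2_alpha = sigma2_a / denominator`), which is also
what the GBLUP-ridge equivalence test exploits. `G` is invariant to which
allele is counted at each marker; the counted-allele frequency (not the
folded MAF) must be used for centering so that the columns of `W` sum to
zero.

Prior families on the marker effects:

* **ridge / GBLUP** — `alpha_j ~ N(0, sigma2_alpha)` with a common
  variance; GBLUP is the same model expressed through `G` and sampled in
  its eigenbasis (one `eigh` up front; coordinates are conditionally
  independent given the variances). Numerically negative eigenvalues
  beyond `1e-8` of the largest are clamped to zero and excluded from the
  variance update (logged).
* **BayesA** — per-marker variances `sigma2_j ~ ScInv-chi2(nu, S)`;
  marginally a scaled t prior.
* **BayesB** — `alpha_j = 0` with probability `pi` (default 0.95, fixed;
  estimable under Beta(1,1) on request), scaled t otherwise. The
  inclusion indicator is sampled from the marginal likelihood ratio with
  the effect integrated out; variances of excluded markers are refreshed
  from their prior so the hierarchy stays proper.
* **BayesCpi** — point mass at zero plus a *common* normal variance for
  included markers; `pi` estimated with a Beta(1,1) prior. Marginalizing
  the common ScInv-chi2 variance makes the slab t-distributed, which is
  the t-mixture reading of this family.
* **Bayesian LASSO** — the Park-Casella exponential scale mixture in its
  unconditional form: `alpha_j | tau2_j ~ N(0, tau2_j)`,
  `tau2_j ~ Exp(lambda2/2)`, `lambda2 ~ Gamma(shape, rate)` sampled by
  conjugacy; `1/tau2_j` has an inverse-Gaussian full conditional. We use
  the unconditional rather than the sigma2_e-scaled hierarchy because the
  scaled variant couples `sigma2_e` to all m augmented scales (its update
  gains m degrees of freedom of prior reinforcement), which in m >> n
  problems inflated the residual variance and biased heritability
  downward in our matched-architecture recovery experiments; with the
  unconditional form the sampled `lambda2` concentrates on the value
  implied by the simulated effect scale.

Fixed effects have flat priors; all variances have scaled-inverse-chi2
priors with `nu = 5`.

### Hyperparameter defaults

Prior scales follow an assumed-R2 heuristic (default `R2 = 0.5`): the
prior *mode* of the residual variance is `(1-R2) Var(y)` and of the
genetic variance `R2 Var(y)`, the latter spread over markers through
`MSx = sum_j var(w_j)` (so the per-marker target is `R2 Var(y)/MSx`,
inflated by `1/(1-pi)` for point-mass families). For the LASSO,
`Var(alpha) = 2/lambda2` gives `lambda2_hat = 2 MSx / (R2 Var(y))`; the
Gamma hyperprior has shape 1.1 with its mode at `lambda2_hat`.

For BayesA and BayesB the scale `S` is itself learned through a conjugate
Gamma hyperprior whose mode sits at the heuristic value. With m >> n the
data cannot update per-marker variances individually, so a *fixed* `S`
acts as a hard floor on the realized genetic variance
(`~ MSx * E[sigma2_j]` regardless of the data); learning `S` removes the
floor and is what makes BayesA/B heritability estimates track the truth.

### Missing phenotypes, heritability, GEBVs

Candidate (validation) animals stay in the sampler with `y` missing and
are redrawn from the current model each iteration — exact data
augmentation, matching the practice of setting candidate phenotypes to NA
rather than refitting without them. Heritability is summarized draw by
draw as `sigma2_a / (sigma2_a + sigma2_e)`; for marker models `sigma2_a`
at a draw is the realized variance of the genetic values `W alpha` at that
draw. GEBVs are posterior means: `W_new alpha_bar` for marker models
(`W_new` centered with *training* frequencies) and the posterior mean of
`u` for GBLUP.

MCMC defaults are 15000 iterations, 5000 burn-in, thinning 5, one chain;
the tests use much shorter chains on small problems. Chains are exactly
reproducible given a seed. In debug mode the sampler verifies at every
stored iteration that the maintained residual equals `y - Xb - g` to
1e-8.

## Quality control

Filters run in a fixed order — non-autosomal (sheep autosomes "1"-"26";
"X", "Y", "MT" recognized for exclusion), call rate, MAF, exact HWE — so
the per-filter attribution in the QC report is deterministic. Removal is
by strict inequality ("below" the threshold), so a marker exactly at
call-rate 0.95, MAF 0.01 or HWE p 1e-6 is kept. The HWE test is the exact
conditional test (probability-ordering two-sided p-value over all
heterozygote counts compatible with the observed allele counts), computed
with the standard ratio recurrence; the chi-square approximation is
unreliable at the 1e-6 tail this filter uses. MAF and HWE use the
non-missing genotypes of markers that survived the call-rate filter.

Sporadic missing genotypes (at most a few percent after QC) are filled
from per-marker allele frequencies: expected dosage `2p` (default,
fractional values allowed downstream) or a Binomial(2, p) draw. This
deliberately replaces haplotype-based imputation: the downstream models
need a complete dosage matrix, not phased haplotypes, and at these
missingness levels the difference is negligible for variance components
and accuracy.

## Cross-validation

`k`-fold (default 5) with replicates (default 3): each replicate draws a
fresh uniformly random partition into folds whose sizes differ by at most
one (821 animals -> 165+164x4). For each fold, the fold members'
phenotypes are masked and the model refit; accuracy is
`cor(GEBV, y*)` on the fold, with `y* = y - X b_hat` using the
*training-fold* posterior-mean fixed effects — correcting with full-data
estimates would leak validation phenotypes into their own correction (a
full-data option exists for comparison). The final accuracy is the mean
of all k x replicates fold values; its SE across those values is
reported. Factor levels absent from a training fold are mapped to the
reference level for the validation design (logged). Replicate r uses fold
seed `seed + r`, so paired comparisons across datasets can share the
partition sequence. For marker models the validation rows of `W` are
centered with training-fold frequencies; GBLUP uses a single `G` built
from the full analyzed sample, as is standard when all animals are
genotyped together.

## Synthetic data generator

The generator emulates the structure of a single-station fine-wool sheep
study: ~821 animals in 7 balanced herds, two sexes (Bernoulli(0.5)), a
high-density autosomal SNP panel with a nested low-density subset (every
k-th marker, the way a 50K array's sites sit inside a denser array),
sporadic missingness, and a single additive trait.

* **Frequencies** — truncated Beta(a, b) on [0.01, 0.99] (default
  Beta(1,1): array-ascertained common variants, not a sequencing site
  spectrum). Frequencies are drawn through a Gaussian AR(1) copula with
  lag correlation `ld_rho`, which preserves the truncated-Beta marginal
  exactly while making adjacent frequencies locally similar — necessary,
  because two Bernoulli alleles can only correlate strongly when their
  frequencies are close, so independent frequencies would cap attainable
  LD well below the target.
* **LD** — first-order Markov haplotypes: allele j is Bernoulli with mean
  shifted linearly by allele j-1 to give adjacent-allele correlation
  `ld_rho`; two independent haplotypes sum to the dosage, so the
  adjacent-genotype correlation matches. Default `ld_rho = 0.85`,
  appropriate for a dense panel with few-kb spacing in a livestock
  population (long-range LD, small effective population size); the
  realized correlation is attenuated ~10 % at that level by feasibility
  clipping, and is essentially exact at low values.
* **Architectures** — `normal`, `t` (df 5), `laplace` for
  all-markers-affect traits; `point_normal` / `point_t` place exactly
  `round(prop_qtl * m)` nonzero effects. Each matches one prior family,
  which is what the recovery tests exploit.
* **Phenotypes** — `y = mu + herd + sex + BV + e`, with BV the centered
  dosages times the effects (exact, kept in the truth record). The
  residual variance is calibrated to the *realized* Var(BV) so that the
  realized heritability equals `h2_target` exactly for every dataset —
  this makes recovery tests sharp instead of confounded by effect-sampling
  noise. Herd effects are normal with SD `herd_sd` (default 0.3) and the
  male offset is `sex_effect` (default 0.2), both in phenotypic-SD units.

What the generator does *not* emulate: family/pedigree structure (animals
are unrelated beyond chance allele sharing), genotyping error, selection,
dominance or epistasis, and population stratification. Consequently the
simulated G has near-zero off-diagonals, and heritability information
comes only from fine relatedness fluctuations — its precision scales
roughly with n²/m_effective, which is why the bundled experiments use
strong LD and moderate marker counts. Passing tests demonstrate the
estimators are correct under the assumed additive model, not that real
datasets are free of these additional complications.

## Problem sizes in the bundled experiments

Heritability recovery: n = 600, m = 1200, h2 targets {0.3, 0.5, 0.7},
three replicate datasets per model x target, chains 5000/2000/4. The
h2-accuracy ordering check: n = 400, m = 800, fivefold, paired datasets at
h2 0.3 vs 0.7. Sampler distribution checks run on deliberately tiny
problems (n = 30, m = 20) with long thinned chains. These sizes keep the
full experiment battery in the minutes range on one core while leaving
each check statistically sharp; all tolerances are stated in the tests
themselves.

## Numerical and degenerate-case choices

* Markers with zero variance are dropped from the GRM denominator (or
  rejected, configurable); an all-monomorphic panel is an error.
* Collinear design columns (confounded factor levels) are dropped
  greedily, keeping the intercept; single-level factors collapse into the
  intercept.
* A phenotype vector with zero variance is rejected; accuracy on a
  zero-variance GEBV or y* vector raises rather than silently returning 0.
* The inclusion-probability logistic in BayesB/Cpi clips pi to
  [1e-12, 1-1e-12]; the inverse-Gaussian sampler floors its draw at 1e-12;
  a LASSO effect numerically at zero redraws its scale from the
  exponential prior.
* `simulate_effects` with all-zero effects yields zero BVs and realized
  h2 = 0 with unit residual variance.
* Seeds must fit in an unsigned 32-bit integer (numba RNG); derived seeds
  in the pipeline and acceptance script stay below 2^31.

## Known limitations

* Single trait, single chain, additive effects only; no REML fallback.
* BayesB with estimated pi mixes slowly on strongly LD-structured panels;
  the default keeps pi fixed.
* The Bayesian LASSO retains a mild downward heritability bias at low h2
  (strong one-sided shrinkage of many small effects); it stays within the
  recovery tolerance used here but is the least accurate variance
  estimator of the five.
* The exact HWE test assumes hard-called genotypes; QC must precede
  imputation (enforced).
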