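# Methods

## The model

Each analysed trait is either an ordered categorical score (angular hoof
defects scored 0/1/2 under the three-category coding, 0/1 under the
dichotomous coding; optionally a 1–9 tendon-diameter scale) or a continuous
measurement (the proportionality index). Ordinal scores are modelled with a
liability threshold model: an unobserved Gaussian liability

    l = X b + Z u + e,        u ~ N(0, G ⊗ A),     e_i ~ N(0, R)

is cut at ordered thresholds to produce the observed category. `X` carries
the fixed effects (sex, birth-stud size) and centred linear covariates
(evaluation age in years, Wright's inbreeding coefficient F); `Z` is the
animal incidence; `A` is the pedigree-based numerator relationship matrix;
`G` and `R` are the additive-genetic and residual covariance matrices
across traits. Continuous traits enter the same multivariate system with
their observed values as "liabilities". Each animal carries at most one
record per trait (the underlying assessment happens once in a lifetime), so
no permanent-environment effect is fitted.

Heritability is reported on the liability scale as
h² = σ²_u / (σ²_u + σ²_e), and genetic correlations as
r_g = G_ij / √(G_ii G_jj).

## Pedigree algebra

* Inbreeding coefficients use the Meuwissen–Luo recursion (per-animal
  accumulation of the diagonal of A over ancestor paths), O(pedigree depth)
  per animal and exact.
* The dense A (tabular method) exists only below a configurable cap
  (default 5,000 animals) and is used for oracles and small problems.
* The sampler consumes only the sparse inverse of A, assembled in one
  pedigree pass by Henderson's rules with the inbreeding-correct
  Mendelian-sampling variances d_i = 0.5 − 0.25(F_s + F_d) (0.75 − 0.25 F
  with one known parent, 1 with none). Unknown parents are treated as
  unrelated, non-inbred founders; animals appearing only as parents are
  added as founders.

## Gibbs sampler

Per iteration, in fixed order:

1. **Liabilities.** Each ordinal record's liability is drawn from a normal
   conditioned on its linear predictor and on the animal's residuals for
   the other traits (through R), truncated to its category's threshold
   interval (inverse-CDF draw with probability floors of 1e−12 against
   degenerate intervals). Liabilities of trait-wise *missing* cells are
   sampled unconstrained; this data augmentation keeps every record
   complete across traits so the R update stays a single inverse-Wishart.
   Observed Gaussian cells are never resampled.
2. **Location.** Fixed effects are drawn column-wise from their Gaussian
   full conditionals (flat prior). Breeding values are drawn animal by
   animal in a sequential Gauss–Seidel sweep from the mixed-model-equation
   full conditionals, whose precision is `has_record·R⁻¹ + A⁻¹_aa·G⁻¹`; the
   inner loop is a numba kernel with a hand-rolled T×T Cholesky (T ≤ 6).
3. **Thresholds.** The first cutpoint of every ordinal trait is fixed at 0.
   Interior cutpoints (three or more categories) are drawn uniformly
   between the extreme liabilities of the adjacent categories; when an
   adjacent category is empty the neighbouring thresholds bound the
   interval (logged), and an unbounded side falls back to a width-3 window.
4. **G** from the inverse-Wishart full conditional with scale
   `S0_G + U'A⁻¹U` and degrees of freedom `df0_G + n_animals` (all animals,
   phenotyped or not).
5. **R** from the inverse-Wishart with scale `S0_R + E'E` over the
   augmentation-complete residuals.
6. **Identification rescale.** Each ordinal trait's residual variance is
   rescaled to exactly 1, transforming liabilities, u, b, thresholds and
   the G/R rows and columns consistently (correlations are invariant).
   Covariance draws use a direct Bartlett-decomposition construction,
   cross-checked against scipy's inverse-Wishart in the tests; a
   numerically non-PD draw is redrawn, never eigenvalue-clipped.

Binary traits therefore have threshold 0 and residual variance 1; their
heritability is identified on the liability scale. The published analysis
reports variance components in arbitrary software-convention units (its
categorical residual variances are in the hundreds), so only the
scale-free ratios h² and r_g are comparable — which is how all recovery
checks are framed here.

Determinism: one `numpy.random.Generator` seeded from the configuration
drives every draw, so identical data + config + seed give bit-identical
chains. The default schedule matches the source analysis (100,000
iterations, 20,000 burn-in, thin 10 → 8,000 stored draws); tests and the
acceptance script use shorter schedules (stated inline) chosen as the
package's own scaled-down study sizes.

Priors default to inverse-Wishart with df = n_traits + 2 and scale 0.2·I
(G) / 0.8·I (R) — weakly informative and proper — with flat priors on
fixed effects. The sampler-validation studies (prior recovery with no
data, successive-conditional joint test) use df = n_traits + 6 in their
configurations because element variances of the df = p + 2
inverse-Wishart are infinite, which would leave Monte Carlo moment
comparisons undefined.

Two validation caveats are deliberate: the prior-invariance checks run on
Gaussian traits, because the identification rescale changes the marginal
prior on the identified scale for ordinal traits (the ordinal path is
validated instead by truncation-bound tests and binary-trait parameter
recovery); and the model A/B DIC comparison follows the source
convention of comparing DICs across the two codings of the same records,
although the two likelihoods live on different data scales.

## DIC

DIC = 2·mean(D) − D(posterior means), with the observed-data deviance
computed per record and per trait with liabilities integrated out
(differences of normal CDFs for ordinal categories, the normal density for
continuous traits), category probabilities floored at 1e−12. The plug-in
deviance uses posterior means of b, u, thresholds and R.

## Post-Gibbs diagnostics

* **HPD:** exhaustive shortest window over the sorted draws containing
  ⌈0.95·n⌉ draws, leftmost window on ties.
* **Geweke Z:** first 10% vs last 50% of the chain, variances estimated by
  the spectral density at frequency zero (Bartlett-windowed autocovariances
  with lag window ⌊√n⌋).
* **MCSE:** batch means with ⌊√n⌋ batches. Note this estimator itself has
  ~(2·n_batches)^(-1/2) ≈ 7% relative Monte Carlo noise on a single chain;
  calibration tests therefore judge its mean over replicate chains.
* **Sign probability** P≠0 = max(share > 0, share < 0) of a correlation
  chain.
* **EBV percentile overlap:** animals strictly above the 0.8-quantile of
  each model's posterior-mean breeding values; the reported percentage uses
  the first model's top-set size as denominator.

## Risk screen

A baseline-category multinomial logit (binary as the two-class special
case) fitted by full Newton–Raphson with an exact observed-information
Hessian (ridge 1e−10 for numerical safety). Per-effect p-values come from
likelihood-ratio tests against the model with that effect removed.
Diverging coefficients (|β| > 25) stop the iteration and raise a
complete-separation warning rather than an error. statsmodels is used only
as an independent oracle in the tests.

## Synthetic data generator

The generator emulates the structure of the studbook data, and its
defaults are the study's published descriptives:

* Non-overlapping generations, parents drawn from the previous generation;
  mating schemes: random, within-stud assortative (raises inbreeding
  gradually; stud follows the sire), and a full-sib chain (drives F above
  0.25 so the deepest inbreeding bin is populated).
* Breeding values by gene dropping: founders ~ N(0, G); offspring are the
  parent average plus a Mendelian deviation with covariance d_i·G, so
  Var(u_i) = (1 + F_i)·G by construction.
* Liabilities add sex, stud-size, age and F effects plus N(0, R) residuals
  (residual correlations default to 0; the source reports none). Ordinal
  residual variance is 1, so the true liability heritability is exactly
  G_ii/(G_ii + 1).
* Thresholds are either given or calibrated to target category shares via
  the normal inverse CDF on the realised liability mean/s.d. — an
  approximation exact only under normality of the liability mixture, good
  to well under one percentage point here.
* The six-trait default configuration uses the published category shares
  (e.g. 73.39/20.61/5.99% for the splay-footed forelimb), heritabilities
  (0.18/0.20/0.11/0.31 for the defects; 0.076 tendon, 0.348 proportionality
  index), the printed genetic correlations (unprinted pairs — the two
  same-side defect pairs and tendon × index — default to 0; the resulting
  correlation matrix is verified positive definite), per-trait record
  missingness matching the published unequal record counts, the 33.1% male
  share, and a shifted-gamma evaluation age (mean 4.86 y, s.d. 2.25,
  clipped to 2–23). Sex and stud effects and the age/F slopes are modest
  liability-scale values chosen once (the published slope units are not
  portable to the identified scale); the slope signs follow the published
  directions.

What the generator does **not** emulate: overlapping generations,
selection/culling feedback (including the breeder-eligibility rule's
effect on matings), evaluator effects, and non-random missingness. Passing
recovery tests therefore demonstrate correctness of the estimator under
the stated generative model, not robustness to those real-data features.

## Problem sizes

The parameter-recovery study uses 10 replicate populations of 2,000
animals over 5 generations (one binary + one Gaussian trait, true h² =
0.3/0.4, r_g = 0.3) fitted with 20,000 iterations / 4,000 burn-in / thin 4
— the package's scaled-down version of the source's 100,000-iteration
six-trait analysis. The acceptance script re-runs three such replicates,
a 20,000-animal descriptive population, and a 1,500-animal model A/B
comparison.

## Known limitations

* Single-site threshold updates mix slowly for many-category traits with
  large record counts; the analyses here use 2–3 categories where this is
  benign.
* Dense A is quadratic in memory; use the sparse inverse beyond ~5,000
  animals.
* DIC across codings (model A vs B) inherits the source's
  incommensurability; within-coding comparisons (effects in vs out) are
  the statistically clean use.
* The multinomial logit reports asymptotic LR p-values; no small-sample or
  separation-robust (penalised) alternative is provided.
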