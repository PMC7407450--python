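# Methods

`gprisk` implements an end-to-end genomic-prediction workflow for binary
complex traits, motivated by case/control genotyping studies in purebred
dogs (the package's running example is cruciate-ligament rupture in Labrador
Retrievers: prevalence K ≈ 0.0579, liability heritability estimated between
0.3 and 0.5, haplotype blocks of roughly 20 kb).  This note records the
models, the default parameters and the design decisions that were genuinely
open, and states what the synthetic cohorts do and do not establish.

## The liability threshold model

Disease status is modelled through a latent liability
`l = g + Xb + ε`, with `g` the additive genetic score `Σ_j m_ij α_j`
(`m_ij` = minor-allele dosage), `Xb` covariate effects and
`ε ~ N(0, σ²_e)`; an individual is a case when `l` exceeds the threshold
corresponding to prevalence K.  Heritability h² is the share of liability
variance carried by `g`.

Two analytic consequences anchor the package:

* **Maximum AUC of a genomic profile.** A score explaining a fraction ρ² of
  liability variance cannot exceed
  `AUC = Φ( (i−v)ρ² / sqrt(ρ²[(1−ρ²·i(i−T)) + (1−ρ²·v(v−T))]) )`, where
  `T = Φ⁻¹(1−K)`, `z = φ(T)`, `i = z/K`, `v = −z/(1−K)`
  (`evaluate.max_liability_auc`).  At K = 0.0579 this gives 0.86 for
  ρ² = 0.4 and 0.69 for ρ² = 0.1 — the ceiling and a realistic
  partial-variance benchmark for any predictor of this trait.
* **Simulation twin.** A cohort simulated under the generative model with
  h² = 0.4 must place the AUC of its *true* genetic score at that ceiling;
  this closes the loop between generator and theory and is recomputed by
  `scripts/acceptance.py`.

## Synthetic cohorts (`gprisk.simulate`)

The generator emulates the statistical structure the analysis assumes, not
any particular genome:

* **Genotypes.** SNPs come in haplotype blocks (default 10 SNPs spanning
  20 kb).  Per block, 20 founder haplotypes are drawn from a thresholded
  AR(1) Gaussian process whose copula correlation is solved numerically so
  that adjacent-SNP genotype correlation hits `within_block_r` (default
  0.6) after dilution by a 2% per-site copy "mutation".  Individual
  haplotypes copy random founders; blocks are mutually independent and are
  spread over up to 38 chromosomes.  This produces the blocky
  LD that windowed pruning expects, without coalescent machinery.
* **Orientation.** Columns are flipped to count the minor allele using the
  *observed* (post-missingness) frequency — the same rule the PLINK reader
  applies — so write/read round-trips are bit-exact.
* **Liability.** `n_causal` SNPs (default 1000 of 100k) receive Gaussian
  effects rescaled so the realized genetic variance equals h² (default
  0.4).  Covariates: sex ~ Bernoulli(0.5), neuter status ~ Bernoulli(0.7),
  weight ~ N(30, 4²) kg for females and N(34, 4²) for males — plausible
  Labrador constants, configurable.  Default liability effects are 0.04 per
  kg, 0.2 for male sex and 0.4 for neutering.  The residual completes unit
  total variance; a configuration whose genetic plus covariate variance
  exceeds 1 is rejected.
* **Threshold.** Cases are individuals above the realized `(1−K)` liability
  quantile, not the theoretical Normal quantile, so finite cohorts match K
  exactly.

What the simulations do *not* contain: genotyping batch effects, population
stratification or relatedness beyond the shared founder pools, non-additive
genetic effects, covariate–genotype correlation (real dog weight is itself
heritable), and real LD decay profiles.  Tests passing on these cohorts
validate the machinery and its statistical honesty — not clinical accuracy
on real dogs.

## QC and LD pruning (`gprisk.qc`)

Filters run in the fixed order call rate → MAF → exact HWE, so each removed
SNP lands in one category: call rate ≤ 0.95 (exclusive bound), MAF ≤ 0.05
(inclusive — deliberately as stated for array panels of this kind, although
many studies use a strict inequality), exact two-sided Hardy–Weinberg
p < 1e-7.  The HWE test enumerates the conditional distribution of the
heterozygote count given allele totals through the standard probability
recurrence, with no mid-p correction, matching the default of the
genotype-QC tooling this pipeline mirrors.

LD pruning is the `--indep-pairwise 50 5 0.7` idiom: per chromosome, a
50-SNP window advanced 5 SNPs at a time over the currently kept SNPs;
within a window the most-correlated pair above r² = 0.7 (Pearson, on
mean-imputed dosages) loses its lower-MAF member (ties: the later
position); sweeps repeat until a pass removes nothing.  "Window overlap of
5 SNPs" is read as the step-size-5 signature; the alternative literal
reading (step 45) is available by setting `ld_step=45`.  Pruning defaults
to a single pass over the full cohort before fold splitting, mirroring the
workflow this package reproduces; fold-internal pruning is a flag away
(run it on each training fold before ranking).

Missing genotypes are retained in storage and mean-imputed per SNP with
*training-fold* means at model-fitting time; the imputation rule is this
package's choice (the standard one for dosage models).

## Feature selection (`gprisk.features`)

Two filters rank SNPs inside each training fold:

* **Mixed-model GWAS p-value.**  The 0/1 phenotype is treated as
  quantitative — the filter only ranks.  A VanRaden GRM
  (`K = WWᵀ / Σ 2p_j q_j`) is built from the fold's post-QC SNPs; the
  polygenic variance ratio is REML-estimated once per fold on the
  eigendecomposed GRM; every SNP is then scored by a Wald t-test in the
  whitened regression (the EMMAX shortcut).  With `K = I` this reduces
  exactly to OLS, which the tests exploit as an oracle.  Covariates are
  included in the ranking model by default (switchable) — the source
  workflow leaves this unstated.
* **Mean allele-frequency difference** between cases and controls,
  descending; ties break lexicographically by SNP id for cross-platform
  determinism.

Top-k selection supports the grid {5, 10, 25, 100, 750, 4000, 7500, 10000,
12500, 15000}.  Everything is computed from training samples only;
`run_cv(whole_data_selection=True)` deliberately breaks this to demonstrate
the optimistic bias (see Calibration below).

## Bayesian probit regression (`gprisk.bayes`)

Five "Bayesian alphabet" priors on marker effects — BRR (Gaussian, common
variance), Bayesian LASSO (Laplace via exponential scale mixture), BayesA
(scaled-t via per-marker inverse-χ² variances), BayesB (spike + scaled-t
slab), BayesCπ (spike + common-variance Gaussian slab) — share one probit
Gibbs sampler with truncated-Normal data augmentation.  Numerical and
modelling choices:

* Residual variance is fixed at 1 and the threshold γ at 0: neither is
  likelihood-identified, and the free intercept absorbs γ.
* Flat priors on the intercept and covariate effects; π (prior probability
  of *no* effect) gets Beta(P0·π0, P0(1−π0)) with π0 = 0.5, P0 = 10.
* Default scale rules: df = 5 for all scaled-t components; scales solved
  from an R² = 0.5 heuristic against the total marker variance so markers
  explain about half the unit latent variance a priori.  The scaled-t scale
  S is held fixed at its rule value rather than given its own hyperprior —
  a simplification that leaves shrinkage behaviour intact at the cohort
  sizes used here.  The LASSO λ² gets a Gamma hyperprior centred near its
  rule value.
* Dosages are centered (not scaled) with training means; prediction applies
  the same centering and returns plug-in probabilities Φ(η̂) at posterior
  means.  The posterior mean of Φ(η) over kept draws is also stored; the
  two rank samples near-identically.
* Truncated-Normal draws use inverse-CDF sampling with the linear predictor
  clipped to ±6 to keep the Normal CDF out of its saturated tails.
* Chain defaults are 52,000 iterations, 6,000 burn-in, thinning 5; the
  bundled tests and examples run shortened chains (hundreds to a few
  thousand iterations), which the validation oracles show is ample for the
  posterior *means* used in prediction at these problem sizes.
* `alpha_var_fixed` pins the BRR marker variance so the two-parameter
  posterior can be checked against dense 2-D quadrature — a validation
  hook, not a modelling feature.

Sampler validation: an intercept-only fit recovers the case fraction
through Φ(μ̂); a single-SNP fit matches the quadrature posterior mean of α;
spike-and-slab inclusion probabilities shrink below π0 on null data and
separate causal from null SNPs under a sparse architecture.

## Classifiers (`gprisk.classifiers`)

* **wRF** — weighted-subspace random forest: ≥1000 trees (default), each
  grown on a bootstrap sample over a feature subspace of ⌊√p⌋ columns drawn
  with probability proportional to |point-biserial correlation| with the
  class (floored at 1e-6, normalized).  Weighting is per tree rather than
  per node — simpler, and it preserves the method's key idea that
  informative features enter subspaces more often.  The weighting statistic
  is switchable to χ²; `uniform_subspace=True` recovers a plain random
  forest.
* **GBT** — xgboost with learning rate 0.05, γ = 0.3, depth 10, column and
  row subsampling 0.8, binary-error evaluation metric, 1000 rounds, no
  early stopping.
* **NB** — hybrid naive Bayes: categorical likelihoods (Laplace-smoothed)
  for dosage, sex and neuter columns; Gaussian for body weight.
* **KNN** — five nearest neighbours by Euclidean distance on features
  standardized with training-fold statistics; the score is the case
  fraction among neighbours.

Covariates enter as extra columns (sex/neuter as 0/1, weight standardized);
whether to standardize for KNN/NB was an open choice, resolved here as
"always standardize weight, never the dosages".

## Ensembles (`gprisk.ensembles`)

Eight base models = 4 classifiers × 2 selection filters, combined two ways:
**n-agreement** (positive iff ≥ n of 8 binary calls at threshold 0.5 are
positive; n chosen per fold by maximum AUC, ties to smaller n) and
**stacking** (out-of-fold base scores shuffled into 10 fresh folds; a
supervisor — unpenalized logistic regression or a 500-tree random forest —
cross-fitted on the 8-column score matrix).  The 0.5 call threshold and the
supervisor hyperparameters are this package's defaults; the workflow being
reproduced does not state them.

## Cross-validation and calibration (`gprisk.evaluate`)

Folds are seeded, near-equal and stratified by case status by default
(unstratified splitting risks single-class test folds at low prevalence; a
flag restores plain random splits).  Within each fold: rank on training
samples, select top k, impute/standardize with training statistics, fit,
score the held-out fold.  The headline statistic is the mean of per-fold
AUCs with its SD reported both across folds and across the 5 repeats
(published tables of this design are ambiguous about which SD they show, so
both are kept); the AUC of pooled out-of-fold predictions is logged
alongside.

Calibration experiments bundled with the test suite, at sizes chosen to
keep the default run fast (n = 400, p = 2000, shortened chains and
forests; results averaged over six independent null cohorts because a
single finite cohort's CV AUC wobbles around chance by several points even
under the null):

* fold-internal top-5 selection on h² = 0 cohorts keeps every model's mean
  AUC within [0.45, 0.55];
* ranking on the whole cohort first inflates the same null AUC above 0.55 —
  the quantitative case for fold-internal selection;
* the leakage cohorts use prevalence 0.30 rather than 0.0579 so each test
  fold holds enough cases for a stable AUC at n = 400.

The qualitative-pattern tests use a covariate-dominant cohort (covariate
liability effects 0.07/kg, 0.3, 0.6; h² = 0.3), mirroring a study regime in
which the covariate-only baseline out-predicts SNP-only models: adding
covariates must raise CV AUC for wRF, GBT, NB and all five Bayesian models,
and the five Bayesian means must lie within one fold-SD of each other.

## Known limitations

* The LMM filter is linear-on-0/1, adequate for ranking but not for effect
  estimation or significance claims.
* Gibbs updates are single-site; very large p with long chains is slow in
  this pure-NumPy implementation (the defaults above are recorded, not
  routinely run in the test suite).
* Real-data idiosyncrasies (stratification, relatedness, batch effects) are
  outside the generator, so CV numbers on synthetic cohorts bound what the
  machinery can do, not what field data will give.
* `hwe_exact_p` is exact for the two-sided "no more probable" definition
  only; mid-p variants are not provided.
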