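"""Cross-validation orchestration, AUC scoring and the liability-scale AUC bound.

The headline statistic throughout is the Mann-Whitney AUC: the probability
that a randomly chosen case outscores a randomly chosen control, with ties
counted half.  Model comparison follows a repeated, stratified 10-fold design
in which every data-dependent choice (SNP ranking, imputation means, feature
standardisation) is made inside the training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io_plink import GenotypeMatrix, mean_impute


# ---------------------------------------------------------------------------
# AUC


def auc(scores, labels) -> float:
    """Mann-Whitney AUC of ``scores`` against binary ``labels``.

    Equals (concordant pairs + 0.5 * tied pairs) / (n_case * n_control),
    computed via midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_case = int((labels == 1).sum())
    n_ctrl = int((labels == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("AUC requires at least one case and one control")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[labels == 1].sum() - n_case * (n_case + 1) / 2.0
    return float(u / (n_case * n_ctrl))


# ---------------------------------------------------------------------------
# Liability-threshold maximum AUC


def max_liability_auc(K: float, rho2: float) -> float:
    """Maximum achievable AUC of a genomic profile under the liability model.

    ``K`` is the population prevalence and ``rho2`` the proportion of
    liability variance the profile explains.  With T = Phi^-1(1-K),
    z = phi(T), case mean i = z/K and control mean v = -z/(1-K) of the
    truncated liability, the bound is

        AUC = Phi( (i - v) rho^2 / sqrt( rho^2 [ (1 - rho^2 i (i - T))
                                               + (1 - rho^2 v (v - T)) ] ) ).
    """
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must be in (0,1); got {K}")
    if not (0.0 <= rho2 <= 1.0):
        raise ValueError(f"variance explained rho2 must be in [0,1]; got {rho2}")
    if rho2 == 0.0:
        return 0.5
    T = norm.ppf(1.0 - K)
    z = norm.pdf(T)
    i = z / K
    v = -z / (1.0 - K)
    num = (i - v) * rho2
    den = np.sqrt(rho2 * ((1.0 - rho2 * i * (i - T)) + (1.0 - rho2 * v * (v - T))))
    return float(norm.cdf(num / den))


# ---------------------------------------------------------------------------
# Folds


@dataclass
class FoldPlan:
    """Partition of samples into k folds, fixed for all models within a repeat."""

    assignments: np.ndarray  # fold index in {0..k-1} per sample
    k: int
    seed: int
    repeat: int = 0

    def test_index(self, fold: int) -> np.ndarray:
        return np.where(self.assignments == fold)[0]

    def train_index(self, fold: int) -> np.ndarray:
        return np.where(self.assignments != fold)[0]


def make_folds(labels, k: int = 10, seed: int = 0, stratify: bool = True,
               repeat: int = 0) -> FoldPlan:
    """Seeded random partition into k near-equal folds, stratified by class by default."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    if stratify:
        # round-robin continues across classes so total fold sizes differ by <= 1
        start = 0
        for cls in np.unique(labels):
            idx = np.where(labels == cls)[0]
            idx = rng.permutation(idx)
            assignments[idx] = (start + np.arange(len(idx))) % k
            start += len(idx)
    else:
        perm = rng.permutation(n)
        assignments[perm] = np.arange(n) % k
    return FoldPlan(assignments=assignments, k=k, seed=seed, repeat=repeat)


# ---------------------------------------------------------------------------
# Covariate design matrix helpers


def covariate_design(samples: pd.DataFrame, standardize_with: dict | None = None
                     ) -> tuple[np.ndarray, dict]:
    """Numeric design matrix for (sex, neutered, weight).

    Sex and neuter status enter as 0/1 indicators, weight standardized with
    training-fold mean/SD.  ``standardize_with`` carries the training
    statistics when transforming held-out samples.
    """
    sex = samples["sex"].map({"female": 0.0, "male": 1.0}).to_numpy(dtype=float)
    neut = samples["neutered"].map({"intact": 0.0, "neutered": 1.0}).to_numpy(dtype=float)
    weight = samples["weight"].to_numpy(dtype=float)
    if standardize_with is None:
        mu, sd = float(np.nanmean(weight)), float(np.nanstd(weight))
        sd = sd if sd > 0 else 1.0
        standardize_with = {"weight_mean": mu, "weight_sd": sd}
    w = (weight - standardize_with["weight_mean"]) / standardize_with["weight_sd"]
    X = np.column_stack([sex, neut, w])
    return X, standardize_with


# ---------------------------------------------------------------------------
# CV result container


@dataclass
class CVResult:
    """Per-fold AUCs with repeat-level aggregation."""

    fold_aucs: list = field(default_factory=list)       # list of lists, one per repeat
    aggregated_aucs: list = field(default_factory=list)  # AUC of pooled out-of-fold scores
    oof_scores: list = field(default_factory=list)       # per-repeat out-of-fold score vectors
    metadata: dict = field(default_factory=dict)

    @property
    def repeat_means(self) -> np.ndarray:
        return np.array([float(np.mean(f)) for f in self.fold_aucs])

    @property
    def mean_auc(self) -> float:
        return float(np.mean(np.concatenate([np.asarray(f) for f in self.fold_aucs])))

    @property
    def sd_across_repeats(self) -> float:
        m = self.repeat_means
        return float(np.std(m, ddof=1)) if len(m) > 1 else float("nan")

    @property
    def sd_across_folds(self) -> float:
        allf = np.concatenate([np.asarray(f) for f in self.fold_aucs])
        return float(np.std(allf, ddof=1)) if len(allf) > 1 else float("nan")

    def summary(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "sd_folds": self.sd_across_folds,
            "sd_repeats": self.sd_across_repeats,
            "aggregated_auc_mean": float(np.mean(self.aggregated_aucs)),
            **self.metadata,
        }


# ---------------------------------------------------------------------------
# CV driver


def run_cv(geno: GenotypeMatrix, samples: pd.DataFrame, model,
           selection: str | None = None, k_snps: int | None = None,
           include_covariates: bool = False, n_folds: int = 10,
           repeats: int = 5, seed: int = 0, stratify: bool = True,
           selection_kwargs: dict | None = None,
           whole_data_selection: bool = False) -> CVResult:
    """Repeated k-fold cross-validation with fold-internal feature selection.

    ``model`` is anything exposing ``fit(X_snps, X_cov, y, seed)`` and
    ``predict(X_snps, X_cov)`` (see :mod:`gprisk.bayes` and
    :mod:`gprisk.classifiers` adapters).  ``selection`` is ``"gwas_p"``,
    ``"mean_diff"`` or ``None`` (use all SNPs, the Bayesian whole-genome
    setting).  ``whole_data_selection=True`` deliberately breaks the
    leakage guard by ranking SNPs on the full cohort once — provided only to
    demonstrate the optimistic bias this induces.
    """
    from . import features as fs  # deferred: avoids import cycle at package init

    y = samples["phenotype"].to_numpy()
    if np.isnan(y.astype(float)).any():
        raise ValueError("phenotype contains missing values")
    y = y.astype(int)
    selection_kwargs = selection_kwargs or {}

    leaked_ids = None
    if whole_data_selection and selection is not None:
        ranked = _rank(geno, samples, y, np.arange(len(y)), selection, selection_kwargs)
        leaked_ids = fs.select_top_k(ranked, k_snps)

    result = CVResult(metadata={
        "model": getattr(model, "name", type(model).__name__),
        "selection": selection, "k_snps": k_snps,
        "covariates": include_covariates, "repeats": repeats, "folds": n_folds,
    })
    snp_pos = {s: i for i, s in enumerate(geno.snp_ids)}

    for rep in range(repeats):
        plan = make_folds(y, k=n_folds, seed=seed * 1000 + rep, stratify=stratify, repeat=rep)
        fold_aucs = []
        oof = np.full(len(y), np.nan)
        for fold in range(n_folds):
            tr, te = plan.train_index(fold), plan.test_index(fold)
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                warnings.warn(f"fold {fold} single-class; skipped")
                continue
            if selection is None:
                col_idx = np.arange(geno.n_snps)
            elif leaked_ids is not None:
                col_idx = np.array([snp_pos[s] for s in leaked_ids])
            else:
                ranked = _rank(geno, samples, y, tr, selection, selection_kwargs)
                ids = fs.select_top_k(ranked, k_snps)
                col_idx = np.array([snp_pos[s] for s in ids], dtype=int)

            dos = geno.dosages[:, col_idx] if len(col_idx) else np.empty((len(y), 0))
            Xtr, means = mean_impute(dos[tr])
            Xte, _ = mean_impute(dos[te], means=means)
            if include_covariates:
                Ctr, stats = covariate_design(samples.iloc[tr])
                Cte, _ = covariate_design(samples.iloc[te], standardize_with=stats)
            else:
                Ctr = Cte = None
            fit_seed = (seed * 100003 + rep * 101 + fold) % (2**31 - 1)
            fitted = model.fit(Xtr, Ctr, y[tr], seed=fit_seed)
            scores = fitted.predict(Xte, Cte)
            oof[te] = scores
            fold_aucs.append(auc(scores, y[te]))
        result.fold_aucs.append(fold_aucs)
        result.oof_scores.append(oof)
        ok = ~np.isnan(oof)
        result.aggregated_aucs.append(auc(oof[ok], y[ok]))
    return result


def _rank(geno, samples, y, train_idx, selection, selection_kwargs):
    from . import features as fs

    sub = geno.subset_samples(train_idx)
    if selection == "mean_diff":
        return fs.mean_diff_rank(sub, y[train_idx])
    if selection == "gwas_p":
        covs = selection_kwargs.get("covariates")
        C = None
        if covs:
            C, _ = covariate_design(samples.iloc[train_idx])
        X, _ = mean_impute(sub.dosages)
        K = fs.grm(sub)
        return fs.lmm_gwas(sub, y[train_idx].astype(float), C, K, imputed=X)
    raise ValueError(f"unknown selection method {selection!r}")


def covariate_logistic_baseline(samples: pd.DataFrame, n_folds: int = 10,
                                repeats: int = 5, seed: int = 0) -> CVResult:
    """10-fold CV of a plain logistic regression on sex, neuter status and weight."""
    from sklearn.linear_model import LogisticRegression

    y = samples["phenotype"].to_numpy().astype(int)
    result = CVResult(metadata={"model": "covariate_logistic", "selection": None,
                                "k_snps": 0, "covariates": True,
                                "repeats": repeats, "folds": n_folds})
    for rep in range(repeats):
        plan = make_folds(y, k=n_folds, seed=seed * 1000 + rep, repeat=rep)
        fold_aucs = []
        oof = np.full(len(y), np.nan)
        for fold in range(n_folds):
            tr, te = plan.train_index(fold), plan.test_index(fold)
            Ctr, stats = covariate_design(samples.iloc[tr])
            Cte, _ = covariate_design(samples.iloc[te], standardize_with=stats)
            clf = LogisticRegression(C=np.inf, max_iter=1000)  # unpenalized
            clf.fit(Ctr, y[tr])
            scores = clf.predict_proba(Cte)[:, 1]
            oof[te] = scores
            fold_aucs.append(auc(scores, y[te]))
        result.fold_aucs.append(fold_aucs)
        result.oof_scores.append(oof)
        result.aggregated_aucs.append(auc(oof, y))
    return result
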