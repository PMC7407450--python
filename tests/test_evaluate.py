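"""AUC scoring, fold construction, the liability AUC bound and CV plumbing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gprisk import (ClassifierModel, ClassifierSpec, SimConfig, auc,
                    covariate_logistic_baseline, make_folds, max_liability_auc,
                    run_cv, simulate_cohort)


def pairwise_auc(scores, labels):
    """Exhaustive case/control pair counting."""
    cases = [s for s, l in zip(scores, labels) if l == 1]
    ctrls = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for c, d in itertools.product(cases, ctrls):
        total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(ctrls))


def test_auc_examples():
    assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
    assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5
    scores = [0.9, 0.4, 0.7, 0.6, 0.2]
    labels = [1, 1, 0, 0, 0]
    assert auc(scores, labels) == pytest.approx(4 / 6)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc([1, 2], [1, 1])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_auc_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n - 1))] = 1
    rng.shuffle(labels)
    scores = rng.choice(np.round(rng.standard_normal(6), 2), size=n)  # force ties
    assert auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels),
                                                abs=1e-12)


# ----------------------------------------------------------------- liability AUC


def test_liability_bound_published_values():
    assert max_liability_auc(K=0.0579, rho2=0.4) == pytest.approx(0.86, abs=0.005)
    assert max_liability_auc(K=0.0579, rho2=0.1) == pytest.approx(0.69, abs=0.005)


def test_liability_bound_limits_and_monotonicity():
    assert max_liability_auc(K=0.3, rho2=0.0) == 0.5
    grid = [max_liability_auc(K=0.1, rho2=r) for r in np.linspace(0.05, 1.0, 12)]
    assert all(a < b for a, b in zip(grid, grid[1:]))
    with pytest.raises(ValueError):
        max_liability_auc(K=0.0, rho2=0.5)
    with pytest.raises(ValueError):
        max_liability_auc(K=0.1, rho2=1.5)


# ----------------------------------------------------------------- folds


def test_fold_sizes_and_partition():
    labels = np.r_[np.ones(247, dtype=int), np.zeros(375, dtype=int)]
    plan = make_folds(labels, k=10, seed=0)
    sizes = [len(plan.test_index(f)) for f in range(10)]
    assert set(sizes) <= {62, 63}
    all_idx = np.concatenate([plan.test_index(f) for f in range(10)])
    assert len(all_idx) == 622 and len(np.unique(all_idx)) == 622
    # stratification keeps both classes in every fold
    for f in range(10):
        assert len(np.unique(labels[plan.test_index(f)])) == 2


def test_fold_determinism():
    labels = np.arange(100) % 2
    a = make_folds(labels, k=10, seed=4)
    b = make_folds(labels, k=10, seed=4)
    np.testing.assert_array_equal(a.assignments, b.assignments)
    c = make_folds(labels, k=10, seed=5)
    assert not np.array_equal(a.assignments, c.assignments)


def test_too_few_samples_rejected():
    with pytest.raises(ValueError):
        make_folds(np.array([0, 1, 0]), k=10, seed=0)


# ----------------------------------------------------------------- CV plumbing


def test_run_cv_reports_both_auc_flavours(small_cohort):
    model = ClassifierModel(ClassifierSpec("knn"))
    res = run_cv(small_cohort.geno, small_cohort.samples, model,
                 selection="mean_diff", k_snps=20, include_covariates=True,
                 repeats=2, seed=3)
    assert len(res.fold_aucs) == 2 and len(res.fold_aucs[0]) == 10
    assert len(res.aggregated_aucs) == 2
    assert 0.0 <= res.mean_auc <= 1.0
    assert res.sd_across_repeats >= 0.0
    # fold-mean and aggregated AUC tell the same broad story
    assert abs(res.mean_auc - float(np.mean(res.aggregated_aucs))) < 0.1
    summary = res.summary()
    assert summary["model"] == "knn" and summary["k_snps"] == 20


def test_run_cv_deterministic_given_seed(small_cohort):
    model = ClassifierModel(ClassifierSpec("knn"))
    kw = dict(selection="mean_diff", k_snps=10, repeats=1, seed=9)
    a = run_cv(small_cohort.geno, small_cohort.samples, model, **kw)
    b = run_cv(small_cohort.geno, small_cohort.samples, model, **kw)
    assert a.fold_aucs == b.fold_aucs


def test_covariate_baseline_null_is_chance(null_cohort):
    res = covariate_logistic_baseline(null_cohort.samples, repeats=2, seed=1)
    assert res.mean_auc == pytest.approx(0.5, abs=0.08)


def test_covariate_baseline_matches_liability_oracle():
    """One strong covariate: CV AUC of the logistic baseline approaches the
    analytic liability-AUC of the variance share that covariate explains."""
    beta_w = 0.1
    cfg = SimConfig(n_individuals=5000, n_snps=20, n_causal=0, h2_liability=0.0,
                    covariate_effects=(beta_w, 0.0, 0.0), prevalence_K=0.2,
                    missing_rate=0.0, seed=13)
    cohort = simulate_cohort(cfg)
    w = cohort.samples["weight"].to_numpy()
    rho2 = float(np.var(beta_w * w))  # total liability variance is 1
    expected = max_liability_auc(K=0.2, rho2=rho2)
    res = covariate_logistic_baseline(cohort.samples, repeats=1, seed=2)
    assert res.mean_auc == pytest.approx(expected, abs=0.03)


def test_cv_repeat_scaling_reduces_dispersion(small_cohort):
    """More repeats shrink the SE of the grand mean (statistical scaling)."""
    model = ClassifierModel(ClassifierSpec("knn"))
    res = run_cv(small_cohort.geno, small_cohort.samples, model,
                 selection="mean_diff", k_snps=10, include_covariates=True,
                 repeats=4, seed=21)
    means = res.repeat_means
    se2 = np.var(means[:2], ddof=1) / 2
    se4 = np.var(means, ddof=1) / 4
    # noisy check: quadrupling repeats should not inflate the SE
    assert se4 < 4 * se2 + 1e-6
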