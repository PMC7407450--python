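"""The four classification learners and the weighted-subspace machinery."""

import numpy as np
import pytest

from gprisk import ClassifierModel, ClassifierSpec, auc, feature_weights


@pytest.fixture(scope="module")
def separable_toy():
    """y is a deterministic threshold of the first covariate column, which
    separates the classes with a margin; SNP dosages lean the same way."""
    rng = np.random.default_rng(14)
    n = 120
    y = rng.integers(0, 2, n)
    driver = (2 * y - 1) * (0.5 + np.abs(rng.standard_normal(n)))
    cov = np.column_stack([driver, rng.standard_normal(n)])
    snps = (y[:, None] + rng.integers(0, 2, (n, 6))).astype(float)
    return snps, cov, y


def test_spec_validation():
    with pytest.raises(ValueError):
        ClassifierSpec(method="svm").validate()
    with pytest.raises(ValueError):
        ClassifierSpec(n_trees=0).validate()


def test_feature_weights_toy_arithmetic():
    rng = np.random.default_rng(6)
    n = 4000
    y = rng.integers(0, 2, n).astype(float)
    perfect = y.copy()                      # correlation 1
    half = np.where(rng.random(n) < 0.75, y, 1 - y)  # correlation ~0.5
    noise = rng.integers(0, 2, n).astype(float)      # correlation ~0
    w = feature_weights(np.column_stack([perfect, half, noise]), y)
    assert w.sum() == pytest.approx(1.0)
    assert w[0] == pytest.approx(2 / 3, abs=0.05)
    assert w[1] == pytest.approx(1 / 3, abs=0.05)
    assert w[2] < 0.05
    assert np.argmax(w) == 0


def test_feature_weights_floor_for_constant_feature():
    y = np.array([0, 1, 0, 1, 0, 1])
    X = np.column_stack([y, np.ones(6)])
    w = feature_weights(X, y)
    assert w[1] > 0  # floored, never exactly zero
    assert w[0] > 100 * w[1]


def test_feature_weights_single_class_rejected():
    with pytest.raises(ValueError):
        feature_weights(np.ones((4, 2)), np.ones(4))


@pytest.mark.parametrize("method,kwargs", [
    ("wrf", dict(n_trees=60)),
    ("gbt", dict(n_rounds=60)),
    ("nb", {}),
    ("knn", {}),
])
def test_separable_data_fit_perfectly(method, kwargs, separable_toy):
    snps, cov, y = separable_toy
    model = ClassifierModel(ClassifierSpec(method, **kwargs))
    fitted = model.fit(snps, cov, y, seed=0)
    scores = fitted.predict(snps, cov)
    assert np.all((scores >= 0) & (scores <= 1))
    assert auc(scores, y) > 0.99


@pytest.mark.parametrize("method,kwargs", [
    ("wrf", dict(n_trees=60)), ("gbt", dict(n_rounds=60)),
])
def test_fixed_seed_reproducible_predictions(method, kwargs, separable_toy):
    snps, cov, y = separable_toy
    model = ClassifierModel(ClassifierSpec(method, **kwargs))
    a = model.fit(snps, cov, y, seed=5).predict(snps, cov)
    b = model.fit(snps, cov, y, seed=5).predict(snps, cov)
    np.testing.assert_array_equal(a, b)


def test_label_permutation_scores_near_chance(separable_toy):
    """Training on permuted labels and scoring held-out samples gives ~0.5 AUC."""
    snps, cov, y = separable_toy
    rng = np.random.default_rng(3)
    tr, te = np.arange(0, 80), np.arange(80, 120)
    for method, kwargs in [("wrf", dict(n_trees=60)), ("gbt", dict(n_rounds=60)),
                           ("nb", {}), ("knn", {})]:
        aucs = []
        for perm in range(6):
            y_perm = rng.permutation(y)
            model = ClassifierModel(ClassifierSpec(method, **kwargs))
            fitted = model.fit(snps[tr], cov[tr], y_perm[tr], seed=perm)
            aucs.append(auc(fitted.predict(snps[te], cov[te]), y_perm[te]))
        assert abs(np.mean(aucs) - 0.5) < 0.12, method


def test_knn_neighbor_vote_matches_hand_count():
    """7-sample toy: brute-force 5-nearest-neighbour vote."""
    X = np.array([[0.0], [0.1], [0.2], [0.3], [5.0], [5.1], [5.2]])
    y = np.array([1, 1, 1, 0, 0, 0, 0])
    model = ClassifierModel(ClassifierSpec("knn"))
    fitted = model.fit(X, None, y, seed=0)
    q = np.array([[0.05], [5.05]])
    scores = fitted.predict(q, None)
    # brute force on standardized coordinates (single feature: order preserved)
    for qi, s in zip(q[:, 0], scores):
        d = np.abs(X[:, 0] - qi)
        nearest = np.argsort(d)[:5]
        assert s == pytest.approx(y[nearest].mean())


def test_nb_symmetric_classes_give_half():
    """Identical class-conditional densities with balanced priors -> 0.5."""
    X = np.array([[0.0], [1.0], [0.0], [1.0]])
    y = np.array([0, 0, 1, 1])
    model = ClassifierModel(ClassifierSpec("nb"))
    fitted = model.fit(X, None, y, seed=0)
    np.testing.assert_allclose(fitted.predict(np.array([[0.0]]), None), [0.5],
                               atol=1e-12)


def test_knn_all_case_neighbors_score_one():
    X = np.vstack([np.zeros((5, 1)), np.full((5, 1), 10.0)])
    y = np.array([1] * 5 + [0] * 5)
    fitted = ClassifierModel(ClassifierSpec("knn")).fit(X, None, y, seed=0)
    assert fitted.predict(np.array([[0.1]]), None)[0] == 1.0


def test_wrf_uniform_subspace_matches_weighted_on_easy_data(separable_toy):
    """With uniform weights wRF degrades to a plain random forest; on easy
    data both land in the same performance band."""
    snps, cov, y = separable_toy
    weighted = ClassifierModel(ClassifierSpec("wrf", n_trees=120)).fit(
        snps, cov, y, seed=2).predict(snps, cov)
    uniform = ClassifierModel(ClassifierSpec("wrf", n_trees=120,
                                             uniform_subspace=True)).fit(
        snps, cov, y, seed=2).predict(snps, cov)
    assert abs(auc(weighted, y) - auc(uniform, y)) < 0.1


def test_single_class_training_rejected(separable_toy):
    snps, cov, y = separable_toy
    with pytest.raises(ValueError, match="single class"):
        ClassifierModel(ClassifierSpec("nb")).fit(snps, cov, np.zeros_like(y), seed=0)


def test_layout_mismatch_rejected(separable_toy):
    snps, cov, y = separable_toy
    fitted = ClassifierModel(ClassifierSpec("knn")).fit(snps, cov, y, seed=0)
    with pytest.raises(ValueError, match="layout"):
        fitted.predict(snps[:, :3], cov)
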