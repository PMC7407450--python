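"""The four classification learners: weighted-subspace random forest,
gradient boosted trees, naive Bayes and k-nearest neighbours.

Hyperparameters default to the tuned values used throughout the study:
wRF with 1000 trees and sqrt(p)-sized feature subspaces sampled with
probability proportional to each feature's class correlation; xgboost with
eta 0.05, gamma 0.3, depth 10, column/row subsampling 0.8 and 1000 rounds;
KNN with the five closest neighbours on standardized features.  Naive Bayes
treats SNP dosages and the binary covariates as categorical and body weight
as Gaussian.

Every learner is wrapped in the same ``fit``/``predict`` adapter protocol as
the Bayesian models so :func:`gprisk.evaluate.run_cv` can drive all of them.
Features arrive as a :class:`FeatureBlock`: selected SNP dosages (imputed
with training-fold means) plus optional covariate columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

METHODS = ("wrf", "gbt", "nb", "knn")


@dataclass
class ClassifierSpec:
    method: str = "wrf"
    # wRF
    n_trees: int = 1000
    uniform_subspace: bool = False  # True reduces wRF to a plain random forest
    weight_statistic: str = "point_biserial"  # or "chi2"
    # GBT
    eta: float = 0.05
    gamma: float = 0.3
    max_depth: int = 10
    colsample: float = 0.8
    subsample: float = 0.8
    n_rounds: int = 1000
    # KNN
    k_neighbors: int = 5
    include_covariates: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.n_trees < 1 or self.n_rounds < 1 or self.k_neighbors < 1:
            raise ValueError("tree counts, rounds and k must be positive")


@dataclass
class FeatureBlock:
    """Numeric feature matrix: SNP dosage columns first, covariates last."""

    X: np.ndarray
    n_snp_cols: int
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if np.isnan(self.X).any():
            raise ValueError("FeatureBlock must be fully imputed (no NaN)")
        if not self.names:
            self.names = [f"f{j}" for j in range(self.X.shape[1])]


def feature_weights(X: np.ndarray, y: np.ndarray, statistic: str = "point_biserial",
                    floor: float = 1e-6) -> np.ndarray:
    """Per-feature subspace-sampling probabilities from class association.

    Default statistic is |point-biserial correlation| with the 0/1 class;
    constant features get the floor weight; weights are normalized to sum 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("feature weights need both classes")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        if statistic == "point_biserial":
            w = np.abs((Xc * yc[:, None]).mean(axis=0) / (sx * sy))
        elif statistic == "chi2":
            from sklearn.feature_selection import chi2

            stat, _ = chi2(X - X.min(axis=0), y.astype(int))
            w = np.asarray(stat, dtype=float)
        else:
            raise ValueError(f"unknown weight statistic {statistic!r}")
    w = np.where(np.isfinite(w), w, 0.0)
    w = np.maximum(w, floor)
    return w / w.sum()


class _WeightedSubspaceForest:
    """Random forest whose per-tree feature subspaces of size floor(sqrt(p))
    are sampled with probability proportional to the feature weights, so
    class-informative features enter trees more often."""

    def __init__(self, n_trees: int, weights: np.ndarray, seed: int):
        self.n_trees = n_trees
        self.weights = weights
        self.seed = seed
        self.trees: list = []
        self.subspaces: list = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_WeightedSubspaceForest":
        rng = np.random.default_rng(self.seed)
        n, p = X.shape
        k = max(1, int(np.floor(np.sqrt(p))))
        n_pos = min(k, int(np.sum(self.weights > 0)))
        for t in range(self.n_trees):
            cols = rng.choice(p, size=n_pos, replace=False, p=self.weights)
            rows = rng.integers(0, n, size=n)  # bootstrap
            if len(np.unique(y[rows])) < 2:  # resample a degenerate bootstrap
                rows = rng.permutation(n)
            tree = DecisionTreeClassifier(
                random_state=int(rng.integers(0, 2**31 - 1)))
            tree.fit(X[rows][:, cols], y[rows])
            self.trees.append(tree)
            self.subspaces.append(cols)
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        acc = np.zeros(X.shape[0])
        for tree, cols in zip(self.trees, self.subspaces):
            proba = tree.predict_proba(X[:, cols])
            idx = np.where(tree.classes_ == 1)[0]
            acc += proba[:, idx[0]] if len(idx) else 0.0
        return acc / len(self.trees)


class _HybridNaiveBayes:
    """Naive Bayes with categorical likelihoods for dosage/sex/neuter columns
    and a Gaussian likelihood for body weight (last covariate column)."""

    def __init__(self, categorical_cols: np.ndarray, gaussian_cols: np.ndarray,
                 laplace: float = 1.0):
        self.cat = categorical_cols
        self.gau = gaussian_cols
        self.laplace = laplace

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_HybridNaiveBayes":
        self.classes_ = np.unique(y)
        self.log_prior_ = np.log(np.array([(y == c).mean() for c in self.classes_]))
        self.cat_levels_ = [np.unique(X[:, j]) for j in self.cat]
        self.cat_logp_ = []
        self.gau_params_ = []
        for ci, c in enumerate(self.classes_):
            Xc = X[y == c]
            tabs = []
            for jj, j in enumerate(self.cat):
                levels = self.cat_levels_[jj]
                counts = np.array([(Xc[:, j] == lv).sum() for lv in levels], dtype=float)
                tabs.append(np.log((counts + self.laplace)
                                   / (counts.sum() + self.laplace * len(levels))))
            self.cat_logp_.append(tabs)
            mu = Xc[:, self.gau].mean(axis=0) if len(self.gau) else np.zeros(0)
            sd = Xc[:, self.gau].std(axis=0) if len(self.gau) else np.zeros(0)
            self.gau_params_.append((mu, np.maximum(sd, 1e-6)))
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        logpost = np.tile(self.log_prior_, (n, 1))
        for ci in range(len(self.classes_)):
            for jj, j in enumerate(self.cat):
                levels = self.cat_levels_[jj]
                logp = self.cat_logp_[ci][jj]
                # unseen level -> uniform over known levels
                idx = np.searchsorted(levels, X[:, j])
                idx = np.clip(idx, 0, len(levels) - 1)
                known = np.isclose(levels[idx], X[:, j])
                contrib = np.where(known, logp[idx], -np.log(len(levels)))
                logpost[:, ci] += contrib
            mu, sd = self.gau_params_[ci]
            if len(self.gau):
                z = (X[:, self.gau] - mu) / sd
                logpost[:, ci] += np.sum(-0.5 * z**2 - np.log(sd), axis=1)
        logpost -= logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=1, keepdims=True)
        pos = np.where(self.classes_ == 1)[0]
        return post[:, pos[0]] if len(pos) else np.zeros(n)


class ClassifierModel:
    """``fit``/``predict`` adapter over the four learners."""

    def __init__(self, spec: ClassifierSpec):
        spec.validate()
        self.spec = spec
        self.name = spec.method

    def fit(self, X_snps, X_cov, y, seed: int = 0) -> "ClassifierModel._Fitted":
        spec = self.spec
        X_snps = np.atleast_2d(np.asarray(X_snps, dtype=float)) if X_snps is not None \
            else np.zeros((len(y), 0))
        parts = [X_snps]
        if X_cov is not None and np.size(X_cov):
            parts.append(np.atleast_2d(np.asarray(X_cov, dtype=float)))
        X = np.hstack(parts)
        if X.shape[1] == 0:
            raise ValueError("no features to train on")
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training fold contains a single class")
        n_snp = X_snps.shape[1]

        if spec.method == "wrf":
            if spec.uniform_subspace:
                w = np.full(X.shape[1], 1.0 / X.shape[1])
            else:
                w = feature_weights(X, y, statistic=spec.weight_statistic)
            model = _WeightedSubspaceForest(spec.n_trees, w, seed).fit(X, y)
            predict = model.predict_proba_pos
        elif spec.method == "gbt":
            model = XGBClassifier(
                learning_rate=spec.eta, gamma=spec.gamma, max_depth=spec.max_depth,
                colsample_bytree=spec.colsample, subsample=spec.subsample,
                n_estimators=spec.n_rounds, eval_metric="error",
                objective="binary:logistic", random_state=seed, n_jobs=1,
                verbosity=0, tree_method="hist",
            )
            model.fit(X, y)
            predict = lambda Z: model.predict_proba(Z)[:, 1]
        elif spec.method == "nb":
            # dosage + binary covariate columns are categorical; weight (the
            # continuous covariate, last column when covariates are present)
            # is Gaussian
            cols = np.arange(X.shape[1])
            if X.shape[1] > n_snp:  # covariates present: sex, neuter, weight
                gaussian = cols[-1:]
                categorical = cols[:-1]
            else:
                gaussian = cols[:0]
                categorical = cols
            model = _HybridNaiveBayes(categorical, gaussian).fit(X, y)
            predict = model.predict_proba_pos
        else:  # knn
            mu = X.mean(axis=0)
            sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
            Xs = (X - mu) / sd
            model = KNeighborsClassifier(n_neighbors=min(spec.k_neighbors, len(y)))
            model.fit(Xs, y)

            def predict(Z, _mu=mu, _sd=sd, _m=model):
                proba = _m.predict_proba((Z - _mu) / _sd)
                idx = np.where(_m.classes_ == 1)[0]
                return proba[:, idx[0]] if len(idx) else np.zeros(Z.shape[0])

        return ClassifierModel._Fitted(predict, X.shape[1], n_snp)

    class _Fitted:
        def __init__(self, predict_fn, n_features: int, n_snp: int):
            self._predict = predict_fn
            self.n_features = n_features
            self.n_snp = n_snp

        def predict(self, X_snps, X_cov) -> np.ndarray:
            X_snps = np.atleast_2d(np.asarray(X_snps, dtype=float)) \
                if X_snps is not None else None
            parts = []
            if X_snps is not None:
                if X_snps.shape[1] != self.n_snp:
                    raise ValueError("SNP feature layout mismatch")
                parts.append(X_snps)
            if X_cov is not None and np.size(X_cov):
                parts.append(np.atleast_2d(np.asarray(X_cov, dtype=float)))
            X = np.hstack(parts)
            if X.shape[1] != self.n_features:
                raise ValueError("feature layout mismatch")
            return np.clip(self._predict(X), 0.0, 1.0)
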