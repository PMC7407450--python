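"""Combining the 8 base models (4 classifiers x 2 feature-selection methods).

Two combination strategies: *n-agreement* voting over binarized base calls
(positive iff at least n of the 8 base models call positive, n chosen per
fold by maximum AUC) and *stacked* supervision, where out-of-fold base
scores are re-partitioned into 10 fresh folds and a supervisor (plain
logistic regression or a 500-tree random forest) is cross-fitted on the
8-column score matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .evaluate import FoldPlan, auc, make_folds

N_BASE_MODELS = 8
CALL_THRESHOLD = 0.5  # base score -> binary call


@dataclass
class BasePredictions:
    """samples x 8 matrix of out-of-fold base-model scores."""

    scores: np.ndarray
    columns: list

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape[1] != N_BASE_MODELS:
            raise ValueError(
                f"expected {N_BASE_MODELS} base-model columns, got {self.scores.shape[1]}"
            )
        if len(self.columns) != N_BASE_MODELS:
            raise ValueError("need one label per base-model column")

    @property
    def calls(self) -> np.ndarray:
        return (self.scores >= CALL_THRESHOLD).astype(int)


def n_agreement(preds: BasePredictions, n: int) -> np.ndarray:
    """Positive prediction iff at least ``n`` of the 8 base calls are positive."""
    if not 1 <= n <= N_BASE_MODELS:
        raise ValueError(f"n must be in 1..{N_BASE_MODELS}; got {n}")
    return (preds.calls.sum(axis=1) >= n).astype(int)


def best_n_per_fold(preds: BasePredictions, y: np.ndarray, plan: FoldPlan
                    ) -> list[dict]:
    """Per test fold, the agreement threshold n maximizing AUC (ties -> smaller n).

    Returns one record per usable fold with keys ``fold``, ``n``, ``auc``;
    single-class folds are skipped with a warning.  Averages of ``n`` and
    ``auc`` across folds give the per-run summary.
    """
    y = np.asarray(y).astype(int)
    records = []
    for fold in range(plan.k):
        te = plan.test_index(fold)
        if len(np.unique(y[te])) < 2:
            warnings.warn(f"fold {fold} has a single class; skipped")
            continue
        best = None
        for n in range(1, N_BASE_MODELS + 1):
            votes = n_agreement(preds, n)[te]
            a = auc(votes, y[te])
            if best is None or a > best["auc"]:
                best = {"fold": fold, "n": n, "auc": a}
        records.append(best)
    return records


def stack(preds: BasePredictions, y: np.ndarray, supervisor: str = "logistic",
          seed: int = 0, n_folds: int = 10) -> np.ndarray:
    """Cross-fitted supervisor scores over the 8 base-model score columns.

    The samples are shuffled and re-partitioned into ``n_folds`` fresh folds;
    the supervisor is trained on the base scores of 9 folds and scores the
    held-out fold, so no sample's own label influences its stacked score.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression

    if supervisor not in ("logistic", "random_forest"):
        raise ValueError(f"unknown supervisor {supervisor!r}")
    y = np.asarray(y).astype(int)
    S = preds.scores
    plan = make_folds(y, k=n_folds, seed=seed, stratify=True)
    out = np.full(len(y), np.nan)
    for fold in range(n_folds):
        tr, te = plan.train_index(fold), plan.test_index(fold)
        if supervisor == "logistic":
            clf = LogisticRegression(C=np.inf, max_iter=2000)  # unpenalized
        else:
            clf = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
        clf.fit(S[tr], y[tr])
        idx = np.where(clf.classes_ == 1)[0][0]
        out[te] = clf.predict_proba(S[te])[:, idx]
    return out
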