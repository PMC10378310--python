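"""Initial feature selection (FFS): balancing, SVM-RFE-CV and ensemble vote.

Influential-spreader labels are imbalanced (the positive class is a top-f
fraction, f ≤ 20%), which biases wrapper selection toward the majority
class.  Phase 1 therefore draws k balanced replicates by undersampling the
majority class, runs recursive feature elimination with a cross-validated
linear SVM on each, and votes: features appearing in more than a fraction ε
of the k per-replicate best subsets form F*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .centrality import canonical_sort

__all__ = ["LabeledDataset", "RfeTrace", "VoteResult", "balance_by_undersampling",
           "svm_rfe_cv", "ensemble_vote", "run_initial_selection"]


@dataclass
class LabeledDataset:
    """Feature matrix (one row per node) with ±1 influence labels."""

    X: pd.DataFrame
    y: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError("row count of X must match label count")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be in {-1, +1}")
        if not np.all(np.isfinite(self.X.to_numpy())):
            raise ValueError("features must be finite")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.y)

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        return int(np.sum(self.y == -1)), int(np.sum(self.y == 1))

    def restrict(self, features) -> "LabeledDataset":
        return LabeledDataset(self.X[list(features)].copy(), self.y.copy(),
                              dict(self.provenance))


@dataclass
class RfeTrace:
    """Record of one recursive-elimination run: removal order (first removed
    first), the cross-validated score at each surviving-subset size, and the
    best subset (the survivors at the size with maximal CV score)."""

    elimination_order: list[str]
    cv_scores: dict[int, float]
    subsets_by_size: dict[int, list[str]]
    best_subset: list[str]


@dataclass
class VoteResult:
    k: int
    frequencies: dict[str, float]
    epsilon: float
    f_star: list[str]


def balance_by_undersampling(
    data: LabeledDataset, rng: np.random.Generator, with_replacement: bool = False
) -> LabeledDataset:
    """Balance classes by sampling the majority class down to minority size.

    All minority rows are kept verbatim; majority rows are sampled without
    replacement by default.  The returned rows are shuffled.
    """
    n_neg, n_pos = data.class_counts()
    if n_neg == 0 or n_pos == 0:
        raise ValueError("both classes must be present")
    minority_label = 1 if n_pos <= n_neg else -1
    min_idx = np.flatnonzero(data.y == minority_label)
    maj_idx = np.flatnonzero(data.y == -minority_label)
    chosen = rng.choice(maj_idx, size=min_idx.size, replace=with_replacement)
    keep = np.concatenate([min_idx, chosen])
    rng.shuffle(keep)
    return LabeledDataset(
        data.X.iloc[keep].reset_index(drop=True),
        data.y[keep],
        {**data.provenance, "balanced": True},
    )


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    counts = (int(np.sum(y == -1)), int(np.sum(y == 1)))
    minority = min(counts)
    if minority < 2:
        raise ValueError(
            f"minority class has {minority} member(s); cross-validation impossible "
            "(insufficient sampling quantity)"
        )
    n_splits = min(folds, minority)
    return StratifiedKFold(n_splits=n_splits, shuffle=True,
                           random_state=int(rng.integers(2**31)))


def svm_rfe_cv(
    data: LabeledDataset,
    folds: int = 10,
    C: float = 1.0,
    rng: np.random.Generator | None = None,
) -> RfeTrace:
    """Recursive feature elimination with a cross-validated linear SVM.

    At each subset size: features are standardised per fold (scaler fit on
    the training folds only), a linear SVM (regularisation C) is fit per
    fold, the importance of feature j is the sum over folds of |w_j|, and
    the subset's score is the mean validation F1 of the positive class.
    The least important feature is removed (ties: higher column index) until
    none remain; the best subset maximises the CV score, ties going to the
    smaller size.
    """
    if not data.feature_names:
        raise ValueError("need at least one feature")
    rng = rng or np.random.default_rng()
    y = data.y
    surviving = list(data.feature_names)
    elimination_order: list[str] = []
    cv_scores: dict[int, float] = {}
    subsets_by_size: dict[int, list[str]] = {}

    while surviving:
        X = data.X[surviving].to_numpy()
        skf = _stratified_folds(y, folds, rng)
        importance = np.zeros(len(surviving))
        fold_scores = []
        for tr, va in skf.split(X, y):
            scaler = StandardScaler().fit(X[tr])
            clf = SVC(kernel="linear", C=C)
            clf.fit(scaler.transform(X[tr]), y[tr])
            importance += np.abs(clf.coef_[0])
            pred = clf.predict(scaler.transform(X[va]))
            fold_scores.append(f1_score(y[va], pred, pos_label=1, zero_division=0))
        size = len(surviving)
        cv_scores[size] = float(np.mean(fold_scores))
        subsets_by_size[size] = list(surviving)
        # least important out; ties resolve to the higher column index
        worst = size - 1 - int(np.argmin(importance[::-1]))
        elimination_order.append(surviving.pop(worst))

    best_score = max(cv_scores.values())
    best_size = min(s for s, v in cv_scores.items() if v == best_score)
    return RfeTrace(elimination_order, cv_scores, subsets_by_size,
                    best_subset=subsets_by_size[best_size])


def ensemble_vote(subsets: list[list[str]], epsilon: float = 0.5,
                  all_features: list[str] | None = None) -> VoteResult:
    """Vote features across k per-replicate best subsets into F*.

    frequency(feature) = (#subsets containing it) / k; F* keeps features with
    frequency strictly above ε.  If no feature clears ε, the maximum-frequency
    features are taken instead (ties resolved in canonical column order).
    """
    if not subsets:
        raise ValueError("need at least one subset")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    k = len(subsets)
    universe = all_features if all_features is not None else sorted(
        {f for s in subsets for f in s})
    freq = {f: sum(f in s for s in subsets) / k for f in universe}
    f_star = canonical_sort([f for f, q in freq.items() if q > epsilon])
    if not f_star:
        top = max(freq.values())
        f_star = canonical_sort([f for f, q in freq.items() if q == top])
    return VoteResult(k=k, frequencies=freq, epsilon=epsilon, f_star=f_star)


def run_initial_selection(
    data: LabeledDataset,
    k: int = 10,
    epsilon: float = 0.5,
    folds: int = 10,
    C: float = 1.0,
    rng: np.random.Generator | None = None,
    with_replacement: bool = False,
) -> tuple[VoteResult, list[RfeTrace]]:
    """Phase 1 end to end: k× (balance → SVM-RFE-CV) → ensemble vote."""
    rng = rng or np.random.default_rng()
    traces = []
    for _ in range(k):
        balanced = balance_by_undersampling(data, rng, with_replacement=with_replacement)
        traces.append(svm_rfe_cv(balanced, folds=folds, C=C, rng=rng))
    vote = ensemble_vote([t.best_subset for t in traces], epsilon=epsilon,
                         all_features=data.feature_names)
    return vote, traces
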