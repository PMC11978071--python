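"""Nucleus classification from normalized response PSTHs.

First-order (VPM-like) and higher-order (POm-like) neurons differ in the
shape of their deflection-aligned PSTHs (latency, width, touch
sensitivity).  A cross-validated L2 logistic regression is trained on
max-normalized PSTHs (rows = neurons, columns = time bins; puff, touch, or
both conditions concatenated) with a stratified shuffled 75/25 train/test
split and an internal 5-fold CV over 50 log-spaced regularization
strengths in [1e-3, 1e2].  Significance of the test accuracy is an
empirical permutation test that re-runs the whole split/fit/test pipeline
under label permutation; the attainable p-value floor is 1/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "ClassifierResult",
    "build_feature_matrix",
    "train_and_test",
    "permutation_significance",
]

CS_GRID = np.logspace(-3, 2, 50)
TEST_FRACTION = 0.25
N_PERMUTATIONS = 256
CV_FOLDS = 5


@dataclass
class ClassifierResult:
    features_used: str
    test_accuracy: float
    n_train: int
    n_test: int
    chosen_regularization: float
    predicted: np.ndarray
    truth: np.ndarray
    permutation_p: Optional[float] = None


def build_feature_matrix(psths_by_condition: dict, conditions: Sequence[str]):
    """Stack max-normalized PSTHs into a feature matrix.

    ``psths_by_condition`` maps condition -> {neuron_id: rate array}; all
    arrays of one condition must share the bin grid.  Each neuron's PSTH is
    normalized to its maximum firing rate, then conditions are concatenated
    column-wise.  Neurons with an all-zero PSTH in any requested condition
    are dropped (logged).  Returns (matrix, neuron_ids).
    """
    ids = None
    for cond in conditions:
        if cond not in psths_by_condition:
            raise ValueError(f"condition {cond!r} not available")
        cond_ids = set(psths_by_condition[cond])
        ids = cond_ids if ids is None else ids & cond_ids
    ids = sorted(ids)

    rows, kept = [], []
    for nid in ids:
        parts = []
        ok = True
        for cond in conditions:
            v = np.asarray(psths_by_condition[cond][nid], float)
            m = v.max()
            if m <= 0:
                warnings.warn(f"neuron {nid}: all-zero PSTH in {cond}; dropped")
                ok = False
                break
            parts.append(v / m)
        if not ok:
            continue
        lengths = {p.size for p in parts}
        row = np.concatenate(parts)
        rows.append(row)
        kept.append(nid)
    if not rows:
        raise ValueError("no usable neurons")
    sizes = {r.size for r in rows}
    if len(sizes) != 1:
        raise ValueError("PSTH bin grids are mismatched across neurons")
    return np.vstack(rows), kept


def _fit_and_score(X, y, seed, cs, cv_folds):
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=TEST_FRACTION, stratify=y, shuffle=True, random_state=seed)
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError("a class is absent from the train or test split")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf = LogisticRegressionCV(
            Cs=cs, penalty="l2", scoring="accuracy",
            cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
            max_iter=2000,
        )
        clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    acc = float(np.mean(pred == y_te))
    return acc, clf, X_te, y_te, pred


def train_and_test(matrix, labels, seed, *, features_used: str = "both",
                   cs=CS_GRID, cv_folds: int = CV_FOLDS) -> ClassifierResult:
    """Stratified 75/25 split + cross-validated L2 logistic regression."""
    X = np.asarray(matrix, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 4:
        raise ValueError("need at least 4 neurons per class")
    acc, clf, X_te, y_te, pred = _fit_and_score(X, y, seed, cs, cv_folds)
    return ClassifierResult(
        features_used=features_used, test_accuracy=acc,
        n_train=X.shape[0] - y_te.size, n_test=int(y_te.size),
        chosen_regularization=float(np.atleast_1d(clf.C_)[0]),
        predicted=pred, truth=y_te,
    )


def permutation_significance(matrix, labels, seed, *, n_perm: int = N_PERMUTATIONS,
                             cs=CS_GRID, cv_folds: int = CV_FOLDS,
                             observed: Optional[float] = None) -> float:
    """Empirical p for the test accuracy under label permutation.

    Labels are permuted jointly over train+test and the entire
    split/fit/test pipeline re-run per permutation (the conservative
    reading of permuting the PSTH-to-cell correspondence).
    p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 20:
        warnings.warn("fewer than 20 permutations: p-value granularity is coarse")
    X = np.asarray(matrix, float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if observed is None:
        observed, *_ = _fit_and_score(X, y, seed, cs, cv_folds)
    count = 0
    for k in range(n_perm):
        y_perm = rng.permutation(y)
        try:
            acc, *_ = _fit_and_score(X, y_perm, seed + k + 1, cs, cv_folds)
        except ValueError:
            acc = 0.0
        if acc >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)
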