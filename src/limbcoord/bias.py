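"""Lateralization of interlimb phase: stimulation-side classification.

Unilateral midbrain stimulation can bias left-right coordination. The
module quantifies this by training a margin classifier (linear support
vector classifier by default) to predict the stimulated side from the
sine/cosine components of limb-pair phases, on a 75/25 split whose
training portion is balanced for both label and mouse identity, and by
testing the held-out accuracy against a label-permutation null with an
add-one p-value estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.svm import LinearSVC

__all__ = ["BiasResult", "phase_features", "train_side_classifier", "permutation_test", "run_bias_analysis"]


@dataclass
class BiasResult:
    """Classification outcome for one feature set."""

    accuracy: float
    n_train: int
    n_test: int
    feature_set: str = "combined"
    permutation_p: float | None = None
    roc_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def phase_features(phases) -> np.ndarray:
    """Sine/cosine feature matrix: columns (sin phi, cos phi) per limb pair.

    ``phases`` may be a 1-D array (one pair), a 2-D array, or a DataFrame
    of phase columns. Features are invariant under adding 2*pi.
    """
    if isinstance(phases, pd.DataFrame):
        phases = phases.to_numpy(dtype=float)
    phases = np.asarray(phases, dtype=float)
    if phases.ndim == 1:
        phases = phases[:, None]
    feats = np.empty((phases.shape[0], 2 * phases.shape[1]))
    feats[:, 0::2] = np.sin(phases)
    feats[:, 1::2] = np.cos(phases)
    return feats


def _balanced_split(labels, groups, split, rng):
    """75/25 split with the training part balanced per (mouse, label)."""
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    n = labels.size
    train = np.zeros(n, dtype=bool)
    for g in np.unique(groups):
        for lab in np.unique(labels):
            idx = np.flatnonzero((groups == g) & (labels == lab))
            idx = rng.permutation(idx)
            k = int(round(split * idx.size))
            train[idx[:k]] = True
    # balance training labels within each mouse by subsampling the majority
    keep = train.copy()
    for g in np.unique(groups):
        counts = {lab: np.flatnonzero(train & (groups == g) & (labels == lab)) for lab in np.unique(labels)}
        m = min(len(v) for v in counts.values())
        for lab, idx in counts.items():
            if len(idx) > m:
                drop = rng.permutation(idx)[m:]
                keep[drop] = False  # dropped entirely (not added to test)
    test = ~train
    return np.flatnonzero(keep & train), np.flatnonzero(test)


def train_side_classifier(
    features,
    labels,
    groups=None,
    split: float = 0.75,
    seed: int = 0,
    C: float = 1.0,
) -> BiasResult:
    """Train the side classifier and evaluate held-out accuracy and ROC.

    ``labels`` must contain exactly two classes and, when ``groups``
    (mouse ids) are given, at least two groups. The training partition is
    balanced for label within each mouse by subsampling; the test
    partition is untouched.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes to train the side classifier")
    if groups is None:
        groups = np.zeros(X.shape[0], dtype=int)
    rng = np.random.default_rng(seed)
    tr, te = _balanced_split(labels, groups, split, rng)
    clf = LinearSVC(C=C, dual="auto", max_iter=5000, random_state=int(rng.integers(2**31)))
    clf.fit(X[tr], labels[tr])
    acc = float(np.mean(clf.predict(X[te]) == labels[te]))
    scores = clf.decision_function(X[te])
    fpr, tpr, _ = roc_curve((labels[te] == classes[1]).astype(int), scores)
    return BiasResult(
        accuracy=acc,
        n_train=tr.size,
        n_test=te.size,
        roc_points=np.column_stack([fpr, tpr]),
    )


def permutation_test(
    features,
    labels,
    groups=None,
    n_perm: int = 1000,
    split: float = 0.75,
    seed: int = 0,
    C: float = 1.0,
    observed: float | None = None,
) -> float:
    """Label-shuffle permutation p-value for classifier accuracy.

    p = (1 + #{permuted accuracy >= observed}) / (1 + n_perm); the
    add-one estimator cannot return zero. Labels are shuffled globally;
    the split/balancing procedure is re-run per permutation.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if observed is None:
        observed = train_side_classifier(X, labels, groups, split, seed, C).accuracy
    rng = np.random.default_rng(seed + 1)
    count = 0
    for b in range(n_perm):
        perm = rng.permutation(labels)
        res = train_side_classifier(X, perm, groups, split, seed=int(rng.integers(2**31)), C=C)
        if res.accuracy >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


def run_bias_analysis(
    phases,
    labels,
    groups=None,
    feature_set: str = "combined",
    n_perm: int = 1000,
    split: float = 0.75,
    seed: int = 0,
    C: float = 1.0,
) -> BiasResult:
    """Full lateralization analysis: features, classifier, permutation test."""
    X = phase_features(phases)
    res = train_side_classifier(X, labels, groups, split, seed, C)
    res.feature_set = feature_set
    res.permutation_p = permutation_test(
        X, labels, groups, n_perm=n_perm, split=split, seed=seed, C=C, observed=res.accuracy
    )
    return res
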