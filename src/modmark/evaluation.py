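"""Classification validation of candidate biomarkers.

Feature genes are fed to a linear-kernel maximum-margin classifier (SVM)
under stratified k-fold cross-validation; performance is summarised by
fold accuracies and the AUC of pooled held-out decision scores.  A
label-noise harness flips a fraction of training labels (test labels are
never touched) across repetitions to probe robustness, and a comparison
helper evaluates several feature sets on one shared fold partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import CASE, ExpressionMatrix, PhenotypeLabels

#: fixed soft-margin constant of the linear SVM; recorded in every report
DEFAULT_C = 1.0


@dataclass
class CVReport:
    fold_accuracies: list[float]
    mean_accuracy: float
    auc: float
    feature_genes: list[str]
    n_folds: int
    svm_c: float = DEFAULT_C


@dataclass
class NoiseRobustnessReport:
    """Per noise-fraction accuracy summary over repetitions.

    ``ci95`` is the normal-approximation interval mean +/- 1.96*SD/sqrt(reps);
    ``percentiles`` the empirical 2.5/97.5 percentiles of the repetitions.
    """

    fractions: list[float]
    mean_accuracy: dict[float, float]
    sd_accuracy: dict[float, float]
    ci95: dict[float, tuple[float, float]]
    percentiles: dict[float, tuple[float, float]]
    n_repetitions: int
    per_rep: dict[float, list[float]] = field(default_factory=dict)


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve with midrank tie handling.

    Equivalent to the normalised Mann-Whitney rank-sum statistic: the
    probability that a random CASE sample scores above a random NORMAL
    sample, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = truth == CASE
    neg = ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # midranks
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _feature_table(expr: ExpressionMatrix, feature_genes, labels: PhenotypeLabels):
    feature_genes = list(feature_genes)
    idx = expr.gene_indices(feature_genes)
    X = expr.values[idx].T  # samples x features
    y = np.array([labels.labels[s] for s in expr.sample_ids])
    return X, y


def _cv_run(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int,
    rng_seed: int,
    flip_fraction: float = 0.0,
    flip_rng: np.random.Generator | None = None,
    svm_c: float = DEFAULT_C,
) -> tuple[list[float], np.ndarray]:
    """Stratified CV; returns fold accuracies and pooled held-out scores."""
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {n_folds} folds; "
            "use a smaller k"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    accs: list[float] = []
    pooled = np.empty(len(y), dtype=float)
    for train, test in skf.split(X, y):
        y_train = y[train].copy()
        if flip_fraction > 0:
            n_flip = int(np.ceil(flip_fraction * len(train)))
            pick = flip_rng.choice(len(train), size=n_flip, replace=False)
            flip_to = np.where(y_train[pick] == CASE, "NORMAL", CASE)
            y_train[pick] = flip_to
        clf = SVC(kernel="linear", C=svm_c)
        clf.fit(X[train], y_train)
        pred = clf.predict(X[test])
        accs.append(float(np.mean(pred == y[test])))
        score = clf.decision_function(X[test])
        # orient decision scores so larger means CASE
        if clf.classes_[-1] != CASE:
            score = -score
        pooled[test] = score
    return accs, pooled


def crossvalidate(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    feature_genes,
    n_folds: int = 10,
    rng_seed: int = 0,
    svm_c: float = DEFAULT_C,
) -> CVReport:
    """Stratified k-fold CV of a linear SVM on the given feature genes."""
    X, y = _feature_table(expr, feature_genes, labels)
    accs, pooled = _cv_run(X, y, n_folds, rng_seed, svm_c=svm_c)
    return CVReport(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        auc=roc_auc(pooled, y),
        feature_genes=list(feature_genes),
        n_folds=n_folds,
        svm_c=svm_c,
    )


def noise_robustness(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    feature_genes,
    fractions,
    n_reps: int = 100,
    n_folds: int = 10,
    rng_seed: int = 0,
    svm_c: float = DEFAULT_C,
) -> NoiseRobustnessReport:
    """Mean CV accuracy under random training-label flips.

    For each fraction f and repetition, ceil(f * n_train) uniformly chosen
    training labels are inverted inside every fold before fitting; held-out
    labels are never perturbed.  Fully reproducible from ``rng_seed``.
    """
    fractions = [float(f) for f in fractions]
    if any(f < 0 or f >= 0.5 for f in fractions):
        raise ValueError("noise fractions must lie in [0, 0.5)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X, y = _feature_table(expr, feature_genes, labels)
    rng = np.random.default_rng(rng_seed)
    mean_acc, sd_acc, ci, pct, per_rep = {}, {}, {}, {}, {}
    for f in fractions:
        reps = []
        for _ in range(n_reps):
            accs, _ = _cv_run(
                X, y, n_folds, rng_seed, flip_fraction=f,
                flip_rng=rng, svm_c=svm_c,
            )
            reps.append(float(np.mean(accs)))
        reps_arr = np.array(reps)
        m = float(reps_arr.mean())
        sd = float(reps_arr.std(ddof=1)) if n_reps > 1 else 0.0
        half = 1.96 * sd / np.sqrt(n_reps)
        mean_acc[f], sd_acc[f] = m, sd
        ci[f] = (m - half, m + half)
        pct[f] = (
            float(np.percentile(reps_arr, 2.5)),
            float(np.percentile(reps_arr, 97.5)),
        )
        per_rep[f] = reps
    return NoiseRobustnessReport(
        fractions=fractions,
        mean_accuracy=mean_acc,
        sd_accuracy=sd_acc,
        ci95=ci,
        percentiles=pct,
        n_repetitions=n_reps,
        per_rep=per_rep,
    )


def compare_biomarkers(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    feature_sets: dict[str, list[str]],
    n_folds: int = 10,
    rng_seed: int = 0,
    svm_c: float = DEFAULT_C,
) -> list[tuple[str, float, float]]:
    """CV each named feature set on one shared fold partition.

    Returns (name, mean fold accuracy, variance of fold accuracies) rows in
    input order.
    """
    if not feature_sets:
        raise ValueError("need at least one feature set")
    rows = []
    for name, genes in feature_sets.items():
        rep = crossvalidate(expr, labels, genes, n_folds, rng_seed, svm_c)
        accs = np.array(rep.fold_accuracies)
        rows.append((name, float(accs.mean()), float(accs.var(ddof=1))))
    return rows
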