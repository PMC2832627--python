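"""Serum-group classification: linear SVM, repeated CV, permutation tests.

The protocol: a soft-margin linear-kernel SVM with cost C = 1 is evaluated
by stratified 10-fold cross validation, the whole procedure repeated 10
times with re-drawn folds; sensitivity, specificity and accuracy are
computed per repetition from the pooled fold confusion counts and
summarized by their median and a 95% percentile interval. Overfitting is
probed by stratified label permutation: class labels are reshuffled
(preserving class sizes), the full cross validation is re-run per
permutation, and the true-label repetition accuracies are compared to the
permutation accuracies with a one-sided rank-sum test.

Quantile normalization is refit inside every training fold and applied to
the held-out fold with the training reference, so no test-set information
leaks into the normalization.

Group 1 of a task is the positive (disease) class throughout: sensitivity
is TP/(TP+FN) on group 1, specificity TN/(TN+FP) on group 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .stats import (
    ProfileMatrix,
    apply_quantile_reference,
    fit_quantile_reference,
)

logger = logging.getLogger("seroarray")

__all__ = [
    "ConfusionCounts",
    "ClassificationReport",
    "PermutationTestResult",
    "confusion_metrics",
    "cross_validate",
    "permutation_test",
    "decision_scores",
]


@dataclass
class ConfusionCounts:
    """Pooled confusion counts; positives are the task's group-1 (disease) sera."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


def confusion_metrics(
    counts: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """``(sensitivity, specificity, accuracy)`` from confusion counts.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/total. A metric whose denominator is zero is
    undefined and reported as ``None``.
    """
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    acc = (counts.tp + counts.tn) / counts.total if counts.total else None
    return sens, spec, acc


@dataclass
class ClassificationReport:
    """Cross-validation outcome for one two-group task."""

    task: tuple[str, str]
    folds: int
    repetitions: int
    cost: float
    repetition_metrics: pd.DataFrame  # rows = repetitions; sens/spec/acc columns
    confusion: list[ConfusionCounts]
    medians: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    scores: pd.Series | None = None  # mean P(serum is group 2) across repetitions
    threshold: float = 0.5
    warnings_: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "task": list(self.task),
            "folds": self.folds,
            "repetitions": self.repetitions,
            "cost": self.cost,
            "repetition_metrics": self.repetition_metrics.to_dict(orient="list"),
            "confusion": [
                {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
                for c in self.confusion
            ],
            "medians": self.medians,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "scores": None if self.scores is None else self.scores.to_dict(),
            "threshold": self.threshold,
            "warnings": self.warnings_,
        }


@dataclass
class PermutationTestResult:
    """Stratified label-permutation null distribution of CV accuracy."""

    accuracies: np.ndarray
    median: float
    mean: float
    p_value: float
    true_accuracies: np.ndarray


def _child_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def _fold_pass(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    cost: float,
    random_state: int,
    per_fold_normalize: bool,
    calibrate: bool,
) -> tuple[ConfusionCounts, np.ndarray]:
    """One complete k-fold pass; returns pooled counts and per-serum scores.

    ``y`` is 1 for group-1 (positive) sera, 0 for group-2. Scores are the
    calibrated probability of being group 2 (NaN when not calibrating).
    """
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    counts = ConfusionCounts()
    scores = np.full(len(y), np.nan)
    for train_idx, test_idx in skf.split(X, y):
        Xtr, Xte = X[train_idx], X[test_idx]
        if per_fold_normalize:
            ref = fit_quantile_reference(Xtr)
            Xtr = apply_quantile_reference(Xtr, ref)
            Xte = apply_quantile_reference(Xte, ref)
        clf = SVC(kernel="linear", C=cost)
        clf.fit(Xtr, y[train_idx])
        pred = clf.predict(Xte)
        yt = y[test_idx]
        counts = counts + ConfusionCounts(
            tp=int(np.sum((pred == 1) & (yt == 1))),
            fp=int(np.sum((pred == 1) & (yt == 0))),
            tn=int(np.sum((pred == 0) & (yt == 0))),
            fn=int(np.sum((pred == 0) & (yt == 1))),
        )
        if calibrate:
            # Platt scaling: logistic fit on training decision values only
            dtr = clf.decision_function(Xtr).reshape(-1, 1)
            dte = clf.decision_function(Xte).reshape(-1, 1)
            lr = LogisticRegression(C=1e6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lr.fit(dtr, y[train_idx])
            # probability of class 0 = group 2 (control-style score)
            scores[test_idx] = lr.predict_proba(dte)[:, list(lr.classes_).index(0)]
    return counts, scores


def cross_validate(
    matrix: ProfileMatrix,
    task: tuple[str, str],
    folds: int = 10,
    repetitions: int = 10,
    cost: float = 1.0,
    seed: int = 0,
    per_fold_normalize: bool = True,
    calibrate: bool = True,
) -> ClassificationReport:
    """Repeated stratified k-fold cross validation of the linear SVM.

    Folds are stratified (class proportions preserved) and re-drawn every
    repetition from a deterministic child seed, so a fixed ``seed`` gives
    an identical report. Sera are put in canonical (sorted-id) order before
    fold assignment, making the result invariant to input row order. If a
    class holds fewer sera than ``folds``, the fold count is reduced to the
    smaller class size with a warning.

    ``per_fold_normalize=False`` quantile-normalizes the whole task matrix
    once up front instead (the leakage-prone variant, kept as an escape
    hatch for comparison).
    """
    group1, group2 = task
    sub = matrix.task_subset(group1, group2)
    order = np.argsort(sub.values.index.to_numpy())
    values = sub.values.iloc[order]
    groups = sub.groups.iloc[order]
    y = (groups == group1).to_numpy().astype(int)
    n1, n2 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"task {task} is degenerate: a class has no sera")
    warn_list: list[str] = []
    min_class = min(n1, n2)
    if min_class < folds:
        warn_list.append(
            f"folds reduced from {folds} to {min_class} (smallest class size)"
        )
        logger.warning(warn_list[-1])
        folds = min_class
    if folds < 2:
        raise ValueError("need at least 2 sera per class for cross validation")

    X = values.to_numpy(dtype=float)
    if not per_fold_normalize:
        ref = fit_quantile_reference(X)
        X = apply_quantile_reference(X, ref)

    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(repetitions)
    rows = []
    confusion = []
    all_scores = np.full((repetitions, len(y)), np.nan)
    for r in range(repetitions):
        counts, scores = _fold_pass(
            X,
            y,
            folds=folds,
            cost=cost,
            random_state=_child_int(rep_seeds[r]),
            per_fold_normalize=per_fold_normalize,
            calibrate=calibrate,
        )
        sens, spec, acc = confusion_metrics(counts)
        rows.append(
            {"sensitivity": sens, "specificity": spec, "accuracy": acc}
        )
        confusion.append(counts)
        all_scores[r] = scores

    metrics = pd.DataFrame(rows, index=pd.RangeIndex(repetitions, name="repetition"))
    medians = {k: float(metrics[k].median()) for k in metrics.columns}
    ci95 = {
        k: (
            float(np.percentile(metrics[k].to_numpy(dtype=float), 2.5)),
            float(np.percentile(metrics[k].to_numpy(dtype=float), 97.5)),
        )
        for k in metrics.columns
    }
    scores_series = None
    if calibrate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scores_series = pd.Series(
                np.nanmean(all_scores, axis=0), index=values.index, name="p_group2"
            )
    return ClassificationReport(
        task=task,
        folds=folds,
        repetitions=repetitions,
        cost=cost,
        repetition_metrics=metrics,
        confusion=confusion,
        medians=medians,
        ci95=ci95,
        scores=scores_series,
        warnings_=warn_list,
    )


def permutation_test(
    matrix: ProfileMatrix,
    task: tuple[str, str],
    n_permutations: int = 100,
    folds: int = 10,
    repetitions: int = 10,
    cost: float = 1.0,
    seed: int = 0,
    per_fold_normalize: bool = True,
) -> PermutationTestResult:
    """Stratified label-permutation test of the cross-validated accuracy.

    Each permutation reshuffles the class labels over the sera (class
    sizes preserved), runs one full stratified k-fold CV on the permuted
    labels, and records the pooled accuracy. The true-label accuracies come
    from the standard repeated CV; the one-sided Wilcoxon-Mann-Whitney
    rank-sum p-value tests whether they exceed the permutation accuracies.
    """
    group1, group2 = task
    sub = matrix.task_subset(group1, group2)
    order = np.argsort(sub.values.index.to_numpy())
    values = sub.values.iloc[order]
    groups = sub.groups.iloc[order]
    y = (groups == group1).to_numpy().astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"task {task} is degenerate: a class has no sera")
    X = values.to_numpy(dtype=float)

    root = np.random.SeedSequence(seed)
    true_seed_seq, perm_root = root.spawn(2)
    report = cross_validate(
        matrix,
        task,
        folds=folds,
        repetitions=repetitions,
        cost=cost,
        seed=_child_int(true_seed_seq),
        per_fold_normalize=per_fold_normalize,
        calibrate=False,
    )
    true_accs = report.repetition_metrics["accuracy"].to_numpy(dtype=float)

    eff_folds = report.folds  # possibly reduced for small classes
    perm_seeds = perm_root.spawn(n_permutations)
    accs = np.empty(n_permutations)
    for p in range(n_permutations):
        rng = np.random.default_rng(perm_seeds[p])
        yp = rng.permutation(y)
        counts, _ = _fold_pass(
            X,
            yp,
            folds=eff_folds,
            cost=cost,
            random_state=_child_int(perm_seeds[p]),
            per_fold_normalize=per_fold_normalize,
            calibrate=False,
        )
        _, _, acc = confusion_metrics(counts)
        accs[p] = acc

    p_value = float(
        mannwhitneyu(true_accs, accs, alternative="greater").pvalue
    )
    return PermutationTestResult(
        accuracies=accs,
        median=float(np.median(accs)),
        mean=float(np.mean(accs)),
        p_value=p_value,
        true_accuracies=true_accs,
    )


def decision_scores(report: ClassificationReport) -> tuple[pd.Series, float]:
    """Per-serum calibrated scores and the decision threshold.

    Scores are each serum's mean calibrated probability of belonging to
    the task's group 2 across repetitions (every serum is tested exactly
    once per repetition); values lie in [0, 1] and the classification
    threshold is 0.5 -- suitable for a per-serum probability strip plot.
    """
    if report.scores is None:
        raise ValueError("report carries no scores; rerun cross_validate(calibrate=True)")
    return report.scores, report.threshold
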