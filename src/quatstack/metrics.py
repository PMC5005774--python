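"""Evaluation measures and the cross-validation / self-consistency drivers.

Binary metrics (per class, one-vs-rest): sensitivity, specificity and
accuracy as percentages; MCC, precision, recall and F-measure unitless.
Multiclass metrics: CCI (correctly classified instances, %), Cohen's
kappa, and a macro-averaged F-measure.

Zero-denominator conventions are explicit because minor oligomer
classes easily produce empty confusion cells: MCC with any zero factor
in the radical is 0, F-measure with precision + recall = 0 is 0, and
Sn/Sp/ACC with a zero denominator are NaN ("NA" in reports) — never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("confusion counts are all zero")


def sensitivity(c: ConfusionCounts) -> float:
    """Sn = TP/(TP+FN) x 100; NaN if the class has no positives."""
    d = c.tp + c.fn
    return math.nan if d == 0 else 100.0 * c.tp / d


def specificity(c: ConfusionCounts) -> float:
    """Sp = TN/(TN+FP) x 100; NaN if the class has no negatives."""
    d = c.tn + c.fp
    return math.nan if d == 0 else 100.0 * c.tn / d


def accuracy(c: ConfusionCounts) -> float:
    """ACC = (TP+TN)/total x 100."""
    return 100.0 * (c.tp + c.tn) / (c.tp + c.fp + c.fn + c.tn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; any zero factor in the radical gives 0."""
    num = c.tp * c.tn - c.fn * c.fp
    fac = [(c.tp + c.fn), (c.tn + c.fp), (c.tp + c.fp), (c.tn + c.fn)]
    if 0 in fac:
        return 0.0
    return num / math.sqrt(math.prod(float(f) for f in fac))


def precision(c: ConfusionCounts) -> float:
    d = c.tp + c.fp
    return math.nan if d == 0 else c.tp / d


def recall(c: ConfusionCounts) -> float:
    d = c.tp + c.fn
    return math.nan if d == 0 else c.tp / d


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    p, r = precision(c), recall(c)
    p = 0.0 if math.isnan(p) else p
    r = 0.0 if math.isnan(r) else r
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def kappa(matrix: np.ndarray) -> float:
    """Cohen's chance-corrected agreement on a multiclass matrix.

    ``(p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o`` (the
    diagonal fraction) and chance agreement ``p_e`` from the row/column
    marginals; ``p_e == 1`` gives 0 by convention.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(m) / n
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / (n * n)
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def cci(matrix: np.ndarray) -> float:
    """Correctly classified instances, % of the matrix total."""
    m = np.asarray(matrix, dtype=float)
    n = m.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(m)) / float(n)


@dataclass
class MetricReport:
    """Derived metrics for one binary (or reduced one-vs-rest) problem."""

    sn: float
    sp: float
    acc: float
    mcc: float
    precision: float
    recall: float
    f_measure: float
    counts: ConfusionCounts | None = None

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "MetricReport":
        return cls(
            sn=sensitivity(c), sp=specificity(c), acc=accuracy(c), mcc=mcc(c),
            precision=precision(c), recall=recall(c), f_measure=f_measure(c),
            counts=c,
        )


@dataclass
class MulticlassReport:
    """Pooled multiclass evaluation with a per-class one-vs-rest breakdown."""

    classes: list[str]
    matrix: np.ndarray  # rows = true class, columns = predicted
    cci: float
    kappa: float
    f_measure: float  # macro mean over classes
    per_class: dict[str, MetricReport] = field(default_factory=dict)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, classes: list[str]) -> "MulticlassReport":
        m = np.asarray(matrix, dtype=np.int64)
        if m.shape != (len(classes), len(classes)):
            raise ValueError("matrix shape must be (n_classes, n_classes)")
        per_class = {}
        for i, name in enumerate(classes):
            tp = int(m[i, i])
            fn = int(m[i].sum() - tp)
            fp = int(m[:, i].sum() - tp)
            tn = int(m.sum() - tp - fn - fp)
            per_class[name] = MetricReport.from_counts(ConfusionCounts(tp, fp, fn, tn))
        macro_f = float(np.mean([r.f_measure for r in per_class.values()]))
        return cls(classes=list(classes), matrix=m, cci=cci(m), kappa=kappa(m),
                   f_measure=macro_f, per_class=per_class)

    def to_tsv(self, path) -> None:
        def fmt(x: float) -> str:
            return "NA" if (isinstance(x, float) and math.isnan(x)) else f"{x:.4f}"

        with open(path, "w") as fh:
            fh.write(f"# CCI(%)\t{self.cci:.2f}\tKappa\t{self.kappa:.4f}"
                     f"\tF-measure\t{self.f_measure:.4f}\n")
            fh.write("class\tSn(%)\tSp(%)\tACC(%)\tMCC\tF-measure\n")
            for name in self.classes:
                r = self.per_class[name]
                fh.write(f"{name}\t{fmt(r.sn)}\t{fmt(r.sp)}\t{fmt(r.acc)}"
                         f"\t{fmt(r.mcc)}\t{fmt(r.f_measure)}\n")


def confusion_matrix(
    y_true: list[str], y_pred: list[str], classes: list[str]
) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        m[idx[t], idx[p]] += 1
    return m


def cross_validate(
    features: dict[str, np.ndarray],
    labels: list[str],
    config,
    trainer: Callable | None = None,
) -> MulticlassReport:
    """K-fold cross-validation of the stacked classifier.

    Outer folds are stratified (seeded from ``config.seed``); per fold
    the trainer fits on the remaining folds and predicts the held-out
    records.  Confusion counts are pooled over folds and all metrics
    are computed once on the pooled matrix (micro aggregation), so the
    report is deterministic and per-class cells are never averaged
    across folds.
    """
    from .curation import assign_folds_labels
    from .stack import predict_features, train_stack

    trainer = trainer or train_stack
    classes = sorted(set(labels))
    k = config.folds
    counts = np.array([labels.count(c) for c in classes])
    if counts.min() < k:
        raise ValueError(
            f"class {classes[int(counts.argmin())]!r} has only {counts.min()} "
            f"records: every fold would not see every class; use k <= {counts.min()}"
        )
    # outer folds drawn from an offset seed so they differ from the
    # stacking folds used inside the trainer
    folds = assign_folds_labels(labels, k=k, seed=config.seed + 104729)
    y = np.array(labels)
    pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for f in range(k):
        train_mask = folds != f
        Xtr = {t: X[train_mask] for t, X in features.items()}
        Xte = {t: X[~train_mask] for t, X in features.items()}
        model = trainer(Xtr, list(y[train_mask]), config)
        pred = predict_features(Xte, model)
        pooled += confusion_matrix(list(y[~train_mask]), pred, classes)
    return MulticlassReport.from_matrix(pooled, classes)


def self_consistency(
    features: dict[str, np.ndarray],
    labels: list[str],
    config,
    trainer: Callable | None = None,
) -> MulticlassReport:
    """Train on all records and evaluate on the same records.

    An upper-bound diagnostic: it measures how much of the training
    signal the model can represent, not generalization.
    """
    from .stack import predict_features, train_stack

    if not labels:
        raise ValueError("no records to evaluate")
    trainer = trainer or train_stack
    classes = sorted(set(labels))
    model = trainer(features, labels, config)
    pred = predict_features(features, model)
    return MulticlassReport.from_matrix(confusion_matrix(labels, pred, classes), classes)
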