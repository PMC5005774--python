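"""The three-layer stacked classifier.

Layer 1: per quaternary class and per feature type (block / fund /
pseasa), a one-vs-rest RBF-kernel SVM trained on an F-score-selected
feature subset.  Layer 2: per class, an SVM combiner that fuses the
layer-1 decision values of the feature types into one score.  Layer 3:
a seeded random-forest arbiter that maps the per-class combined scores
to the final multiclass label.

Stacking hygiene: every layer-2 input is the decision value produced by
the layer-1 fold model that did NOT train on that record (out-of-fold),
and layer-3 trains on out-of-fold layer-2 scores, so no layer ever sees
a score that leaked from its own training data.  Signed margins, not
hard labels, are passed between layers: they carry confidence that the
downstream combiners can exploit.
"""

from __future__ import annotations

import hashlib
import logging
import math
import pickle
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .curation import assign_folds_labels
from .metrics import ConfusionCounts, MetricReport
from .records import ProteinRecord
from .selection import (
    DEFAULT_ELIGIBLE,
    DEFAULT_FRACTIONS,
    CandidateSubset,
    candidate_subsets,
    rank_features,
    select_best,
)

log = logging.getLogger(__name__)


@dataclass
class StackConfig:
    """Everything the trainer needs, with the shipped defaults.

    ``feature_types`` defaults to block + fund (the combination with the
    best cross-validated stacking performance; pseasa is implemented but
    not in the default stack).  ``negatives`` controls the one-vs-rest
    framing: ``within_group`` draws the negatives of a class from the
    same assembly group (monomer / homo / hetero), falling back to all
    records when the group has a single class; ``global`` always uses
    all records.
    """

    feature_types: tuple[str, ...] = ("block", "fund")
    folds: int = 10
    seed: int = 0
    svm_c_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    svm_gamma: str | float = "scale"
    n_trees: int = 500
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    eligible_fractions: tuple[float, ...] = DEFAULT_ELIGIBLE
    negatives: str = "within_group"

    def __post_init__(self) -> None:
        if not self.feature_types:
            raise ValueError("feature_types must be nonempty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.negatives not in ("within_group", "global"):
            raise ValueError("negatives must be 'within_group' or 'global'")


@dataclass
class Layer1Unit:
    """One (class, feature type) binary model and its chosen subset."""

    class_name: str
    feature_type: str
    subset: list[int]  # 1-based feature indices, ranking order
    svm_c: float
    model: SVC
    cv_report: MetricReport


@dataclass
class StackModel:
    """The trained three-layer predictor."""

    config: StackConfig
    classes: list[str]
    layer1: dict[tuple[str, str], Layer1Unit]
    layer2: dict[str, SVC]
    arbiter: RandomForestClassifier
    folds: np.ndarray = field(repr=False)
    fold_train_indices: dict[int, np.ndarray] = field(repr=False)
    oof_layer1: np.ndarray = field(repr=False)
    oof_layer2: np.ndarray = field(repr=False)
    db_digests: dict[str, str] = field(default_factory=dict)

    def digest(self) -> str:
        """Content hash of the whole trained model (determinism check)."""
        payload = pickle.dumps(
            (
                asdict_config(self.config),
                self.classes,
                {k: (u.subset, u.svm_c, _svc_state(u.model)) for k, u in self.layer1.items()},
                {k: _svc_state(m) for k, m in self.layer2.items()},
                _rf_state(self.arbiter),
                self.db_digests,
            )
        )
        return hashlib.sha256(payload).hexdigest()


@dataclass
class PredictionResult:
    """Final label plus the per-class combined scores that produced it."""

    record_id: str
    label: str
    scores: dict[str, float]


def asdict_config(config: StackConfig) -> dict:
    return asdict(config)


def _svc_state(m: SVC) -> tuple:
    return (m.support_vectors_.tobytes(), m.dual_coef_.tobytes(),
            m.intercept_.tobytes(), float(m.C), str(m.gamma))


def _rf_state(rf: RandomForestClassifier) -> tuple:
    h = hashlib.sha256()
    for est in rf.estimators_:
        t = est.tree_
        h.update(t.feature.tobytes())
        h.update(t.threshold.tobytes())
        h.update(t.value.tobytes())
    return (rf.n_estimators, rf.random_state, h.hexdigest())


def group_of(class_name: str) -> str:
    return class_name.split(":")[0]


def _fit_svc(X: np.ndarray, y: np.ndarray, c: float, gamma) -> SVC:
    svc = SVC(kernel="rbf", C=c, gamma=gamma, class_weight="balanced")
    svc.fit(X, y.astype(int))
    return svc


def _oof_decisions(
    X: np.ndarray,
    y_bin: np.ndarray,
    train_mask: np.ndarray,
    folds: np.ndarray,
    k: int,
    c: float,
    gamma,
) -> np.ndarray:
    """Out-of-fold decision values for every record.

    The model for fold ``f`` trains on ``train_mask`` records outside
    fold ``f`` and scores every record inside fold ``f`` (including
    records outside the training mask, which still need layer-2 inputs).
    """
    out = np.zeros(len(y_bin))
    for f in range(k):
        tr = train_mask & (folds != f)
        te = folds == f
        if not te.any():
            continue
        if len(np.unique(y_bin[tr])) < 2:
            continue  # degenerate fold: neutral score 0
        svc = _fit_svc(X[tr], y_bin[tr], c, gamma)
        out[te] = svc.decision_function(X[te])
    return out


def _cv_report(
    X: np.ndarray,
    y_bin: np.ndarray,
    mask: np.ndarray,
    folds: np.ndarray,
    k: int,
    c: float,
    gamma,
) -> MetricReport:
    """Cross-validated binary report on the masked records."""
    dec = _oof_decisions(X, y_bin, mask, folds, k, c, gamma)
    pred = dec[mask] >= 0
    truth = y_bin[mask]
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return MetricReport.from_counts(ConfusionCounts(tp, fp, fn, tn))


def train_layer1(
    features: dict[str, np.ndarray],
    labels: list[str],
    config: StackConfig,
    folds: np.ndarray,
) -> tuple[dict[tuple[str, str], Layer1Unit], np.ndarray]:
    """Per-(class, type) selected-subset SVMs plus their OOF decisions.

    Returns the units and an ``(n_records, n_classes * n_types)``
    matrix of out-of-fold decision values, column order = classes outer,
    feature types inner.
    """
    classes = sorted(set(labels))
    y = np.array(labels)
    n = len(labels)
    types = config.feature_types
    for t in types:
        if t not in features:
            raise ValueError(f"feature type {t!r} missing from the feature dict")
        if features[t].shape[0] != n:
            raise ValueError(f"feature type {t!r}: row count != number of records")
    oof = np.zeros((n, len(classes) * len(types)))
    units: dict[tuple[str, str], Layer1Unit] = {}
    groups = np.array([group_of(c) for c in y])
    for ci, cls in enumerate(classes):
        if not np.any(y == cls):
            raise ValueError(f"class {cls!r} absent from training data")
        if config.negatives == "within_group":
            mask = groups == group_of(cls)
            if len(np.unique(y[mask])) < 2:
                mask = np.ones(n, dtype=bool)  # lone class in group: global negatives
        else:
            mask = np.ones(n, dtype=bool)
        y_bin = y == cls
        for ti, t in enumerate(types):
            X = features[t]
            ranking = rank_features(X[mask], y_bin[mask])
            cands = candidate_subsets(ranking, config.fractions, config.eligible_fractions)
            pool = [c for c in cands if c.eligible] or cands
            reports, best_cs = [], []
            for cand in pool:
                cols = np.array(cand.indices) - 1
                per_c = [
                    (_cv_report(X[:, cols], y_bin, mask, folds, config.folds, c, config.svm_gamma), c)
                    for c in config.svm_c_grid
                ]
                rep, c_best = max(
                    per_c,
                    key=lambda rc: (_nan_low(rc[0].mcc), _nan_low(rc[0].sn), _nan_low(rc[0].sp)),
                )
                reports.append(rep)
                best_cs.append(c_best)
            chosen = select_best(pool, reports)
            pos = pool.index(chosen)
            c_star, report = best_cs[pos], reports[pos]
            cols = np.array(chosen.indices) - 1
            oof[:, ci * len(types) + ti] = _oof_decisions(
                X[:, cols], y_bin, mask, folds, config.folds, c_star, config.svm_gamma
            )
            final = _fit_svc(X[mask][:, cols], y_bin[mask], c_star, config.svm_gamma)
            units[(cls, t)] = Layer1Unit(cls, t, list(chosen.indices), c_star, final, report)
    return units, oof


def _nan_low(x: float) -> float:
    return -math.inf if (isinstance(x, float) and math.isnan(x)) else x


def train_layer2(
    oof_layer1: np.ndarray,
    labels: list[str],
    config: StackConfig,
    folds: np.ndarray,
) -> tuple[dict[str, SVC], np.ndarray]:
    """Per-class combiners over the layer-1 OOF values.

    Each combiner consumes exactly ``len(feature_types)`` inputs.  The
    returned ``(n_records, n_classes)`` matrix holds out-of-fold
    combined scores for layer-3 training.
    """
    classes = sorted(set(labels))
    y = np.array(labels)
    n_types = len(config.feature_types)
    all_mask = np.ones(len(labels), dtype=bool)
    combiners: dict[str, SVC] = {}
    oof2 = np.zeros((len(labels), len(classes)))
    for ci, cls in enumerate(classes):
        X2 = oof_layer1[:, ci * n_types : (ci + 1) * n_types]
        y_bin = y == cls
        oof2[:, ci] = _oof_decisions(X2, y_bin, all_mask, folds, config.folds, 1.0, config.svm_gamma)
        combiners[cls] = _fit_svc(X2, y_bin, 1.0, config.svm_gamma)
    return combiners, oof2


def train_layer3(
    oof_layer2: np.ndarray, labels: list[str], config: StackConfig
) -> RandomForestClassifier:
    """Seeded random-forest arbiter over the per-class combined scores."""
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        random_state=(config.seed * 31 + 7) % (2**31),
        n_jobs=1,
    )
    rf.fit(oof_layer2, labels)
    return rf


def train_stack(
    features: dict[str, np.ndarray], labels: list[str], config: StackConfig
) -> StackModel:
    """Train all three layers; fully deterministic given config + seed."""
    if not labels:
        raise ValueError("no training records")
    folds = assign_folds_labels(labels, k=config.folds, seed=config.seed)
    units, oof1 = train_layer1(features, labels, config, folds)
    combiners, oof2 = train_layer2(oof1, labels, config, folds)
    arbiter = train_layer3(oof2, labels, config)
    classes = sorted(set(labels))
    fold_train = {f: np.flatnonzero(folds != f) for f in range(config.folds)}
    return StackModel(
        config=config,
        classes=classes,
        layer1=units,
        layer2=combiners,
        arbiter=arbiter,
        folds=folds,
        fold_train_indices=fold_train,
        oof_layer1=oof1,
        oof_layer2=oof2,
    )


def combined_scores(features: dict[str, np.ndarray], model: StackModel) -> np.ndarray:
    """Layer-1 + layer-2 forward pass: (n_records, n_classes) scores."""
    types = model.config.feature_types
    n = next(iter(features.values())).shape[0]
    scores = np.zeros((n, len(model.classes)))
    for ci, cls in enumerate(model.classes):
        d1 = np.empty((n, len(types)))
        for ti, t in enumerate(types):
            unit = model.layer1[(cls, t)]
            cols = np.array(unit.subset) - 1
            d1[:, ti] = unit.model.decision_function(features[t][:, cols])
        scores[:, ci] = model.layer2[cls].decision_function(d1)
    return scores


def predict_features(features: dict[str, np.ndarray], model: StackModel) -> list[str]:
    """Forward pass returning one label string per record."""
    return list(model.arbiter.predict(combined_scores(features, model)))


def predict(
    records: list[ProteinRecord],
    model: StackModel,
    block_db=None,
    domain_db=None,
    pseasa_params=None,
) -> list[PredictionResult]:
    """Encode records against the model's databases and classify them.

    Database digests recorded at training time are enforced: scoring
    against a different database silently permutes the feature space,
    so a mismatch is refused.
    """
    from .features import encode_features

    for name, db in (("block", block_db), ("fund", domain_db)):
        want = model.db_digests.get(name)
        if want is not None and db is not None and db.digest() != want:
            raise ValueError(
                f"{name} database digest mismatch: the model was trained "
                f"against a different {name} database; re-train or load the "
                "original database"
            )
    feats = encode_features(
        records,
        block_db=block_db,
        domain_db=domain_db,
        pseasa_params=pseasa_params,
        feature_types=model.config.feature_types,
    )
    scores = combined_scores(feats, model)
    labels = model.arbiter.predict(scores)
    return [
        PredictionResult(r.id, lab, dict(zip(model.classes, row)))
        for r, lab, row in zip(records, labels, scores)
    ]
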