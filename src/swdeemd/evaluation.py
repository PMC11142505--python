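"""Leakage-safe stratified cross-validation with per-class metrics,
pooled confusion matrices and ROC curves.

SMOTE, when enabled, is applied to the *training* rows of each fold only,
strictly after the split: test folds contain original rows exclusively, and
every fold records a synthetic-row audit count (always 0 in test) so the
no-leakage contract is checkable from the report.

Because the positive-class convention materially changes precision/recall
on imbalanced data, per-fold metrics and pooled confusion matrices are
always reported under *both* conventions (positive = healthy minority and
positive = abnormal majority).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .resampling import SmoteConfig, smote_oversample

LABELS = ("healthy", "abnormal")


@dataclass
class CvConfig:
    n_folds: int = 10
    seed: int = 0
    apply_smote: bool = False
    smote_cfg: SmoteConfig = field(default_factory=SmoteConfig)
    positive_class: str = "healthy"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.positive_class not in LABELS:
            raise ValueError(f"positive_class must be one of {LABELS}")


@dataclass
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive: str) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t, pos_p = y_true == positive, y_pred == positive
        return cls(
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            tp=int(np.sum(pos_t & pos_p)),
        )


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, recall, precision and F-score in percent.

    Zero-denominator cases (e.g. a degenerate majority-only predictor with
    a minority positive class) report 0 and are flagged rather than NaN.
    """
    if cm.n_total < 1:
        raise ValueError("empty confusion matrix")
    flags = []
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.n_total
    if cm.tp + cm.fn > 0:
        recall = 100.0 * cm.tp / (cm.tp + cm.fn)
    else:
        recall, flags = 0.0, flags + ["recall_undefined"]
    if cm.tp + cm.fp > 0:
        precision = 100.0 * cm.tp / (cm.tp + cm.fp)
    else:
        precision, flags = 0.0, flags + ["precision_undefined"]
    if precision + recall > 0:
        f_score = 2.0 * precision * recall / (precision + recall)
    else:
        f_score, flags = 0.0, flags + ["f_score_undefined"]
    return {
        "accuracy": accuracy,
        "recall": recall,
        "precision": precision,
        "f_score": f_score,
        "flags": flags,
    }


def stratified_folds(labels, cfg: CvConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified partition into ``n_folds`` (train, test) index
    pairs; per-class counts across test folds differ by at most one."""
    labels = np.asarray(labels)
    for lab, count in zip(*np.unique(labels, return_counts=True)):
        if count < cfg.n_folds:
            raise ValueError(
                f"class {lab!r} has {count} rows < n_folds={cfg.n_folds}"
            )
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    return [
        (train, test) for train, test in skf.split(np.zeros(len(labels)), labels)
    ]


def stratified_holdout(
    labels, test_fraction: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Single stratified train/test split (the fixed-holdout protocol)."""
    idx = np.arange(len(labels))
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=np.asarray(labels), random_state=seed
    )
    return np.sort(train), np.sort(test)


def roc_points(scores, labels, positive: str = "healthy") -> list[tuple[float, float]]:
    """ROC staircase from a threshold sweep over the scores.

    Returns (FPR, TPR) points from (0,0) to (1,1) with ties grouped.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _roc_curve(labels == positive, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def roc_auc(scores, labels, positive: str = "healthy") -> float:
    pts = roc_points(scores, labels, positive)
    fpr, tpr = zip(*pts)
    return float(_auc(np.array(fpr), np.array(tpr)))


def default_classifiers(seed: int = 0) -> dict:
    """The study's classifier grid with its published hyperparameters.

    ID3 approximated as an entropy-criterion tree; CART is the Gini tree;
    the rest are the standard scikit-learn learners.
    """
    return {
        "ID3": DecisionTreeClassifier(criterion="entropy", random_state=seed),
        "CART": DecisionTreeClassifier(criterion="gini", random_state=seed),
        "Bagging": BaggingClassifier(n_estimators=10, random_state=seed),
        "GBC": GradientBoostingClassifier(
            learning_rate=0.1, n_estimators=100, max_depth=3, random_state=seed
        ),
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed),
        "SVM": SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed),
        "MLP": MLPClassifier(
            hidden_layer_sizes=(100,), max_iter=200, random_state=seed
        ),
        "ET": ExtraTreesClassifier(n_estimators=100, random_state=seed),
    }


def _positive_scores(model, x: np.ndarray, positive: str) -> np.ndarray:
    """Continuous positive-class score, whatever the estimator exposes."""
    classes = list(model.classes_)
    pos_col = classes.index(positive)
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, pos_col]
    s = model.decision_function(x)
    # decision_function is positive towards classes_[1]
    return s if pos_col == 1 else -s


@dataclass
class EvaluationReport:
    """Per-classifier fold metrics (both positive-class conventions),
    pooled confusion matrices, ROC curves and full provenance."""

    classifiers: dict
    metadata: dict

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(
            {"classifiers": self.classifiers, "metadata": self.metadata}, **kwargs
        )


def run_experiment(
    matrix: FeatureMatrix,
    classifiers: dict | None = None,
    cfg: CvConfig | None = None,
) -> EvaluationReport:
    """Stratified k-fold evaluation of a classifier grid on one feature
    matrix, with optional train-fold-only SMOTE.

    The input matrix must contain only original rows; oversampling happens
    inside each fold, after the split.  Predictions and scores are pooled
    across folds for the confusion matrices and ROC; per-fold metrics are
    macro-averaged.
    """
    cfg = cfg or CvConfig()
    if classifiers is None:
        classifiers = default_classifiers(cfg.seed)
    if matrix.is_synthetic.any():
        raise ValueError(
            "input matrix already contains synthetic rows; cross-validation "
            "must start from original data (SMOTE is applied per training fold)"
        )
    folds = stratified_folds(matrix.labels, cfg)
    pos = cfg.positive_class
    neg = next(l for l in LABELS if l != pos)
    n = matrix.n_rows

    results: dict = {}
    for name, estimator in classifiers.items():
        pooled_pred = np.full(n, "", dtype=object)
        pooled_score = np.full(n, np.nan)
        fold_metrics = {pos: [], neg: []}
        fold_errors = []
        leakage_audit = []
        evaluated = np.zeros(n, dtype=bool)
        for k, (train_idx, test_idx) in enumerate(folds):
            train = matrix.subset(train_idx)
            if cfg.apply_smote:
                train = smote_oversample(
                    train, replace(cfg.smote_cfg, seed=cfg.smote_cfg.seed + k)
                )
            test = matrix.subset(test_idx)
            leakage_audit.append(int(test.is_synthetic.sum()))
            try:
                model = clone(estimator)
                model.fit(train.values, train.labels)
                y_pred = model.predict(test.values)
                score = _positive_scores(model, test.values, pos)
            except Exception as exc:  # classifier failure: record, skip fold
                fold_errors.append({"fold": k, "error": f"{type(exc).__name__}: {exc}"})
                continue
            pooled_pred[test_idx] = y_pred
            pooled_score[test_idx] = score
            evaluated[test_idx] = True
            for convention in (pos, neg):
                cm = ConfusionMatrix.from_predictions(
                    test.labels, y_pred, convention
                )
                fold_metrics[convention].append(compute_metrics(cm))

        entry: dict = {
            "fold_metrics": fold_metrics,
            "fold_errors": fold_errors,
            "test_synthetic_rows_per_fold": leakage_audit,
        }
        if evaluated.any():
            y_true = matrix.labels[evaluated]
            y_pred_all = pooled_pred[evaluated].astype(str)
            scores_all = pooled_score[evaluated]
            for convention in (pos, neg):
                cm = ConfusionMatrix.from_predictions(y_true, y_pred_all, convention)
                mean_metrics = {
                    key: float(
                        np.mean([m[key] for m in fold_metrics[convention]])
                    )
                    for key in ("accuracy", "recall", "precision", "f_score")
                    if fold_metrics[convention]
                }
                entry[f"positive_{convention}"] = {
                    "pooled_confusion": asdict(cm),
                    "mean_fold_metrics": mean_metrics,
                    "pooled_metrics": compute_metrics(cm),
                }
            entry["roc"] = roc_points(scores_all, y_true, pos)
            entry["auc"] = roc_auc(scores_all, y_true, pos)
            entry["n_evaluated"] = int(evaluated.sum())
        results[name] = entry

    metadata = {
        "n_rows": n,
        "class_counts": matrix.class_counts(),
        "cv": {
            "n_folds": cfg.n_folds,
            "seed": cfg.seed,
            "apply_smote": cfg.apply_smote,
            "positive_class": cfg.positive_class,
        },
        "smote": asdict(cfg.smote_cfg),
        "columns": list(matrix.column_names),
    }
    return EvaluationReport(classifiers=results, metadata=metadata)
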