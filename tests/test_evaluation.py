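import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from swdeemd import (
    ConfusionMatrix,
    CvConfig,
    SmoteConfig,
    compute_metrics,
    roc_auc,
    roc_points,
    run_experiment,
    stratified_folds,
    stratified_holdout,
)


def test_stratified_fold_counts_on_study_sizes():
    """1533 abnormal + 342 healthy over 10 folds: 153-154 and 34-35 per
    test fold, disjoint folds covering every row exactly once."""
    labels = np.array(["abnormal"] * 1533 + ["healthy"] * 342)
    folds = stratified_folds(labels, CvConfig(n_folds=10, seed=0))
    seen = np.zeros(len(labels), dtype=int)
    for train, test in folds:
        seen[test] += 1
        assert len(np.intersect1d(train, test)) == 0
        n_ab = int(np.sum(labels[test] == "abnormal"))
        n_he = int(np.sum(labels[test] == "healthy"))
        assert n_ab in (153, 154) and n_he in (34, 35)
    assert np.all(seen == 1)  # a partition


def test_stratified_folds_deterministic_and_validated():
    labels = np.array(["healthy"] * 30 + ["abnormal"] * 90)
    cfg = CvConfig(n_folds=5, seed=3)
    a = stratified_folds(labels, cfg)
    b = stratified_folds(labels, cfg)
    for (tr1, te1), (tr2, te2) in zip(a, b):
        np.testing.assert_array_equal(te1, te2)
    with pytest.raises(ValueError, match="< n_folds"):
        stratified_folds(np.array(["healthy"] * 3 + ["abnormal"] * 50),
                         CvConfig(n_folds=5))


def test_stratified_holdout_preserves_proportions():
    labels = np.array(["abnormal"] * 170 + ["healthy"] * 38)
    train, test = stratified_holdout(labels, test_fraction=0.2, seed=0)
    assert len(test) == pytest.approx(0.2 * len(labels), abs=1)
    frac = np.mean(labels[test] == "healthy")
    assert frac == pytest.approx(38 / 208, abs=0.05)


def test_metrics_degenerate_majority_predictor():
    """Majority-only predictions on a 170-abnormal/38-healthy test split
    with positive=healthy: accuracy 81.7%, recall/precision 0 and flagged
    -- the signature of the degenerate classifiers on imbalanced data."""
    cm = ConfusionMatrix(tn=170, fp=0, fn=38, tp=0)
    m = compute_metrics(cm)
    assert m["accuracy"] == pytest.approx(81.73, abs=0.05)
    assert m["recall"] == 0.0 and m["precision"] == 0.0
    assert "precision_undefined" in m["flags"]


def test_metrics_perfect_predictor():
    m = compute_metrics(ConfusionMatrix(tn=100, fp=0, fn=0, tp=50))
    assert all(m[k] == 100.0 for k in ("accuracy", "recall", "precision", "f_score"))


def test_metrics_from_published_confusion_rates():
    """98.9% of 170 abnormal and 60.5% of 38 healthy correct gives
    accuracy 91.8-92.0% after integer rounding of the counts."""
    tn = round(0.989 * 170)  # abnormal = negative for positive=healthy
    tp = round(0.605 * 38)
    cm = ConfusionMatrix(tn=tn, fp=170 - tn, fn=38 - tp, tp=tp)
    acc = compute_metrics(cm)["accuracy"]
    assert 91.8 <= acc <= 92.0


def test_confusion_matrix_total_and_validation():
    cm = ConfusionMatrix.from_predictions(
        np.array(["healthy", "abnormal", "healthy"]),
        np.array(["healthy", "healthy", "abnormal"]),
        positive="healthy",
    )
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 0)
    with pytest.raises(ValueError):
        ConfusionMatrix(tn=-1, fp=0, fn=0, tp=0)


def test_roc_ideal_reversal_and_permutation(rng):
    labels = np.array(["healthy"] * 50 + ["abnormal"] * 50)
    perfect = np.r_[np.ones(50), np.zeros(50)]
    pts = roc_points(perfect, labels)
    assert (0.0, 1.0) in pts  # top-left ideal point
    assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
    fprs = [p[0] for p in pts]
    assert fprs == sorted(fprs)
    a = roc_auc(perfect, labels)
    assert a == 1.0 and roc_auc(-perfect, labels) == pytest.approx(1.0 - a)
    random_scores = rng.standard_normal(2000)
    null_labels = np.array(["healthy", "abnormal"] * 1000)
    assert abs(roc_auc(random_scores, null_labels) - 0.5) < 0.05


def test_roc_rejects_bad_input():
    with pytest.raises(ValueError):
        roc_points(np.array([np.inf, 0.0]), np.array(["healthy", "abnormal"]))
    with pytest.raises(ValueError):
        roc_points(np.array([0.1, 0.2]), np.array(["healthy", "healthy"]))


def _cv_tree(seed=0, **kwargs):
    return {"tree": DecisionTreeClassifier(max_depth=4, random_state=seed)}, CvConfig(
        n_folds=5, seed=seed, **kwargs
    )


def test_run_experiment_smote_never_reaches_test_folds(small_matrix):
    classifiers, cfg = _cv_tree(apply_smote=True, smote_cfg=SmoteConfig(seed=1))
    report = run_experiment(small_matrix, classifiers, cfg)
    entry = report.classifiers["tree"]
    assert entry["test_synthetic_rows_per_fold"] == [0] * cfg.n_folds
    assert entry["positive_healthy"]["pooled_confusion"]["tp"] >= 0
    total = sum(entry["positive_healthy"]["pooled_confusion"].values())
    assert total == small_matrix.n_rows  # pooled confusion covers the dataset


def test_run_experiment_rejects_pre_oversampled_input(small_matrix):
    from swdeemd import smote_oversample

    tainted = smote_oversample(small_matrix, SmoteConfig(seed=0))
    classifiers, cfg = _cv_tree()
    with pytest.raises(ValueError, match="synthetic"):
        run_experiment(tainted, classifiers, cfg)


def test_run_experiment_reports_both_conventions(small_matrix):
    classifiers, cfg = _cv_tree()
    report = run_experiment(small_matrix, classifiers, cfg)
    entry = report.classifiers["tree"]
    for side in ("positive_healthy", "positive_abnormal"):
        assert set(entry[side]["mean_fold_metrics"]) == {
            "accuracy", "recall", "precision", "f_score",
        }
    h = entry["positive_healthy"]["pooled_confusion"]
    a = entry["positive_abnormal"]["pooled_confusion"]
    assert (h["tp"], h["tn"]) == (a["tn"], a["tp"])  # conventions are mirrored


def test_run_experiment_byte_identical_reruns(small_matrix):
    classifiers, cfg = _cv_tree(apply_smote=True)
    r1 = run_experiment(small_matrix, classifiers, cfg)
    classifiers2, cfg2 = _cv_tree(apply_smote=True)
    r2 = run_experiment(small_matrix, classifiers2, cfg2)
    assert r1.to_json() == r2.to_json()


def test_classifier_failure_recorded_not_fatal(small_matrix):
    class Exploding(DecisionTreeClassifier):
        def fit(self, *a, **k):
            raise RuntimeError("boom")

    report = run_experiment(
        small_matrix, {"bad": Exploding()}, CvConfig(n_folds=5, seed=0)
    )
    entry = report.classifiers["bad"]
    assert len(entry["fold_errors"]) == 5
    assert "auc" not in entry
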