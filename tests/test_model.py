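import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)

from lbpradiomics.model import (
    CohortTable,
    TextureRadiomicsModel,
    balanced_holdout_split,
    cross_validate,
    decision_scores,
    evaluate,
    fit_random_forest,
    fit_svm,
    metrics_from_confusion,
    rfe_select,
)


# ---------------------------------------------------------------- split ----
def test_balanced_split_cohort_arithmetic():
    """72 subjects (39/33), 25% test -> train 54 (27/27), test 18 (12/6)."""
    labels = pd.Series([1] * 39 + [0] * 33, index=[f"s{i}" for i in range(72)])
    split = balanced_holdout_split(labels, test_fraction=0.25, seed=3)
    tr, te = labels[split == "train"], labels[split == "test"]
    assert len(tr) == 54 and (tr == 1).sum() == 27 and (tr == 0).sum() == 27
    assert len(te) == 18 and (te == 1).sum() == 12 and (te == 0).sum() == 6


def test_balanced_split_small_cohort():
    labels = pd.Series([1] * 4 + [0] * 4)
    split = balanced_holdout_split(labels, test_fraction=0.25, seed=0)
    tr = labels[split == "train"]
    assert len(tr) == 6 and (tr == 1).sum() == 3
    assert (split == "test").sum() == 2


def test_balanced_split_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        balanced_holdout_split(pd.Series([1] * 10))


def test_balanced_split_class_too_small():
    labels = pd.Series([1] * 20 + [0] * 2)
    with pytest.raises(ValueError, match="needed for a balanced"):
        balanced_holdout_split(labels, test_fraction=0.25)


def test_balanced_split_seeded_determinism():
    labels = pd.Series([1] * 12 + [0] * 10)
    a = balanced_holdout_split(labels, seed=5)
    b = balanced_holdout_split(labels, seed=5)
    c = balanced_holdout_split(labels, seed=6)
    assert a.equals(b)
    assert not a.equals(c)


# ------------------------------------------------------------------ RFE ----
def _toy_matrix(rng, n=24, p=10, informative=None):
    X = rng.normal(size=(n, p))
    y = rng.integers(0, 2, n)
    y[: n // 2], y[n // 2 :] = 0, 1
    if informative is not None:
        X[:, informative] = y * 2.0  # column alone determines the label
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(p)]), y


def test_rfe_threshold_zero_selects_all(rng):
    X, y = _toy_matrix(rng)
    sel = rfe_select(X, y, threshold=0.0)
    assert sel.selected.all()


def test_rfe_selected_count_150_at_09(rng):
    X, y = _toy_matrix(rng, n=30, p=150)
    sel = rfe_select(X, y, threshold=0.9)
    assert sel.n_selected == 15  # ceil(0.1 * 150)


@settings(deadline=None, max_examples=25)
@given(
    p=st.integers(2, 40),
    threshold=st.floats(0.0, 0.99),
    seed=st.integers(0, 100),
)
def test_rfe_selected_count_formula(p, threshold, seed):
    """Threshold t keeps exactly ceil((1 - t) * N) features."""
    rng = np.random.default_rng(seed)
    X, y = _toy_matrix(rng, n=16, p=p)
    sel = rfe_select(X, y, threshold=threshold, estimator_kind="svm")
    assert sel.n_selected == math.ceil((1.0 - threshold) * p)


@pytest.mark.parametrize("kind", ["svm", "rf"])
def test_rfe_recovers_informative_feature(kind, rng):
    """A feature that alone determines the label ranks first, score 1.0."""
    X, y = _toy_matrix(rng, n=30, p=10, informative=3)
    sel = rfe_select(X, y, estimator_kind=kind, threshold=0.9, seed=0)
    assert sel.rfe_rank[3] == 1
    assert sel.importance_score[3] == 1.0
    assert sel.selected[3]
    # scores are monotone non-increasing in rank
    frame = sel.frame()
    assert (np.diff(frame["importance_score"]) <= 0).all()


def test_rfe_all_constant_rejected(rng):
    X = pd.DataFrame(np.ones((10, 4)))
    with pytest.raises(ValueError, match="constant"):
        rfe_select(X, np.array([0, 1] * 5))


# ---------------------------------------------------------- classifiers ----
def test_svm_separable_toy():
    X = np.array([[0, 0], [0, 1], [3, 0], [3, 1]], dtype=float)
    y = np.array([0, 0, 1, 1])
    model = fit_svm(X, y)
    assert (model.predict(X) == y).all()


def test_svm_rejects_nan():
    X = np.array([[0.0, np.nan], [1, 1], [2, 2], [3, 3]])
    with pytest.raises(ValueError, match="NaN"):
        fit_svm(X, [0, 0, 1, 1])


def test_svm_single_informative_feature_auc_one():
    y = np.array([0, 1] * 10)
    X = y.reshape(-1, 1).astype(float)
    model = fit_svm(X, y)
    rep = evaluate(model, X, y)
    assert rep.auc_roc == 1.0


def test_permuted_labels_give_chance_cv(rng):
    """Pure-noise features: CV accuracy within a binomial band around 0.5."""
    X = rng.normal(size=(60, 8))
    y = np.array([0, 1] * 30)
    cv = cross_validate("svm", X, y, k=10, seed=0)
    # 60 predictions at p=0.5: 95% band roughly +/- 0.13
    assert 0.30 <= cv["mean_accuracy"] <= 0.70


@pytest.mark.parametrize("kind", ["svm", "rf"])
def test_cross_validate_separable(kind):
    y = np.array([0, 1] * 10)
    X = np.column_stack([y * 4.0, np.arange(20) * 0.01])
    cv = cross_validate(kind, X, y, k=10, seed=1)
    assert cv["mean_accuracy"] == 1.0


def test_cross_validate_leave_one_out_and_k_too_large():
    y = np.array([0, 1] * 5)
    X = np.column_stack([y * 3.0, y * -1.0])
    cv = cross_validate("svm", X, y, k=10, seed=0)  # k = n here
    assert len(cv["fold_accuracy"]) == 10
    with pytest.raises(ValueError, match="exceeds"):
        cross_validate("svm", X, y, k=11)


def test_random_forest_seeded_determinism(rng):
    X = rng.normal(size=(30, 6))
    y = rng.integers(0, 2, 30)
    a = fit_random_forest(X, y, seed=4).predict(X)
    b = fit_random_forest(X, y, seed=4).predict(X)
    assert np.array_equal(a, b)
    assert decision_scores(fit_random_forest(X, y, seed=4), X).shape == (30,)


# -------------------------------------------------------------- metrics ----
def test_confusion_metrics_unbalanced_test_composition():
    """TP=11 FN=1 FP=2 TN=4 (12 patients / 6 controls) ->
    accuracy 83.33%, precision 84.62%, recall 91.67%, f1 88.0%."""
    m = metrics_from_confusion(tp=11, fn=1, fp=2, tn=4)
    assert round(100 * m["accuracy"], 2) == 83.33
    assert round(100 * m["precision"], 2) == 84.62
    assert round(100 * m["recall"], 2) == 91.67
    assert round(100 * m["f1"], 2) == 88.0


@settings(deadline=None, max_examples=100)
@given(
    tp=st.integers(0, 30), fn=st.integers(0, 30),
    fp=st.integers(0, 30), tn=st.integers(0, 30),
)
def test_confusion_metric_identities_vs_sklearn(tp, fn, fp, tn):
    """Hand formulas agree with sklearn on expanded label arrays."""
    if tp + fn + fp + tn == 0:
        return
    y_true = np.array([1] * (tp + fn) + [0] * (fp + tn))
    y_pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
    m = metrics_from_confusion(tp, fn, fp, tn)
    assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
    assert m["precision"] == pytest.approx(
        precision_score(y_true, y_pred, zero_division=0))
    assert m["recall"] == pytest.approx(
        recall_score(y_true, y_pred, zero_division=0))
    assert m["f1"] == pytest.approx(f1_score(y_true, y_pred, zero_division=0))
    assert all(0.0 <= m[k] <= 1.0 for k in m)


class _StubModel:
    """Fixed predictions/scores, for testing evaluate in isolation."""

    def __init__(self, preds, scores):
        self.preds, self.scores = np.asarray(preds), np.asarray(scores)

    def predict(self, X):
        return self.preds

    def decision_function(self, X):
        return self.scores


def test_evaluate_all_correct():
    y = np.array([0, 1] * 9)
    model = _StubModel(y, y.astype(float))
    rep = evaluate(model, np.zeros((18, 1)), y)
    assert rep.accuracy == 1.0 and rep.f1 == 1.0 and rep.n_test == 18


def test_evaluate_tied_scores_auc_half():
    y = np.array([0, 1, 0, 1])
    model = _StubModel(np.array([1, 1, 1, 1]), np.zeros(4))
    rep = evaluate(model, np.zeros((4, 1)), y)
    assert rep.auc_roc == pytest.approx(0.5)


def test_evaluate_empty_test_set():
    with pytest.raises(ValueError, match="empty test set"):
        evaluate(_StubModel([], []), np.zeros((0, 1)), np.array([]))


# --------------------------------------------------- model orchestration ----
def _small_cohort(rng, n=24, p=20):
    X = rng.normal(size=(n, p))
    y = np.array([0, 1] * (n // 2))
    X[:, 2] += y * 5.0  # two strongly informative features
    X[:, 5] += y * 5.0
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)])
    df.insert(0, "label", y)
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    return CohortTable.from_frame(df)


@pytest.mark.parametrize("kind", ["svm", "rf"])
def test_model_fit_pipeline_determinism(kind, rng):
    """Same seed -> identical split, selection, CV scores and test report."""
    cohort = _small_cohort(rng)
    kw = dict(estimator=kind, rfe_threshold=0.8, folds=5, seed=11)
    r1 = TextureRadiomicsModel(cohort, **kw).fit()
    r2 = TextureRadiomicsModel(cohort, **kw).fit()
    assert r1.cohort.split.equals(r2.cohort.split)
    assert np.array_equal(r1.selection.rfe_rank, r2.selection.rfe_rank)
    assert r1.cv == r2.cv
    assert r1.report.to_dict() == r2.report.to_dict()
    assert "test accuracy" in r1.summary()


def test_model_separable_cohort_beats_chance(rng):
    cohort = _small_cohort(rng, n=40)
    res = TextureRadiomicsModel(cohort, estimator="svm", rfe_threshold=0.8,
                                folds=5, seed=2).fit()
    assert res.report.accuracy > 0.5
    assert res.selection.n_selected == math.ceil(0.2 * 20)
    assert "f2" in res.selected_features


def test_cohort_table_csv_roundtrip(tmp_path, rng):
    cohort = _small_cohort(rng, n=8, p=8)
    df = cohort.features.copy()
    df.insert(0, "label", cohort.labels)
    df = df.reset_index(names="subject_id")
    path = tmp_path / "features.csv"
    df.to_csv(path, index=False)
    loaded = CohortTable.from_csv(path)
    assert loaded.features.shape == (8, 8)
    assert loaded.labels.tolist() == cohort.labels.tolist()
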