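"""Feature selection and classification of texture feature tables.

The workflow mirrors a small-cohort radiomics study: a class-balanced
holdout split, recursive feature elimination (RFE) down to a top fraction of
features, a linear-kernel SVM (or a 150-tree random forest) trained on the
selected features, 10-fold stratified cross-validation on the training
cohort, and a full metric report (accuracy, precision, recall, F1, AUC-ROC,
confusion matrix, ROC points) on the held-out test cohort with the patient
class as positive.

The statsmodels-style entry point is :class:`TextureRadiomicsModel`:

>>> model = TextureRadiomicsModel(cohort, estimator="svm", seed=0)
>>> res = model.fit()
>>> print(res.summary())

Importance scores
-----------------
RFE with one-feature-per-step elimination yields a full ranking 1..N. The
reported importance score is ``(N - rank + 1) / N`` — 1.0 for the top
feature, decreasing linearly. A threshold ``t`` selects the
``ceil((1 - t) * N)`` best-ranked features (a top-fraction rule): at
N = 150 and t = 0.9 that is 15 features. Every selected feature has score
>= t; when ``(1 - t) * N`` is an integer the next-ranked feature sits
exactly on the score boundary without being selected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CohortTable",
    "SelectionResult",
    "EvalReport",
    "balanced_holdout_split",
    "rfe_select",
    "fit_svm",
    "fit_random_forest",
    "decision_scores",
    "cross_validate",
    "metrics_from_confusion",
    "evaluate",
    "TextureRadiomicsModel",
    "TextureRadiomicsResults",
]


@dataclass
class CohortTable:
    """Subjects x features matrix with labels and an optional split.

    labels: 1 = patient, 0 = healthy control.
    split: per-subject "train"/"test" assignment (same index as features).
    """

    features: pd.DataFrame
    labels: pd.Series
    split: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree on subject count")
        if self.features.index.duplicated().any():
            raise ValueError("duplicated subject ids")
        self.labels = self.labels.astype(int)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortTable":
        """Build from a feature table with subject_id and label columns."""
        if "subject_id" not in df.columns or "label" not in df.columns:
            raise ValueError("feature table needs 'subject_id' and 'label' columns")
        df = df.set_index("subject_id")
        labels = df.pop("label")
        split = df.pop("split") if "split" in df.columns else None
        return cls(features=df.astype(float), labels=labels, split=split)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls.from_frame(pd.read_csv(path))

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def train_test(self) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
        if self.split is None:
            raise ValueError("cohort has no split; call balanced_holdout_split")
        tr = self.split == "train"
        te = self.split == "test"
        return (
            self.features[tr],
            self.labels[tr],
            self.features[te],
            self.labels[te],
        )


def balanced_holdout_split(
    labels: pd.Series | np.ndarray, test_fraction: float = 0.25, seed: int = 0
) -> pd.Series:
    """Class-balanced training cohort, remainder held out for testing.

    The training set takes ``round((1 - test_fraction) * n) // 2`` subjects
    from *each* class (sampled without replacement, seeded); everyone else is
    the test set. With 72 subjects (39 patients / 33 controls) and a 0.25
    test fraction this reproduces train 54 (27 + 27) and test 18 (12 + 6).
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    y = labels.astype(int)
    classes = sorted(y.unique())
    if classes != [0, 1]:
        raise ValueError(f"need both classes 0 and 1 present, got {classes}")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(y)
    n_train = int(round((1.0 - test_fraction) * n))
    per_class = n_train // 2
    counts = y.value_counts()
    for c in (0, 1):
        if counts[c] < per_class:
            raise ValueError(
                f"class {c} has {counts[c]} subjects; {per_class} needed for a "
                f"balanced training cohort"
            )
    rng = np.random.default_rng(seed)
    split = pd.Series("test", index=y.index, name="split")
    for c in (0, 1):
        idx = y.index[y == c].to_numpy()
        chosen = rng.choice(idx, size=per_class, replace=False)
        split.loc[chosen] = "train"
    return split


@dataclass
class SelectionResult:
    """RFE ranking with importance scores and the selected-feature mask."""

    names: list[str]
    rfe_rank: np.ndarray  # 1 = best
    importance_score: np.ndarray  # (N - rank + 1) / N, in (0, 1]
    selected: np.ndarray  # bool
    threshold: float

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def selected_names(self) -> list[str]:
        order = np.argsort(self.rfe_rank)
        return [self.names[i] for i in order if self.selected[i]]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.names,
                "rfe_rank": self.rfe_rank,
                "importance_score": self.importance_score,
                "selected": self.selected,
            }
        ).sort_values("rfe_rank", ignore_index=True)


def _make_estimator(estimator_kind: str, seed: int = 0, n_trees: int = 150):
    if estimator_kind == "svm":
        return SVC(kernel="linear", gamma="auto")
    if estimator_kind == "rf":
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    raise ValueError(f"unknown estimator {estimator_kind!r}; use 'svm' or 'rf'")


def rfe_select(
    X: pd.DataFrame | np.ndarray,
    y,
    estimator_kind: str = "svm",
    threshold: float = 0.9,
    seed: int = 0,
) -> SelectionResult:
    """Rank features by recursive elimination; keep the top (1 - t) fraction.

    One feature is eliminated per step using the estimator's linear
    coefficient magnitudes (SVM) or impurity importances (random forest).
    Ties in sklearn's internal ordering fall back to original column order.
    Constant features are tolerated (they rank last naturally); an
    all-constant matrix is rejected.
    """
    Xdf = pd.DataFrame(X)
    names = [str(c) for c in Xdf.columns]
    Xv = Xdf.to_numpy(dtype=float)
    if Xv.shape[1] < 2:
        raise ValueError("need at least 2 features for RFE")
    if np.all(Xv.std(axis=0) == 0):
        raise ValueError("all features are constant; nothing to rank")
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")

    if estimator_kind == "svm":
        # linear SVM coefficients are scale-sensitive; standardize first
        sd = Xv.std(axis=0)
        sd[sd == 0] = 1.0
        Xfit = (Xv - Xv.mean(axis=0)) / sd
    else:
        Xfit = Xv
    est = _make_estimator(estimator_kind, seed=seed)
    rfe = RFE(est, n_features_to_select=1, step=1)
    rfe.fit(Xfit, np.asarray(y, dtype=int))
    rank = rfe.ranking_.astype(int)

    n = len(names)
    score = (n - rank + 1) / n
    k = math.ceil((1.0 - threshold) * n)
    selected = rank <= k
    return SelectionResult(
        names=names,
        rfe_rank=rank,
        importance_score=score,
        selected=selected,
        threshold=threshold,
    )


def fit_svm(X, y) -> Pipeline:
    """Linear-kernel SVM (gamma='auto') behind a train-fitted standardizer."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix; clean or impute before fitting")
    model = Pipeline(
        [("scale", StandardScaler()), ("svc", SVC(kernel="linear", gamma="auto"))]
    )
    model.fit(X, np.asarray(y, dtype=int))
    return model


def fit_random_forest(X, y, n_trees: int = 150, seed: int = 0) -> RandomForestClassifier:
    """Random forest with 150 trees by default; seeded for reproducibility."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix; clean or impute before fitting")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(X, np.asarray(y, dtype=int))
    return model


def decision_scores(model, X) -> np.ndarray:
    """Continuous scores for ROC: SVM margin or RF patient-class probability."""
    X = np.asarray(X, dtype=float)
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def _model_builder(estimator_kind: str, seed: int, n_trees: int = 150):
    if estimator_kind == "svm":
        return lambda: Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="linear", gamma="auto"))]
        )
    if estimator_kind == "rf":
        return lambda: RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    raise ValueError(f"unknown estimator {estimator_kind!r}")


def cross_validate(
    estimator_kind: str, X, y, k: int = 10, seed: int = 0
) -> dict:
    """Stratified k-fold accuracy on the training cohort (seeded folds)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k > len(y):
        raise ValueError(f"k={k} exceeds the {len(y)} training subjects")
    # stratification needs k <= smallest class; beyond that (e.g. leave-one-
    # out) fall back to plain shuffled folds
    if k <= int(np.bincount(y).min()):
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        from sklearn.model_selection import KFold

        cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    scores = cross_val_score(_model_builder(estimator_kind, seed)(), X, y, cv=cv)
    return {
        "fold_accuracy": scores.tolist(),
        "mean_accuracy": float(scores.mean()),
        "sd_accuracy": float(scores.std(ddof=0)),
        "k": k,
    }


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Accuracy / precision / recall / F1 from a binary confusion matrix.

    Positive class = patient. Undefined ratios (zero denominators) are 0.0.
    """
    total = tp + fn + fp + tn
    if total <= 0:
        raise ValueError("empty confusion matrix")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


@dataclass
class EvalReport:
    """Held-out test metrics plus the confusion matrix and ROC points.

    All ratio metrics are fractions in [0, 1]; ``summary_lines`` formats
    them as percentages.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float
    tp: int
    fn: int
    fp: int
    tn: int
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    n_test: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
            "confusion": {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn},
            "roc_points": [[fpr, tpr] for fpr, tpr in self.roc_points],
            "n_test": self.n_test,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary_lines(self) -> list[str]:
        return [
            f"test accuracy : {100 * self.accuracy:6.2f} %",
            f"precision     : {100 * self.precision:6.2f} %",
            f"recall        : {100 * self.recall:6.2f} %",
            f"f1-score      : {100 * self.f1:6.2f} %",
            f"AUC-ROC       : {self.auc_roc:6.3f}",
            f"confusion     : TP={self.tp} FN={self.fn} FP={self.fp} TN={self.tn}",
        ]

    def __str__(self) -> str:
        return "\n".join(self.summary_lines())


def evaluate(model, X_test, y_test) -> EvalReport:
    """Score a fitted model on held-out subjects (patient = positive class).

    AUC uses the rank statistic over continuous decision scores with the
    midrank convention for ties (all-tied scores give 0.5).
    """
    X = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test, dtype=int)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = np.asarray(model.predict(X), dtype=int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    m = metrics_from_confusion(tp, fn, fp, tn)

    scores = decision_scores(model, X)
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, scores))
        fpr, tpr, _ = roc_curve(y, scores)
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    else:  # degenerate single-class test set: AUC undefined
        auc = float("nan")
        roc_points = []
    return EvalReport(
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        auc_roc=auc,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        roc_points=roc_points,
        n_test=len(y),
    )


class TextureRadiomicsModel:
    """End-to-end classifier over a texture-feature cohort table.

    Orchestrates split -> RFE selection -> cross-validation -> test
    evaluation. Identical seeds give identical splits, rankings, forests and
    reports.

    Parameters
    ----------
    cohort : CohortTable
        Feature matrix + labels; if it carries no split, a class-balanced
        holdout split is drawn at fit time.
    estimator : {"svm", "rf"}
        Linear-kernel SVM (standardized features) or 150-tree random forest
        (raw counts).
    rfe_threshold : float
        Importance-score threshold; keeps the top ``ceil((1 - t) * N)``
        RFE-ranked features.
    folds : int
        Stratified CV folds on the training cohort.
    test_fraction : float
        Holdout fraction when the cohort has no split yet.
    """

    def __init__(
        self,
        cohort: CohortTable,
        estimator: str = "svm",
        rfe_threshold: float = 0.9,
        folds: int = 10,
        test_fraction: float = 0.25,
        n_trees: int = 150,
        seed: int = 0,
    ):
        if estimator not in ("svm", "rf"):
            raise ValueError("estimator must be 'svm' or 'rf'")
        self.cohort = cohort
        self.estimator = estimator
        self.rfe_threshold = rfe_threshold
        self.folds = folds
        self.test_fraction = test_fraction
        self.n_trees = n_trees
        self.seed = seed

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TextureRadiomicsModel":
        return cls(CohortTable.from_csv(path), **kwargs)

    def fit(self) -> "TextureRadiomicsResults":
        cohort = self.cohort
        if cohort.split is None:
            split = balanced_holdout_split(
                cohort.labels, test_fraction=self.test_fraction, seed=self.seed
            )
            cohort = CohortTable(cohort.features, cohort.labels, split)
        X_tr, y_tr, X_te, y_te = cohort.train_test()

        selection = rfe_select(
            X_tr, y_tr, estimator_kind=self.estimator,
            threshold=self.rfe_threshold, seed=self.seed,
        )
        sel_cols = [n for n, s in zip(selection.names, selection.selected) if s]
        Xs_tr = X_tr[sel_cols].to_numpy(dtype=float)
        Xs_te = X_te[sel_cols].to_numpy(dtype=float)

        cv = cross_validate(
            self.estimator, Xs_tr, y_tr, k=min(self.folds, len(y_tr)), seed=self.seed
        )
        if self.estimator == "svm":
            fitted = fit_svm(Xs_tr, y_tr)
        else:
            fitted = fit_random_forest(Xs_tr, y_tr, n_trees=self.n_trees, seed=self.seed)
        train_acc = float((fitted.predict(Xs_tr) == np.asarray(y_tr)).mean())
        report = evaluate(fitted, Xs_te, y_te)
        return TextureRadiomicsResults(
            model=self,
            cohort=cohort,
            selection=selection,
            cv=cv,
            train_accuracy=train_acc,
            report=report,
            fitted_estimator=fitted,
            selected_features=sel_cols,
        )


@dataclass
class TextureRadiomicsResults:
    """Fit artifacts: selection, CV metrics, fitted estimator, test report."""

    model: TextureRadiomicsModel
    cohort: CohortTable
    selection: SelectionResult
    cv: dict
    train_accuracy: float
    report: EvalReport
    fitted_estimator: object
    selected_features: list[str]

    def summary(self) -> str:
        m = self.model
        n_tr = int((self.cohort.split == "train").sum())
        n_te = int((self.cohort.split == "test").sum())
        lines = [
            "Texture radiomics classification",
            "=" * 40,
            f"estimator       : {m.estimator}"
            + (f" ({m.n_trees} trees)" if m.estimator == "rf" else " (linear kernel)"),
            f"subjects        : {len(self.cohort.labels)} "
            f"(train {n_tr} / test {n_te})",
            f"features        : {len(self.selection.names)} -> "
            f"{self.selection.n_selected} selected "
            f"(RFE, score >= {self.selection.threshold})",
            f"train accuracy  : {100 * self.train_accuracy:6.2f} %",
            f"CV accuracy     : {100 * self.cv['mean_accuracy']:6.2f} % "
            f"(+/- {100 * self.cv['sd_accuracy']:.2f}, {self.cv['k']}-fold)",
        ] + self.report.summary_lines()
        top = self.selection.frame().head(5)
        lines.append("top features    : " + ", ".join(
            f"{r.feature} ({r.importance_score:.3f})" for r in top.itertuples()
        ))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimator": self.model.estimator,
            "seed": self.model.seed,
            "n_features": len(self.selection.names),
            "n_selected": self.selection.n_selected,
            "selected_features": self.selected_features,
            "train_accuracy": self.train_accuracy,
            "cv": self.cv,
            "test": self.report.to_dict(),
        }
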