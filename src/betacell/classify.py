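"""Healthy-vs-T2D discrimination under leave-one-out cross-validation.

Five classifier kinds are evaluated: Bayesian network (realized as Gaussian
naive Bayes, the simplest Bayes-net classifier over continuous features),
SVM (RBF kernel), random forest, logistic regression and a one-hidden-layer
neural network. Features are log2 expression of the genes that survived the
expressed-gene filter; T2D is the positive class. Scores are accuracy and
the F-measure (harmonic mean of precision and recall), reported together
with the raw confusion counts.

The feature filter runs once on the full cohort before cross-validation,
replicating the published protocol (the filter sees marginal expression of
all cells, including each held-out cell); ``per_fold_filter`` offers the
leakage-free variant.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_io import CellAnnotation, ExpressionMatrix

POSITIVE_CLASS = "T2D"
CLASSIFIER_KINDS = ("bayes_net", "svm", "random_forest", "logistic", "neural_net")


def make_classifier(kind: str, seed: int = 0):
    """Instantiate one of the five classifier kinds with fixed defaults."""
    if kind == "bayes_net":
        return GaussianNB()
    if kind == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0,
                                                   random_state=seed))
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if kind == "logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=1000, random_state=seed))
    if kind == "neural_net":
        return make_pipeline(StandardScaler(),
                             MLPClassifier(hidden_layer_sizes=(16,),
                                           max_iter=200, random_state=seed))
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass
class FeatureTable:
    """Cells x genes log2 feature matrix with condition labels."""

    X: pd.DataFrame  # cells x genes
    y: pd.Series  # condition per cell
    name: str = "features"

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(self.X) != len(self.y):
            raise ValueError("feature/label length mismatch")
        counts = self.y.value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError("need at least 2 cells in each of the two classes")


def build_feature_table(expr_log2: ExpressionMatrix, ann: CellAnnotation,
                        genes: list[str], name: str = "features") -> FeatureTable:
    """Assemble a feature table; genes absent from the matrix become all-zero
    columns with a warning (transfer gene sets may not fully overlap)."""
    if expr_log2.scale != "log2":
        raise ValueError("feature tables are built on the log2 scale")
    cols = {}
    missing = []
    for g in genes:
        if g in expr_log2.data.index:
            cols[g] = expr_log2.gene(g)
        else:
            cols[g] = pd.Series(0.0, index=expr_log2.data.columns)
            missing.append(g)
    if missing:
        warnings.warn(f"feature table {name!r}: {len(missing)} genes absent, "
                      f"filled with zeros: {missing}", stacklevel=2)
    X = pd.DataFrame(cols)
    y = ann.condition_of(X.index)
    return FeatureTable(X=X, y=pd.Series(np.asarray(y), index=X.index,
                                         name="condition"), name=name)


@dataclass
class EvalMetrics:
    """Confusion counts and derived scores for one classifier run."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    classifier: str = ""
    feature_set: str = ""
    undefined_precision: bool = False

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int,
                           classifier: str = "",
                           feature_set: str = "") -> EvalMetrics:
    """Accuracy = (TP+TN)/(TP+TN+FP+FN); F = 2*precision*recall/(precision+recall)
    with precision = TP/(TP+FP), recall = TP/(TP+FN).

    Undefined precision (TP+FP = 0) or recall yields F-measure 0 with a flag.
    """
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    accuracy = (tp + tn) / total
    undefined = (tp + fp) == 0 or (tp + fn) == 0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    if precision + recall > 0:
        f = 2 * precision * recall / (precision + recall)
    else:
        f = 0.0
        undefined = True
    return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy,
                       precision=precision, recall=recall, f_measure=f,
                       classifier=classifier, feature_set=feature_set,
                       undefined_precision=undefined)


def loocv_evaluate(table: FeatureTable, classifier_kind: str,
                   seed: int = 0) -> EvalMetrics:
    """Leave-one-out cross-validation of one classifier kind.

    Each cell is predicted by a model trained on the remaining n-1 cells;
    confusion counts accumulate over all cells with T2D as the positive
    class. Deterministic given ``seed`` (stochastic learners are seeded).
    """
    clf = make_classifier(classifier_kind, seed=seed)
    X = table.X.to_numpy()
    y = table.y.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pred = cross_val_predict(clf, X, y, cv=LeaveOneOut(), n_jobs=1)
    pos = y == POSITIVE_CLASS
    pred_pos = pred == POSITIVE_CLASS
    tp = int((pos & pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    fp = int((~pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    return metrics_from_confusion(tp, tn, fp, fn, classifier=classifier_kind,
                                  feature_set=table.name)


def evaluate_all(table: FeatureTable, kinds: tuple[str, ...] = CLASSIFIER_KINDS,
                 seed: int = 0) -> pd.DataFrame:
    rows = [loocv_evaluate(table, kind, seed=seed).as_row() for kind in kinds]
    return pd.DataFrame(rows)


def feature_sets(kept_genes: dict[str, list[str]],
                 transfer_cohort: str = "dataset2_like") -> dict[str, dict[str, list[str]]]:
    """Per-cohort named feature sets: each cohort's own filtered genes plus
    the transfer set from ``transfer_cohort`` (collapsed to one set for the
    transfer cohort itself)."""
    if transfer_cohort not in kept_genes:
        raise KeyError(f"transfer cohort {transfer_cohort!r} not in results")
    transfer = list(kept_genes[transfer_cohort])
    out: dict[str, dict[str, list[str]]] = {}
    for cohort, genes in kept_genes.items():
        sets = {"own": list(genes)}
        if cohort != transfer_cohort:
            sets["transfer"] = transfer
        out[cohort] = sets
    return out


def majority_baseline(y: pd.Series) -> float:
    """Accuracy of always predicting the majority class."""
    counts = y.value_counts()
    return float(counts.max() / counts.sum())
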