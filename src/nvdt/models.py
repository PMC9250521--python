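"""Classifier training, prediction and the evaluation-metric suite.

Two classifiers are supported over standardized pair features:

* an RBF-kernel support vector machine whose regularization ``c`` and
  kernel width ``gamma`` are chosen by an internal cross-validated grid
  search (the classic LIBSVM-style grid, c in 2^-5..2^15 and gamma in
  2^-15..2^3 stepping by factors of 4), and
* a random forest with the tree count searched over {50, 100, 150, 200},
  sqrt-of-dimension feature sampling and minimum leaf size 1.

Predictions use a positive-class probability in [0, 1] — Platt-scaled for
the SVM, the tree-vote fraction for the forest — thresholded at 0.5 (ties
go to the positive class).  Metrics are accuracy,
precision, sensitivity, specificity, Matthews correlation coefficient,
F1-score and the trapezoidal area under the ROC curve; zero-denominator
ratios are reported as 0 and flagged.  k-fold results are reported as
mean +/- sample standard deviation across folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from . import datasets, features, pairs
from .seqio import GeneSequence, ProteinPair
from .standardize import Standardizer

DEFAULT_SVM_C = [float(2 ** e) for e in range(-5, 16, 2)]
DEFAULT_SVM_GAMMA = [float(2 ** e) for e in range(-15, 4, 2)]
DEFAULT_RF_NTREE = [50, 100, 150, 200]


@dataclass
class ModelSpec:
    """Classifier kind, hyperparameter grids and decision cutoff."""

    kind: str = "SVM"  # or "RF"
    svm_c: Sequence[float] = field(default_factory=lambda: list(DEFAULT_SVM_C))
    svm_gamma: Sequence[float] = field(default_factory=lambda: list(DEFAULT_SVM_GAMMA))
    rf_n_tree: Sequence[int] = field(default_factory=lambda: list(DEFAULT_RF_NTREE))
    rf_min_leaf: int = 1
    cutoff: float = 0.5
    inner_cv: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("SVM", "RF"):
            raise ValueError(f"kind must be SVM or RF, got {self.kind!r}")
        if not (0 < self.cutoff < 1):
            raise ValueError("cutoff must lie in (0, 1)")
        if self.kind == "SVM" and (not self.svm_c or not self.svm_gamma):
            raise ValueError("SVM grids must be non-empty")
        if self.kind == "RF" and (not self.rf_n_tree or min(self.rf_n_tree) <= 0):
            raise ValueError("rf_n_tree values must be positive")


@dataclass
class TrainedModel:
    spec: ModelSpec
    standardizer: Standardizer
    estimator: object
    best_params: dict
    feature_dim: int


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Acc/Pre/Sen/Spe/MCC/F1 as fractions in [0, 1] (or [-1, 1] for MCC),
    plus trapezoidal ROC AUC; ``undefined`` lists metrics whose denominator
    was zero (reported as 0)."""

    acc: float
    pre: float
    sen: float
    spe: float
    mcc: float
    f1: float
    auc: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self, percent: bool = False) -> dict:
        d = {k: getattr(self, k) for k in ("acc", "pre", "sen", "spe", "mcc", "f1")}
        if percent:
            d = {k: 100.0 * v for k, v in d.items()}
        d["auc"] = self.auc
        return d


def train(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> TrainedModel:
    """Fit the standardizer and a grid-searched classifier on training rows.

    Hyperparameters are chosen by stratified ``spec.inner_cv``-fold
    cross-validated accuracy; the whole procedure is deterministic given
    ``spec.seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    if min(np.bincount(y)) < 2:
        raise ValueError("training data needs >= 2 examples per class")
    std = Standardizer().fit(X)
    Xs = std.transform(X)
    cv = StratifiedKFold(n_splits=spec.inner_cv, shuffle=True,
                         random_state=spec.seed)
    if spec.kind == "SVM":
        grid = {"C": list(spec.svm_c), "gamma": list(spec.svm_gamma)}
        base = SVC(kernel="rbf")
    else:
        grid = {"n_estimators": list(spec.rf_n_tree)}
        base = RandomForestClassifier(
            max_features="sqrt", min_samples_leaf=spec.rf_min_leaf,
            random_state=spec.seed,
        )
    search = GridSearchCV(base, grid, scoring="accuracy", cv=cv, n_jobs=1)
    search.fit(Xs, y)
    if spec.kind == "SVM":
        estimator, best_params = _fit_calibrated_svm(search, Xs, y, spec, cv)
    else:
        estimator, best_params = search.best_estimator_, dict(search.best_params_)
    return TrainedModel(spec=spec, standardizer=std,
                        estimator=estimator,
                        best_params=best_params,
                        feature_dim=X.shape[1])


def _fit_calibrated_svm(search: GridSearchCV, Xs: np.ndarray, y: np.ndarray,
                        spec: ModelSpec, cv: StratifiedKFold):
    """Refit the grid winner with Platt-calibrated probabilities.

    Deployed predictions threshold the calibrated score at the cutoff, so
    the selected (c, gamma) must survive calibration: extreme corners of
    the grid can classify by raw margin sign while their margins are so
    tiny that the fitted sigmoid degenerates to a constant.  Tied grid
    winners are therefore tried in rank order and the first whose
    calibrated training accuracy backs up its cross-validated score is
    kept; if none does, the raw winner is used as-is.
    """
    res = search.cv_results_
    order = np.lexsort((np.arange(len(res["mean_test_score"])),
                        -res["mean_test_score"]))
    first = None
    for idx in order[:10]:
        params = res["params"][idx]
        est = CalibratedClassifierCV(SVC(kernel="rbf", **params),
                                     method="sigmoid", ensemble=False,
                                     cv=cv).fit(Xs, y)
        if first is None:
            first = (est, dict(params))
        prob_acc = ((est.predict_proba(Xs)[:, 1] >= spec.cutoff) == y).mean()
        if prob_acc >= search.best_score_ - 0.05:
            return est, dict(params)
    return first


def _scores(model: TrainedModel, Xs: np.ndarray) -> np.ndarray:
    return model.estimator.predict_proba(Xs)[:, 1]


def predict(model: TrainedModel, X: np.ndarray,
            cutoff: Optional[float] = None) -> tuple[np.ndarray, np.ndarray]:
    """Labels and [0, 1] scores for new pair features (score >= cutoff -> 1)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.feature_dim:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.feature_dim}"
        )
    if cutoff is None:
        cutoff = model.spec.cutoff
    scores = _scores(model, model.standardizer.transform(X))
    labels = (scores >= cutoff).astype(np.int64)
    return labels, scores


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def auc_trapezoid(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve by the trapezoidal rule."""
    fpr, tpr, _ = roc_curve(np.asarray(y_true), np.asarray(scores))
    return float(np.trapezoid(tpr, fpr))


def metrics(cm: ConfusionCounts, scores: Optional[Sequence[float]] = None,
            y_true: Optional[Sequence[int]] = None) -> MetricsReport:
    """The full metric suite from confusion counts (AUC needs scores)."""
    und: list[str] = []
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    acc = _ratio(tp + tn, cm.total, "acc", und)
    pre = _ratio(tp, tp + fp, "pre", und)
    sen = _ratio(tp, tp + fn, "sen", und)
    spe = _ratio(tn, tn + fp, "spe", und)
    mcc_den = np.sqrt(float(tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", und)
    f1 = _ratio(2 * pre * sen, pre + sen, "f1", und)
    if scores is not None and y_true is not None:
        y_true = np.asarray(y_true)
        if len(y_true) != cm.total:
            raise ValueError("score count does not match confusion totals")
        if np.unique(y_true).size < 2:
            und.append("auc")
            auc = 0.0
        else:
            auc = auc_trapezoid(y_true, scores)
    else:
        und.append("auc")
        auc = 0.0
    return MetricsReport(acc=acc, pre=pre, sen=sen, spe=spe, mcc=float(mcc),
                         f1=f1, auc=auc, undefined=und)


def evaluate(model: TrainedModel, X: np.ndarray, y: Sequence[int]) -> MetricsReport:
    labels, scores = predict(model, X)
    return metrics(confusion(y, labels), scores=scores, y_true=y)


@dataclass
class CVResult:
    """Per-fold metric reports with mean +/- sample-std summaries."""

    folds: list[MetricsReport]
    mean: dict[str, float]
    std: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.folds]
        df = pd.DataFrame(rows, index=[f"fold{i+1}" for i in range(len(rows))])
        df.loc["mean"] = pd.Series(self.mean)
        df.loc["std"] = pd.Series(self.std)
        return df

    def summary(self) -> str:
        keys = ("acc", "pre", "sen", "spe", "mcc", "f1")
        parts = [f"{k}={100*self.mean[k]:.2f}±{100*self.std[k]:.2f}%" for k in keys]
        parts.append(f"auc={self.mean['auc']:.4f}±{self.std['auc']:.4f}")
        return " ".join(parts)


def cross_validate(sequences: Sequence[GeneSequence], pair_list: list[ProteinPair],
                   spec: ModelSpec, k: int = 5, seed: int = 0,
                   variant: str = "NVDT", scheme: str = "Cod5",
                   augment_orders: bool = False) -> CVResult:
    """k-fold cross-validation of the full pipeline.

    Per fold, the standardizer and classifier are fitted on the k-1
    training folds only (features per sequence involve no fitting, so they
    are computed once).  Fold assignment is stratified and seeded.
    """
    feats = features.feature_matrix(sequences, variant=variant)
    folds = datasets.kfold(pair_list, k=k, seed=seed, stratified=True)
    reports: list[MetricsReport] = []
    for i in range(k):
        test_pairs = folds[i]
        train_pairs = [p for j in range(k) if j != i for p in folds[j]]
        Xtr, ytr = pairs.split_xy(pairs.pair_feature_matrix(
            train_pairs, feats, scheme=scheme, augment_orders=augment_orders))
        Xte, yte = pairs.split_xy(pairs.pair_feature_matrix(
            test_pairs, feats, scheme=scheme))
        model = train(Xtr, ytr, spec)
        reports.append(evaluate(model, Xte, yte))
    keys = ("acc", "pre", "sen", "spe", "mcc", "f1", "auc")
    arr = {k_: np.array([getattr(r, k_) for r in reports]) for k_ in keys}
    mean = {k_: float(v.mean()) for k_, v in arr.items()}
    std = {k_: float(v.std(ddof=1)) for k_, v in arr.items()}
    return CVResult(folds=reports, mean=mean, std=std)


# -- persistence --------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise spec + standardizer + fitted classifier to one archive."""
    payload = {
        "spec": asdict(model.spec),
        "standardizer": model.standardizer.to_dict(),
        "estimator": model.estimator,
        "best_params": model.best_params,
        "feature_dim": model.feature_dim,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(
        spec=ModelSpec(**payload["spec"]),
        standardizer=Standardizer.from_dict(payload["standardizer"]),
        estimator=payload["estimator"],
        best_params=payload["best_params"],
        feature_dim=payload["feature_dim"],
    )
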