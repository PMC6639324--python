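"""Classifier training, cross-validated evaluation, ROC/AUC and significance.

Two classifier families are supported, mirroring the analysis design:

* SVM — maximum-margin separator (linear kernel by default; polynomial and
  RBF available) on z-scored features, C = 1 by default;
* TREE — the C4.5/C5.0-family gain-ratio tree with pessimistic pruning.

Evaluation protocols: leave-one-out CV, stratified 10-fold CV, and
resubstitution.  Out-of-fold real-valued scores (oriented so larger = more
PD-like; PD is the positive class) are pooled into one ROC curve; AUC,
Youden-point operating metrics, and a one-sided exact binomial test of pooled
accuracy against the no-information rate are reported.

Feature selection can run POOLED (once on all data before CV — the apparent
protocol of analyses that report near-perfect cross-validated AUCs; the report
carries an explicit caveat) or NESTED (re-run inside every training fold, the
statistically sound default for honest estimates).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ClassLabel, FeatureTable
from .mrmr import mrmr_rank_matrix
from .tree import GainRatioTreeClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "Protocol",
    "SelectionMode",
    "ClassifierSpec",
    "RadiomicsClassifier",
    "CVReport",
    "train_classifier",
    "run_cv",
    "roc_auc",
    "operating_metrics",
    "binomial_test",
    "predict_new",
    "save_model_bundle",
    "load_model_bundle",
]

POOLED_CAVEAT = (
    "selection performed outside CV: feature selection saw the full cohort, "
    "so cross-validated metrics are optimistically biased"
)


class Protocol(str, enum.Enum):
    LOOCV = "loocv"
    KFOLD10 = "kfold10"
    RESUBSTITUTION = "resubstitution"


class SelectionMode(str, enum.Enum):
    POOLED = "pooled"
    NESTED = "nested"


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative classifier settings; ``build`` yields a fresh estimator."""

    family: str = "svm"  # "svm" | "tree"
    kernel: str = "linear"  # SVM only
    C: float = 1.0
    tree_cf: float = 0.25
    standardize: bool = True

    def build(self) -> "RadiomicsClassifier":
        return RadiomicsClassifier(
            family=self.family,
            kernel=self.kernel,
            C=self.C,
            tree_cf=self.tree_cf,
            standardize=self.standardize,
        )


class RadiomicsClassifier(ClassifierMixin, BaseEstimator):
    """SVM- or tree-backed binary classifier with frozen preprocessing.

    Features are z-scored with training-set statistics when ``standardize``;
    zero-variance columns are dropped with a warning.  ``decision_scores``
    returns a real-valued score oriented toward ``classes_[1]`` (PD when labels
    are 0/1 with PD = 1); ``predict_proba`` maps SVM decision values through a
    logistic link fitted on the training scores, and uses leaf class
    frequencies for the tree.
    """

    def __init__(
        self,
        family: str = "svm",
        kernel: str = "linear",
        C: float = 1.0,
        tree_cf: float = 0.25,
        standardize: bool = True,
    ):
        self.family = family
        self.kernel = kernel
        self.C = C
        self.tree_cf = tree_cf
        self.standardize = standardize

    def fit(self, X, y):
        X = validate_data(self, X, ensure_2d=True, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = unique_labels(y)
        if self.classes_.size != 2:
            raise ValueError("binary classification requires exactly 2 classes in y")
        self.keep_ = np.ones(X.shape[1], dtype=bool)
        if self.standardize:
            variances = X.var(axis=0)
            self.keep_ = variances > 0
            dropped = int((~self.keep_).sum())
            if dropped:
                logger.warning("dropping %d zero-variance feature(s) before scaling", dropped)
            if not self.keep_.any():
                raise ValueError("all features have zero variance")
            self.scaler_ = StandardScaler().fit(X[:, self.keep_])
            Xt = self.scaler_.transform(X[:, self.keep_])
        else:
            self.scaler_ = None
            Xt = X[:, self.keep_]
        if self.family == "svm":
            self.base_ = SVC(kernel=self.kernel, C=self.C)
        elif self.family == "tree":
            self.base_ = GainRatioTreeClassifier(cf=self.tree_cf)
        else:
            raise ValueError(f"unknown classifier family {self.family!r}")
        self.base_.fit(Xt, y)
        if self.family == "svm":
            scores = self.base_.decision_function(Xt).reshape(-1, 1)
            if np.ptp(scores) > 0:
                self.calibrator_ = LogisticRegression().fit(scores, y)
            else:
                self.calibrator_ = None
        return self

    def _transform(self, X):
        X = validate_data(self, X, ensure_2d=True, dtype=np.float64, reset=False)
        Xt = X[:, self.keep_]
        return self.scaler_.transform(Xt) if self.scaler_ is not None else Xt

    def decision_scores(self, X) -> np.ndarray:
        """Real-valued score per subject; larger = more like ``classes_[1]``."""
        check_is_fitted(self)
        Xt = self._transform(X)
        if self.family == "svm":
            return np.asarray(self.base_.decision_function(Xt), dtype=np.float64)
        return np.asarray(self.base_.predict_proba(Xt)[:, 1], dtype=np.float64)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self)
        if self.family == "svm":
            scores = self.decision_scores(X).reshape(-1, 1)
            if self.calibrator_ is None:
                p1 = np.full(scores.shape[0], 0.5)
            else:
                p1 = self.calibrator_.predict_proba(scores)[:, 1]
            return np.column_stack([1 - p1, p1])
        return self.base_.predict_proba(self._transform(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        return self.base_.predict(self._transform(X))


def train_classifier(spec: ClassifierSpec, table: FeatureTable, labels=None) -> RadiomicsClassifier:
    """Fit a classifier on a FeatureTable (labels default to the table's own)."""
    y = table.label_array() if labels is None else np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training requires both classes present")
    return spec.build().fit(table.values, y)


# ---------------------------------------------------------------------------
# Metrics


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """AUC plus ROC curve points (fpr, tpr, thresholds); ties count 1/2.

    Equals the normalized Mann-Whitney concordant-pair statistic.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if np.unique(y).size != 2:
        raise ValueError("ROC requires both classes present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresholds = roc_curve(y, s)
    return auc, fpr, tpr, thresholds


@dataclass(frozen=True)
class OperatingMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int


def _safe_ratio(num: float, den: float) -> float:
    return float(num / den) if den > 0 else 0.0


def operating_metrics(scores, labels, threshold_rule: str = "youden") -> OperatingMetrics:
    """Confusion-matrix metrics at an operating point on the pooled ROC.

    ``youden`` (default) maximizes sensitivity + specificity - 1; a float
    threshold may be passed instead.  Positive class is label 1 (PD).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if threshold_rule == "youden":
        _, fpr, tpr, thresholds = roc_auc(s, y)
        k = int(np.argmax(tpr - fpr))
        threshold = float(thresholds[k])
    else:
        threshold = float(threshold_rule)
    pred = (s >= threshold).astype(int)
    if pred.min() == pred.max():
        logger.warning("degenerate operating threshold: all subjects predicted %d", pred[0])
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    return OperatingMetrics(
        accuracy=_safe_ratio(tp + tn, y.size),
        sensitivity=_safe_ratio(tp, tp + fn),
        specificity=_safe_ratio(tn, tn + fp),
        ppv=_safe_ratio(tp, tp + fp),
        npv=_safe_ratio(tn, tn + fn),
        threshold=threshold,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def binomial_test(correct: int, n: int, p0: float) -> float:
    """Exact one-sided upper-tail P(X >= correct) for X ~ Binomial(n, p0)."""
    if not 0 <= correct <= n:
        raise ValueError(f"correct must be in [0, {n}], got {correct}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    return float(stats.binom.sf(correct - 1, n, p0))


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVReport:
    protocol: Protocol
    selection_mode: SelectionMode
    seed: int
    subject_ids: list[str]
    labels: np.ndarray  # 0/1, PD = 1
    scores: np.ndarray  # pooled out-of-fold scores
    predicted: np.ndarray  # 0/1 at the operating threshold
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    binomial_p: float
    no_information_rate: float
    fpr: np.ndarray
    tpr: np.ndarray
    selected_features: list[str] | None = None
    caveat: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"] = self.protocol.value
        d["selection_mode"] = self.selection_mode.value
        for key in ("labels", "scores", "predicted", "fpr", "tpr"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _folds(protocol: Protocol, y: np.ndarray, seed: int, nested: bool):
    n = y.size
    if protocol is Protocol.RESUBSTITUTION:
        idx = np.arange(n)
        return [(idx, idx)]
    if protocol is Protocol.LOOCV:
        return list(LeaveOneOut().split(np.zeros((n, 1)), y))
    if protocol is Protocol.KFOLD10:
        if n < 10:
            raise ValueError(f"10-fold CV needs at least 10 subjects, got {n}")
        for attempt in range(10):
            cv = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed + attempt)
            folds = list(cv.split(np.zeros((n, 1)), y))
            if all(np.unique(y[tr]).size == 2 for tr, _ in folds):
                return folds
            if not nested:
                return folds
        raise ValueError("could not draw stratified folds with both classes in training")
    raise ValueError(f"unknown protocol {protocol}")


def run_cv(
    spec: ClassifierSpec,
    table: FeatureTable,
    labels=None,
    protocol: Protocol | str = Protocol.LOOCV,
    selector: tuple[str, int] | None = None,
    selection_mode: SelectionMode | str = SelectionMode.POOLED,
    seed: int = 0,
) -> CVReport:
    """Cross-validated evaluation with pooled out-of-fold ROC.

    ``selector`` is ``("mrmr", k)`` to rank features and keep the top k; in
    POOLED mode the ranking is computed once on the full cohort (biased, kept
    for fidelity to common practice and flagged in the report), in NESTED mode
    it is recomputed inside every training fold.
    """
    protocol = Protocol(protocol)
    selection_mode = SelectionMode(selection_mode)
    y = table.label_array() if labels is None else np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("cross-validation requires both classes present")
    if selector is not None:
        method, k = selector
        if method != "mrmr":
            raise ValueError(f"unknown selector {method!r}")
        if not 1 <= k <= table.n_features:
            raise ValueError(f"selector k must be in [1, {table.n_features}]")

    X_full = table.values
    selected_names: list[str] | None = None
    if selector is not None and selection_mode is SelectionMode.POOLED:
        order, _, _ = mrmr_rank_matrix(X_full, y, selector[1])
        selected_names = [table.feature_names[j] for j in order]
        X_full = X_full[:, order]

    folds = _folds(protocol, y, seed, nested=selection_mode is SelectionMode.NESTED)
    scores = np.empty(y.size, dtype=np.float64)
    for train, test in folds:
        X_tr, X_te = X_full[train], X_full[test]
        if selector is not None and selection_mode is SelectionMode.NESTED:
            order, _, _ = mrmr_rank_matrix(X_tr, y[train], selector[1])
            X_tr, X_te = X_tr[:, order], X_te[:, order]
        model = spec.build().fit(X_tr, y[train])
        scores[test] = model.decision_scores(X_te)

    auc, fpr, tpr, _ = roc_auc(scores, y)
    om = operating_metrics(scores, y, "youden")
    nir = max(np.mean(y), 1 - np.mean(y))
    correct = om.tp + om.tn
    p = binomial_test(correct, y.size, float(nir))
    caveat = POOLED_CAVEAT if (selector and selection_mode is SelectionMode.POOLED) else None
    return CVReport(
        protocol=protocol,
        selection_mode=selection_mode,
        seed=seed,
        subject_ids=list(table.subject_ids),
        labels=y,
        scores=scores,
        predicted=(scores >= om.threshold).astype(int),
        auc=auc,
        accuracy=om.accuracy,
        sensitivity=om.sensitivity,
        specificity=om.specificity,
        ppv=om.ppv,
        npv=om.npv,
        threshold=om.threshold,
        binomial_p=p,
        no_information_rate=float(nir),
        fpr=fpr,
        tpr=tpr,
        selected_features=selected_names,
        caveat=caveat,
    )


# ---------------------------------------------------------------------------
# Prediction on new subjects


def predict_new(
    model: RadiomicsClassifier,
    feature_names: list[str],
    new_table: FeatureTable,
):
    """Classify new subjects with frozen training-time preprocessing.

    ``feature_names`` is the model's training column list (post-selection);
    the new table must contain exactly those columns (any order).  Returns
    (predicted labels as ClassLabel, probability-like score in [0, 1] for PD).
    """
    have = set(new_table.feature_names)
    want = set(feature_names)
    if have != want:
        missing = sorted(want - have)[:5]
        extra = sorted(have - want)[:5]
        raise ValueError(
            f"feature mismatch: missing {missing or 'none'}, unexpected {extra or 'none'}"
        )
    sub = new_table.select(feature_names)
    proba = model.predict_proba(sub.values)[:, 1]
    pred = model.predict(sub.values)
    labels = [ClassLabel.PD if p == 1 else ClassLabel.PSP for p in pred]
    return labels, proba


def save_model_bundle(
    model: RadiomicsClassifier,
    feature_names: list[str],
    out_dir: str | Path,
    spec: ClassifierSpec | None = None,
) -> None:
    """Persist a trained model as a directory: config + parameters + features."""
    import joblib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "selected_features.txt").write_text("\n".join(feature_names) + "\n")
    meta = {"spec": dataclasses.asdict(spec) if spec else None, "n_features": len(feature_names)}
    (out / "config.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(model, out / "model.joblib")


def load_model_bundle(in_dir: str | Path) -> tuple[RadiomicsClassifier, list[str]]:
    import joblib

    path = Path(in_dir)
    names = [l for l in (path / "selected_features.txt").read_text().splitlines() if l]
    model = joblib.load(path / "model.joblib")
    return model, names
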