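"""OVO RBF-SVM fold classifier: scaling, grid-tuned training, evaluation.

Hyper-parameters C and gamma are tuned over integer powers of two by
stratified k-fold cross-validation; information-gain selection and min-max
scaling are re-fit inside each training fold so the reported CV accuracy is
leak-free.  The quadratic-program solving is delegated to libsvm via
scikit-learn; this module owns the multiclass vote, the tuning protocol and
the metric formulas.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import __version__
from .dataset import LabeledDataset
from .selection import rank_and_select

logger = logging.getLogger(__name__)

DEFAULT_EXPONENTS = range(-14, 15)


# ---------------------------------------------------------------------------
# scaling

@dataclass
class ScalerParams:
    """Per-feature affine map to [-1, 1] from training min/max."""

    vmin: np.ndarray
    vmax: np.ndarray


def fit_scaler(train_matrix: np.ndarray) -> ScalerParams:
    m = np.asarray(train_matrix, dtype=float)
    if m.size == 0:
        raise ValueError("cannot fit scaler on an empty matrix")
    return ScalerParams(vmin=m.min(axis=0), vmax=m.max(axis=0))


def apply_scaler(params: ScalerParams, matrix: np.ndarray) -> np.ndarray:
    """Map each feature by its stored training range; constant features -> 0."""
    m = np.asarray(matrix, dtype=float)
    span = params.vmax - params.vmin
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = -1.0 + 2.0 * (m - params.vmin) / span
    return np.where(span == 0, 0.0, scaled)


# ---------------------------------------------------------------------------
# selection config used inside cross-validation

@dataclass(frozen=True)
class SelectionConfig:
    """IG selection settings applied within each training fold."""

    n_bins: int = 10
    band_fraction: float = 0.5


# ---------------------------------------------------------------------------
# model

@dataclass
class FoldModel:
    """Trained fold classifier: selected features, scaler, tuned SVM."""

    feature_ids: list[str]
    scaler: ScalerParams
    c: float
    gamma: float
    class_labels: list[str]
    svm: SVC
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if not self.feature_ids:
            raise ValueError("selected feature set must be non-empty")


def _train_svc(x: np.ndarray, y: np.ndarray, c: float, gamma: float) -> SVC:
    svc = SVC(C=c, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
    svc.fit(x, y)
    return svc


def _ovo_predict(svm: SVC, x: np.ndarray, class_labels: list[str]) -> list[str]:
    """Majority vote over the K(K-1)/2 pairwise machines.

    Vote ties are broken by the largest summed pairwise decision margin
    among the tied classes, then by class-label order.  For K=2 this reduces
    to the sign of the single binary decision value.
    """
    classes = list(svm.classes_)
    k = len(classes)
    dec = np.atleast_2d(svm.decision_function(x))
    if k == 2:
        # sklearn's binary decision value is positive for classes_[1]
        idx = np.where(dec.reshape(-1) > 0, 1, 0)
        return [classes[i] for i in idx]
    votes = np.zeros((x.shape[0], k))
    margins = np.zeros((x.shape[0], k))
    for col, (i, j) in enumerate(itertools.combinations(range(k), 2)):
        d = dec[:, col]  # positive favors classes_[i]
        votes[:, i] += d > 0
        votes[:, j] += d <= 0
        margins[:, i] += d
        margins[:, j] -= d
    out = []
    for row in range(x.shape[0]):
        best = np.flatnonzero(votes[row] == votes[row].max())
        if len(best) > 1:
            tied_margins = margins[row, best]
            best = best[tied_margins == tied_margins.max()]
        out.append(classes[best[0]])
    return out


def predict(model: FoldModel, features) -> list[str]:
    """Predict fold labels for a FeatureVector, a LabeledDataset, or a
    (matrix, feature_ids) pair carrying the model's selected features."""
    from .features import FeatureVector  # local import avoids cycle

    if isinstance(features, FeatureVector):
        matrix = features.values[None, :]
        ids = features.feature_ids
    elif isinstance(features, LabeledDataset):
        matrix = features.matrix
        ids = features.feature_ids
    else:
        matrix, ids = features
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))

    pos = {fid: i for i, fid in enumerate(ids)}
    missing = [f for f in model.feature_ids if f not in pos]
    if missing:
        raise ValueError(
            f"input is missing {len(missing)} selected features, "
            f"e.g. {missing[:5]}"
        )
    cols = [pos[f] for f in model.feature_ids]
    x = apply_scaler(model.scaler, matrix[:, cols])
    return _ovo_predict(model.svm, x, model.class_labels)


# ---------------------------------------------------------------------------
# grid-searched training

def _resolve_folds(labels: np.ndarray, folds: int) -> int:
    _, counts = np.unique(labels, return_counts=True)
    smallest = int(counts.min())
    if smallest < folds:
        actual = max(2, smallest)
        logger.warning(
            "reducing folds from %d to %d: smallest class has %d members",
            folds, actual, smallest,
        )
        return actual
    return folds


def grid_search_train(
    data: LabeledDataset,
    c_exponents=DEFAULT_EXPONENTS,
    gamma_exponents=DEFAULT_EXPONENTS,
    folds: int = 10,
    seed: int = 0,
    selection: SelectionConfig | None = SelectionConfig(),
) -> tuple[FoldModel, pd.DataFrame]:
    """Tune (C, gamma) = (2^a, 2^b) by stratified k-fold CV and refit.

    Selection (if enabled) and scaling are re-fit on each training fold.
    The pair with the highest mean CV accuracy wins; ties go to smaller C,
    then smaller gamma.  Returns the refit model and the full CV table.
    """
    c_exponents = list(c_exponents)
    gamma_exponents = list(gamma_exponents)
    if not c_exponents or not gamma_exponents:
        raise ValueError("hyper-parameter grid must be non-empty")
    labels = np.asarray(data.labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes to train")

    folds = _resolve_folds(labels, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    # Selection and scaling do not depend on (C, gamma): prepare folds once.
    prepared = []
    for train_idx, test_idx in skf.split(data.matrix, labels):
        train = data.subset_rows(train_idx)
        if selection is not None:
            ranking = rank_and_select(
                train, n_bins=selection.n_bins,
                band_fraction=selection.band_fraction,
            )
            cols = ranking.selected_mask
        else:
            cols = np.ones(data.n_features, dtype=bool)
        x_train = data.matrix[np.ix_(train_idx, np.flatnonzero(cols))]
        x_test = data.matrix[np.ix_(test_idx, np.flatnonzero(cols))]
        params = fit_scaler(x_train)
        prepared.append(
            (
                apply_scaler(params, x_train),
                labels[train_idx],
                apply_scaler(params, x_test),
                labels[test_idx],
            )
        )

    rows = []
    for a in sorted(c_exponents):
        for b in sorted(gamma_exponents):
            c, gamma = 2.0 ** a, 2.0 ** b
            accs = []
            for x_tr, y_tr, x_te, y_te in prepared:
                svc = _train_svc(x_tr, y_tr, c, gamma)
                pred = _ovo_predict(svc, x_te, sorted(set(y_tr)))
                accs.append(float(np.mean(np.asarray(pred) == y_te)))
            rows.append(
                {
                    "c_exponent": a,
                    "gamma_exponent": b,
                    "C": c,
                    "gamma": gamma,
                    "mean_cv_accuracy": float(np.mean(accs)),
                }
            )
    table = pd.DataFrame(rows)
    # highest accuracy; ties -> smaller C then smaller gamma (rows are
    # already sorted by (C, gamma) ascending)
    best = rows[int(np.argmax([r["mean_cv_accuracy"] for r in rows]))]

    # Final refit on all data with the winning pair.
    if selection is not None:
        ranking = rank_and_select(
            data, n_bins=selection.n_bins, band_fraction=selection.band_fraction
        )
        mask = ranking.selected_mask
    else:
        mask = np.ones(data.n_features, dtype=bool)
    selected_ids = [f for f, m in zip(data.feature_ids, mask) if m]
    x_all = data.matrix[:, mask]
    params = fit_scaler(x_all)
    svc = _train_svc(apply_scaler(params, x_all), labels, best["C"], best["gamma"])
    model = FoldModel(
        feature_ids=selected_ids,
        scaler=params,
        c=best["C"],
        gamma=best["gamma"],
        class_labels=data.class_labels(),
        svm=svc,
        metadata={
            "seed": seed,
            "folds": folds,
            "c_exponents": [int(a) for a in sorted(c_exponents)],
            "gamma_exponents": [int(b) for b in sorted(gamma_exponents)],
            "selection": None
            if selection is None
            else {"n_bins": selection.n_bins,
                  "band_fraction": selection.band_fraction},
            "best_mean_cv_accuracy": best["mean_cv_accuracy"],
        },
    )
    return model, table


def cross_validated_report(
    data: LabeledDataset,
    c: float,
    gamma: float,
    folds: int = 10,
    seed: int = 0,
    selection: SelectionConfig | None = SelectionConfig(),
) -> "EvaluationReport":
    """Out-of-fold predictions at fixed (C, gamma), aggregated into a report."""
    labels = np.asarray(data.labels)
    folds = _resolve_folds(labels, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    true_all: list[str] = []
    pred_all: list[str] = []
    for train_idx, test_idx in skf.split(data.matrix, labels):
        train = data.subset_rows(train_idx)
        if selection is not None:
            ranking = rank_and_select(
                train, n_bins=selection.n_bins,
                band_fraction=selection.band_fraction,
            )
            mask = ranking.selected_mask
        else:
            mask = np.ones(data.n_features, dtype=bool)
        x_tr = data.matrix[np.ix_(train_idx, np.flatnonzero(mask))]
        x_te = data.matrix[np.ix_(test_idx, np.flatnonzero(mask))]
        params = fit_scaler(x_tr)
        svc = _train_svc(apply_scaler(params, x_tr), labels[train_idx], c, gamma)
        pred = _ovo_predict(svc, apply_scaler(params, x_te), sorted(set(labels)))
        true_all.extend(labels[test_idx])
        pred_all.extend(pred)
    return evaluate(true_all, pred_all, data.class_labels())


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationReport:
    """K x K confusion matrix with per-class and macro-averaged metrics.

    Metrics are stored as fractions in [0, 1]; multiply by 100 at the
    presentation layer if percentages are wanted.
    """

    class_labels: list[str]
    confusion_matrix: np.ndarray  # rows = true, columns = predicted
    sensitivity: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    accuracy: float
    undefined_sensitivity: np.ndarray  # classes absent from the truth

    @property
    def macro_sensitivity(self) -> float:
        return float(self.sensitivity.mean())

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_dict(self) -> dict:
        return {
            "class_labels": self.class_labels,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_class": {
                lab: {
                    "sensitivity": float(self.sensitivity[i]),
                    "precision": float(self.precision[i]),
                    "f1": float(self.f1[i]),
                    "sensitivity_undefined": bool(self.undefined_sensitivity[i]),
                }
                for i, lab in enumerate(self.class_labels)
            },
            "macro": {
                "sensitivity": self.macro_sensitivity,
                "precision": self.macro_precision,
                "f1": self.macro_f1,
            },
            "accuracy": self.accuracy,
        }

    def per_class_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_labels,
                "sensitivity": self.sensitivity,
                "precision": self.precision,
                "f1": self.f1,
            }
        )

    def confusion_text(self) -> str:
        width = max(6, max(len(c) for c in self.class_labels) + 1)
        lines = [
            "".join(f"{c:>{width}}" for c in [""] + self.class_labels)
        ]
        for i, lab in enumerate(self.class_labels):
            cells = "".join(
                f"{int(v):>{width}}" for v in self.confusion_matrix[i]
            )
            lines.append(f"{lab:>{width}}" + cells)
        return "\n".join(lines)


def evaluate(true_labels, predicted_labels, class_labels) -> EvaluationReport:
    """Per-class sensitivity TP/(TP+FN), precision TP/(TP+FP) and
    F1 = 2TP/(2TP+FP+FN) from the confusion matrix, plus overall accuracy.

    A class with no true members has undefined sensitivity; it is reported
    as 0 and flagged.  F1 is 0 whenever TP is 0.
    """
    true_arr = list(true_labels)
    pred_arr = list(predicted_labels)
    if len(true_arr) != len(pred_arr):
        raise ValueError("true and predicted label sequences differ in length")
    class_labels = list(class_labels)
    index = {lab: i for i, lab in enumerate(class_labels)}
    for lab in itertools.chain(true_arr, pred_arr):
        if lab not in index:
            raise ValueError(f"label {lab!r} not in class_labels")

    k = len(class_labels)
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(true_arr, pred_arr):
        cm[index[t], index[p]] += 1

    tp = np.diagonal(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp

    with np.errstate(divide="ignore", invalid="ignore"):
        sensitivity = np.where(tp + fn > 0, tp / np.where(tp + fn > 0, tp + fn, 1), 0.0)
        precision = np.where(tp + fp > 0, tp / np.where(tp + fp > 0, tp + fp, 1), 0.0)
        f1_den = 2 * tp + fp + fn
        f1 = np.where(f1_den > 0, 2 * tp / np.where(f1_den > 0, f1_den, 1), 0.0)

    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0
    return EvaluationReport(
        class_labels=class_labels,
        confusion_matrix=cm,
        sensitivity=sensitivity,
        precision=precision,
        f1=f1,
        accuracy=accuracy,
        undefined_sensitivity=(tp + fn) == 0,
    )


# ---------------------------------------------------------------------------
# persistence

_MACHINERY_FILE = "machinery.joblib"
_MANIFEST_FILE = "manifest.json"


def save_model(model: FoldModel, directory) -> Path:
    """Write a portable model archive: JSON manifest + serialized machinery.

    The manifest records everything needed to reproduce or audit the model
    and the SHA-256 of the machinery blob, which ``load_model`` verifies.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    blob_path = directory / _MACHINERY_FILE
    joblib.dump(model.svm, blob_path)
    digest = hashlib.sha256(blob_path.read_bytes()).hexdigest()
    manifest = {
        "format_version": 1,
        "package_version": __version__,
        "feature_ids": model.feature_ids,
        "scaler": {
            "vmin": model.scaler.vmin.tolist(),
            "vmax": model.scaler.vmax.tolist(),
        },
        "C": model.c,
        "gamma": model.gamma,
        "class_labels": model.class_labels,
        "metadata": model.metadata,
        "machinery_sha256": digest,
    }
    (directory / _MANIFEST_FILE).write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return directory


def load_model(directory) -> FoldModel:
    directory = Path(directory)
    manifest = json.loads((directory / _MANIFEST_FILE).read_text())
    blob_path = directory / _MACHINERY_FILE
    digest = hashlib.sha256(blob_path.read_bytes()).hexdigest()
    if digest != manifest["machinery_sha256"]:
        raise ValueError(
            f"model archive corrupted: machinery hash mismatch in {directory}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svm = joblib.load(blob_path)
    return FoldModel(
        feature_ids=manifest["feature_ids"],
        scaler=ScalerParams(
            vmin=np.asarray(manifest["scaler"]["vmin"], dtype=float),
            vmax=np.asarray(manifest["scaler"]["vmax"], dtype=float),
        ),
        c=manifest["C"],
        gamma=manifest["gamma"],
        class_labels=manifest["class_labels"],
        svm=svm,
        metadata=manifest["metadata"],
    )
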