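"""RBF-SVM lesion classification, majority voting and evaluation metrics.

ROIs are classified independently by a support vector machine with a
radial basis function kernel; an image-level call is the majority vote of
its ROI labels (ties go to melanoma, the fail-safe direction).  Evaluation
uses the standard confusion-matrix metrics with benign as the positive
class:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Reported percentages are rounded half-up to integer percent.  For the
melanoma row the class roles are swapped (melanoma as positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "BENIGN",
    "MELANOMA",
    "TrainedModel",
    "ImagePrediction",
    "ConfusionMatrix",
    "ClassMetrics",
    "TrainingError",
    "train",
    "predict_rois",
    "predict_image",
    "confusion",
    "metrics",
    "assert_grouped_split",
]

BENIGN = "benign"
MELANOMA = "melanoma"
CLASS_LABELS = (BENIGN, MELANOMA)


class TrainingError(ValueError):
    """Raised when the training set cannot produce a valid model."""


def _round_half_up_percent(fraction: float) -> int:
    return int(np.floor(fraction * 100.0 + 0.5))


@dataclass
class TrainedModel:
    """A fitted RBF-SVM with its feature standardisation.

    Standardisation statistics come from the training ROIs only.  The
    model can round-trip through JSON; a deserialised model predicts via
    the explicit kernel expansion
    ``f(x) = sum_i a_i * exp(-gamma * ||sv_i - x||^2) + b``.
    """

    feature_names: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    C: float
    classes: tuple[str, str]
    seed: int = 0
    config_hash: str = ""
    _svc: SVC | None = field(default=None, repr=False, compare=False)

    def _standardise(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature matrix must have {len(self.feature_names)} columns "
                f"matching the training manifest, got shape {X.shape}"
            )
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = self._standardise(X)
        if self._svc is not None:
            return self._svc.decision_function(Z)
        d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes[1], self.classes[0])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": "rbf-svm",
            "feature_names": list(self.feature_names),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "C": self.C,
            "classes": list(self.classes),
            "seed": self.seed,
            "config_hash": self.config_hash,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        if d.get("model") != "rbf-svm":
            raise ValueError(f"unrecognised model file: {path}")
        return cls(
            feature_names=tuple(d["feature_names"]),
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_scale=np.asarray(d["scaler_scale"]),
            support_vectors=np.asarray(d["support_vectors"]),
            dual_coef=np.asarray(d["dual_coef"]),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            C=float(d["C"]),
            classes=tuple(d["classes"]),
            seed=int(d.get("seed", 0)),
            config_hash=d.get("config_hash", ""),
        )


@dataclass(frozen=True)
class ImagePrediction:
    """Per-ROI labels and the majority-vote winner for one image."""

    image_id: str
    per_roi_labels: tuple[str, ...]
    n_benign: int
    n_melanoma: int
    winner: str


@dataclass(frozen=True)
class ConfusionMatrix:
    """ROI-level confusion counts with benign as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same counts with the class roles exchanged."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class ClassMetrics:
    """Precision/recall/F1 as fractions plus integer-percent renderings.

    ``undefined`` flags a zero denominator; the corresponding fractions are
    ``nan`` rather than raising.
    """

    precision: float
    recall: float
    f1: float
    undefined: bool = False

    @property
    def precision_pct(self) -> int:
        return _round_half_up_percent(self.precision)

    @property
    def recall_pct(self) -> int:
        return _round_half_up_percent(self.recall)

    @property
    def f1_pct(self) -> int:
        return _round_half_up_percent(self.f1)


def train(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
    C: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
    config_hash: str = "",
) -> TrainedModel:
    """Fit the RBF-SVM on ROI feature vectors.

    Features are standardised (zero mean, unit variance per column) using
    statistics of the training set only.  ``gamma='scale'`` resolves to
    ``1 / (n_features * var)`` of the standardised matrix.  The result is
    deterministic for a given seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    present = set(np.unique(y))
    if not present.issuperset(CLASS_LABELS):
        raise TrainingError(
            f"training data must contain both classes {CLASS_LABELS}, got {sorted(present)}"
        )
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length must match feature columns")

    scaler = StandardScaler().fit(X)
    scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
    Z = (X - scaler.mean_) / scale
    svc = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    svc.fit(Z, y)
    return TrainedModel(
        feature_names=tuple(feature_names),
        scaler_mean=np.asarray(scaler.mean_),
        scaler_scale=scale,
        support_vectors=np.asarray(svc.support_vectors_),
        dual_coef=np.asarray(svc.dual_coef_[0]),
        intercept=float(svc.intercept_[0]),
        gamma=float(svc._gamma),
        C=C,
        classes=tuple(svc.classes_),
        seed=seed,
        config_hash=config_hash,
        _svc=svc,
    )


def predict_rois(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Per-ROI class labels for a feature matrix."""
    return model.predict(features)


def predict_image(
    model: TrainedModel,
    features: np.ndarray,
    image_id: str = "",
    tie_break: str = MELANOMA,
) -> ImagePrediction:
    """Classify every ROI of one image and take the majority vote.

    The predicted class winner is the label receiving the most ROI votes;
    an exact tie goes to ``tie_break`` (default melanoma, erring toward
    the malignant call).
    """
    X = np.asarray(features, dtype=float)
    if X.size == 0 or X.shape[0] == 0:
        raise ValueError("predict_image requires at least one ROI")
    labels = model.predict(X)
    return tally_votes(labels, image_id=image_id, tie_break=tie_break)


def tally_votes(
    per_roi_labels,
    image_id: str = "",
    tie_break: str = MELANOMA,
) -> ImagePrediction:
    """Majority vote over per-ROI labels (order-invariant)."""
    labels = tuple(per_roi_labels)
    unknown = set(labels) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    if tie_break not in CLASS_LABELS:
        raise ValueError(f"tie_break must be one of {CLASS_LABELS}")
    nb = labels.count(BENIGN)
    nm = labels.count(MELANOMA)
    if nb > nm:
        winner = BENIGN
    elif nm > nb:
        winner = MELANOMA
    else:
        winner = tie_break
    return ImagePrediction(
        image_id=image_id,
        per_roi_labels=labels,
        n_benign=nb,
        n_melanoma=nm,
        winner=winner,
    )


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Confusion counts over paired label lists, benign positive."""
    t = np.asarray(list(true_labels))
    p = np.asarray(list(predicted_labels))
    if t.shape != p.shape:
        raise ValueError("label lists must have equal length")
    unknown = (set(np.unique(t)) | set(np.unique(p))) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    return ConfusionMatrix(
        tp=int(np.sum((t == BENIGN) & (p == BENIGN))),
        tn=int(np.sum((t == MELANOMA) & (p == MELANOMA))),
        fp=int(np.sum((t == MELANOMA) & (p == BENIGN))),
        fn=int(np.sum((t == BENIGN) & (p == MELANOMA))),
    )


def metrics(cm: ConfusionMatrix, positive_class: str = BENIGN) -> ClassMetrics:
    """Precision, recall and F1 for the chosen positive class.

    For ``positive_class='melanoma'`` the confusion roles are swapped
    before applying the standard formulas.  Zero denominators set the
    ``undefined`` flag instead of raising.
    """
    if positive_class == MELANOMA:
        cm = cm.swapped()
    elif positive_class != BENIGN:
        raise ValueError(f"positive_class must be one of {CLASS_LABELS}")
    undefined = False
    if cm.tp + cm.fp == 0 or cm.tp + cm.fn == 0:
        undefined = True
        precision = recall = f1 = float("nan")
    else:
        precision = cm.tp / (cm.tp + cm.fp)
        recall = cm.tp / (cm.tp + cm.fn)
        if precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
    return ClassMetrics(precision=precision, recall=recall, f1=f1, undefined=undefined)


def assert_grouped_split(train_ids, test_ids) -> None:
    """Guard against leakage: no image id on both sides of the split."""
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise TrainingError(
            f"image ids appear in both train and test partitions: {sorted(overlap)}"
        )
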