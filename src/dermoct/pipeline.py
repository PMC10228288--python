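"""End-to-end orchestration: AC map -> surface -> ROIs -> features ->
SVM -> majority vote -> metrics.

The unit of training and prediction is the ROI; the unit of diagnosis is
the image, labelled by majority vote over its ROI calls.  The train/test
split is always by image so no lesion contributes ROIs to both sides.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ac import ACMap, BScan, ac_map, depth_profile
from .classify import (
    BENIGN,
    MELANOMA,
    ClassMetrics,
    ConfusionMatrix,
    ImagePrediction,
    assert_grouped_split,
    confusion,
    metrics,
    predict_image,
    train,
)
from .config import PipelineConfig
from .features import GaborBank, extract_features, feature_names
from .segmentation import ROI, SurfaceProfile, apply_artifact_mask, detect_surface, extract_rois

__all__ = [
    "ImageAnalysis",
    "EvaluationReport",
    "gabor_bank_from_config",
    "analyze_image",
    "run_pipeline",
    "simulate_dataset",
    "report_text",
]

logger = logging.getLogger(__name__)


@dataclass
class ImageAnalysis:
    """Intermediate products of one image's journey through the pipeline."""

    image_id: str
    acmap: ACMap
    surface: SurfaceProfile
    rois: list[ROI]
    features: np.ndarray
    label: str | None = None


@dataclass
class EvaluationReport:
    """Per-image votes, ROI-level confusion matrix and class metrics."""

    predictions: list[ImagePrediction]
    true_labels: dict[str, str]
    cm: ConfusionMatrix
    benign_metrics: ClassMetrics
    melanoma_metrics: ClassMetrics
    image_accuracy: float
    roi_accuracy: float
    config_hash: str = ""
    seed: int = 0


def gabor_bank_from_config(config: PipelineConfig) -> GaborBank:
    n = config.gabor_orientations
    return GaborBank(
        frequencies=tuple(config.gabor_frequencies),
        orientations=tuple(k * np.pi / n for k in range(n)),
    )


def _resolve_gamma(value: str) -> float | str:
    try:
        return float(value)
    except ValueError:
        return value


def analyze_image(
    bscan: BScan,
    config: PipelineConfig,
    mask: np.ndarray | None = None,
    label: str | None = None,
    bank: GaborBank | None = None,
) -> ImageAnalysis:
    """Run one image through AC mapping, segmentation and features."""
    if mask is not None:
        bscan = apply_artifact_mask(bscan, mask)
    amap = ac_map(
        bscan,
        kernel=config.ac_kernel,
        fit_depth=config.fit_depth,
        smooth_window=config.smooth_window,
        min_samples=config.min_fit_samples,
    )
    surface = detect_surface(
        amap,
        smooth_sigma=config.surface_smooth_sigma,
        median_width=config.surface_median_width,
    )
    rois = extract_rois(
        bscan,
        surface,
        entrance_band=config.entrance_band,
        acmap=amap,
        roi_width=config.roi_width,
        roi_height=config.roi_height,
        stride=config.roi_stride,
        border_trim=config.border_trim,
        min_valid_fraction=config.min_valid_fraction,
    )
    if bank is None:
        bank = gabor_bank_from_config(config)
    use_ac = config.use_ac_features and config.roi_height == 150
    vectors = []
    for roi in rois:
        patch = bscan.pixels[roi.row_slice, roi.col_slice]
        profile = None
        if use_ac:
            ac_patch = amap.values[roi.row_slice, roi.col_slice]
            profile = depth_profile(ac_patch, roi.valid_mask)
        fv = extract_features(patch, roi.valid_mask, bank, ac_profile=profile)
        vectors.append(fv.values)
    n_feat = len(feature_names(bank, with_ac=use_ac))
    features = np.vstack(vectors) if vectors else np.empty((0, n_feat))
    return ImageAnalysis(
        image_id=bscan.source_id,
        acmap=amap,
        surface=surface,
        rois=rois,
        features=features,
        label=label,
    )


def _roi_table(analyses: list[ImageAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        for i, roi in enumerate(a.rois):
            rows.append(
                {
                    "image_id": a.image_id,
                    "roi_index": i,
                    "column_start": roi.column_start,
                    "top_row": roi.top_row,
                    "valid_fraction": round(roi.valid_fraction, 6),
                }
            )
    return pd.DataFrame(
        rows, columns=["image_id", "roi_index", "column_start", "top_row", "valid_fraction"]
    )


def run_pipeline(
    config: PipelineConfig,
    train_images: list[tuple[BScan, np.ndarray | None, str]],
    test_images: list[tuple[BScan, np.ndarray | None, str]],
    out_dir: str | Path | None = None,
) -> EvaluationReport:
    """Train on one image set, evaluate on a disjoint one.

    Each entry is ``(bscan, artifact_mask_or_None, class_label)``.  Raises
    if any image id appears on both sides of the split.  With ``out_dir``
    set, writes ROI tables, the feature matrix, the model, per-image
    predictions, a plain-text report and a machine-readable run record.
    """
    assert_grouped_split(
        [b.source_id for b, _, _ in train_images],
        [b.source_id for b, _, _ in test_images],
    )
    bank = gabor_bank_from_config(config)

    logger.info("analysing %d training images", len(train_images))
    train_an = [analyze_image(b, config, mask=m, label=l, bank=bank) for b, m, l in train_images]
    logger.info("analysing %d test images", len(test_images))
    test_an = [analyze_image(b, config, mask=m, label=l, bank=bank) for b, m, l in test_images]

    X_parts = [a.features for a in train_an if len(a.rois)]
    y_parts = [[a.label] * len(a.rois) for a in train_an if len(a.rois)]
    if not X_parts:
        raise RuntimeError("no training ROIs survived extraction")
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    use_ac = config.use_ac_features and config.roi_height == 150
    names = feature_names(bank, with_ac=use_ac)
    model = train(
        X,
        y,
        feature_names=names,
        C=config.svm_c,
        gamma=_resolve_gamma(config.svm_gamma),
        seed=config.seed,
        config_hash=config.config_hash,
    )

    predictions, true_roi, pred_roi = [], [], []
    for a in test_an:
        if not len(a.rois):
            logger.warning("test image %s yielded no ROIs; skipped", a.image_id)
            continue
        p = predict_image(model, a.features, image_id=a.image_id, tie_break=config.tie_break)
        predictions.append(p)
        true_roi.extend([a.label] * len(a.rois))
        pred_roi.extend(p.per_roi_labels)

    cm = confusion(true_roi, pred_roi)
    true_by_id = {a.image_id: a.label for a in test_an}
    correct = sum(1 for p in predictions if p.winner == true_by_id[p.image_id])
    report = EvaluationReport(
        predictions=predictions,
        true_labels=true_by_id,
        cm=cm,
        benign_metrics=metrics(cm, BENIGN),
        melanoma_metrics=metrics(cm, MELANOMA),
        image_accuracy=correct / len(predictions) if predictions else float("nan"),
        roi_accuracy=(cm.tp + cm.tn) / cm.total if cm.total else float("nan"),
        config_hash=config.config_hash,
        seed=config.seed,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _roi_table(train_an + test_an).to_csv(out / "rois.csv", index=False)
        pd.DataFrame(X, columns=list(names)).to_csv(out / "train_features.csv", index=False)
        model.to_json(out / "model.json")
        pd.DataFrame(
            [
                {
                    "image_id": p.image_id,
                    "true_class": true_by_id[p.image_id],
                    "n_rois": len(p.per_roi_labels),
                    "n_benign": p.n_benign,
                    "n_melanoma": p.n_melanoma,
                    "winner": p.winner,
                }
                for p in predictions
            ]
        ).to_csv(out / "predictions.csv", index=False)
        (out / "report.txt").write_text(report_text(report))
        record = {
            "dermoct_version": __version__,
            "python": platform.python_version(),
            "config_hash": config.config_hash,
            "seed": config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(config).items()},
        }
        (out / "run_record.json").write_text(json.dumps(record, indent=1))
    return report


def report_text(report: EvaluationReport) -> str:
    """Plain-text evaluation report: per-image votes, confusion counts,
    per-class precision/recall/F1 in integer percent."""
    lines = ["Per-image majority votes", "-" * 72]
    lines.append(
        f"{'image_id':<20}{'true':<10}{'rois':>6}{'benign':>8}{'melanoma':>10}  winner"
    )
    for p in report.predictions:
        lines.append(
            f"{p.image_id:<20}{report.true_labels.get(p.image_id, '?'):<10}"
            f"{len(p.per_roi_labels):>6}{p.n_benign:>8}{p.n_melanoma:>10}  {p.winner}"
        )
    cm = report.cm
    lines += [
        "",
        "ROI-level confusion matrix (positive class: benign)",
        "-" * 72,
        f"TP {cm.tp}  TN {cm.tn}  FP {cm.fp}  FN {cm.fn}",
        "",
        "Class metrics (integer percent, rounded half-up)",
        "-" * 72,
        f"{'class':<12}{'precision':>10}{'recall':>8}{'F1':>6}",
    ]
    for name, m in (("benign", report.benign_metrics), ("melanoma", report.melanoma_metrics)):
        if m.undefined:
            lines.append(f"{name:<12}{'n/a':>10}{'n/a':>8}{'n/a':>6}")
        else:
            lines.append(
                f"{name:<12}{m.precision_pct:>9}%{m.recall_pct:>7}%{m.f1_pct:>5}%"
            )
    lines += [
        "",
        f"Image-level accuracy: {report.image_accuracy:.3f}",
        f"ROI-level accuracy:   {report.roi_accuracy:.3f}",
        f"Config hash: {report.config_hash}  seed: {report.seed}",
        "",
    ]
    return "\n".join(lines)


def simulate_dataset(
    n_train_per_class: int = 37,
    n_test_per_class: int = 6,
    seed: int = 0,
) -> tuple[list, list]:
    """Phantom train/test sets in ``run_pipeline`` input form.

    Defaults mirror a 74-image training and 12-image test design, half
    benign and half melanoma on each side.
    """
    from .synthetic import make_dataset

    phantoms, _ = make_dataset(
        n_train_per_class + n_test_per_class,
        n_train_per_class + n_test_per_class,
        seed=seed,
    )
    benign = [p for p in phantoms if p.label == BENIGN]
    melanoma = [p for p in phantoms if p.label == MELANOMA]
    as_input = lambda p: (p.bscan, p.artifact_mask if p.artifact_mask.any() else None, p.label)
    train_set = [as_input(p) for p in benign[:n_train_per_class] + melanoma[:n_train_per_class]]
    test_set = [as_input(p) for p in benign[n_train_per_class:] + melanoma[n_train_per_class:]]
    return train_set, test_set
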