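"""End-to-end pipeline: crop -> preprocess -> segment -> rule filter ->
control ROIs -> features -> selection -> classification -> report.

A run operates on one or more slices (phase stacks, optionally with
phantom ground truth).  Detection stages run per slice; feature vectors
are pooled across slices into one table before selection and
classification.  Every intermediate is written to the output directory
(crop-window JSON, mask PNGs, ROI/feature CSVs, selection report,
evaluation report), and the whole run is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import EvalReport, mcnemar, train_eval_ffbpn, train_eval_svm
from .control_rois import build_control_set
from .core import DcePhaseStack, to_unit_range
from .crop import crop_to_window
from .features import FeatureConfig, extract_feature_vector, feature_names
from .fp_rules import RoiRecord, region_props, rule_filter
from .phantom import PhantomTruth
from .segmentation import SegmentationConfig, SegmentationResult, segment_slice
from .selection import sequential_backward_select

__all__ = ["PipelineConfig", "SliceDetection", "PipelineResult",
           "detect_slice", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("crop", "segment", "detect", "controls", "features", "train")

#: a kept detected ROI is labelled "lesion" if its overlap with some truth
#: lesion reaches this fraction of either the truth's or the ROI's area
MATCH_OVERLAP = 0.5


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    min_area: int = 15
    max_ecc: float = 0.95
    min_samples_per_class: int = 12         # below this, skip classification
    hidden_sizes: tuple[int, ...] = (6, 10)
    ffbpn_repeats: int = 5
    svm_folds: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        seg = raw.get("segmentation", {})
        for k, v in seg.items():
            setattr(cfg.segmentation, k, tuple(v) if isinstance(v, list) else v)
        feats = raw.get("features", {})
        for k, v in feats.items():
            setattr(cfg.features, k, tuple(v) if isinstance(v, list) else v)
        for k in ("min_area", "max_ecc", "min_samples_per_class",
                  "ffbpn_repeats", "svm_folds"):
            if k in raw:
                setattr(cfg, k, raw[k])
        if "hidden_sizes" in raw:
            cfg.hidden_sizes = tuple(raw["hidden_sizes"])
        return cfg


@dataclass
class SliceDetection:
    """Per-slice result through the control-ROI stage (cropped coordinates)."""

    segmentation: SegmentationResult
    rois: list[RoiRecord]
    kept: list[RoiRecord]
    rejected: list[RoiRecord]
    controls: list[RoiRecord]
    counters: dict


def _label_detected(kept: list[RoiRecord], truth: PhantomTruth, window) -> None:
    """Synthetic-mode labelling: match kept ROIs against truth lesion masks."""
    truth_cropped = [crop_to_window(m, window) for m in truth.lesion_masks]
    for roi in kept:
        roi.label = "healthy"               # surviving false positive
        for tm in truth_cropped:
            inter = int(np.sum(roi.mask & tm))
            if inter >= MATCH_OVERLAP * tm.sum() or inter >= MATCH_OVERLAP * roi.area_px:
                roi.label = "lesion"
                break


def detect_slice(
    stack: DcePhaseStack,
    config: PipelineConfig | None = None,
    truth: PhantomTruth | None = None,
) -> SliceDetection:
    """Run one slice through segmentation, rule filtering and control ROIs."""
    config = config or PipelineConfig()
    seg = segment_slice(stack, config.segmentation)
    rois = region_props(seg.mask)
    kept, rejected = rule_filter(rois, min_area=config.min_area, max_ecc=config.max_ecc)
    truth_lesions_cropped = None
    if truth is not None:
        _label_detected(kept, truth, seg.window)
        truth_lesions_cropped = np.zeros(seg.window.shape, dtype=bool)
        for m in truth.lesion_masks:
            truth_lesions_cropped |= crop_to_window(m, seg.window)
    controls = build_control_set(kept, seg.window, truth_lesions_cropped)
    counters = {
        "rois_found": len(rois),
        "rois_rejected_small": sum(1 for r in rois if r.area_px < config.min_area),
        "rois_rejected_eccentric": sum(
            1 for r in rois
            if r.area_px >= config.min_area and r.eccentricity > config.max_ecc
        ),
        "rois_kept": len(kept),
        "controls_created": len(controls),
    }
    logger.info("slice counters: %s", counters)
    return SliceDetection(
        segmentation=seg, rois=rois, kept=kept, rejected=rejected,
        controls=controls, counters=counters,
    )


@dataclass
class PipelineResult:
    detections: list[SliceDetection]
    roi_table: pd.DataFrame
    feature_table: pd.DataFrame | None
    selection: dict | None
    report: EvalReport | None
    counters: dict


def _roi_table(detections: list[SliceDetection]) -> pd.DataFrame:
    rows = []
    for si, det in enumerate(detections):
        for roi in det.rois + det.controls:
            kept = any(roi is k for k in det.kept) or roi.provenance == "control"
            rows.append(
                {
                    "slice": si,
                    "roi_id": roi.roi_id,
                    "provenance": roi.provenance,
                    "label": roi.label,
                    "area_px": roi.area_px,
                    "eccentricity": round(roi.eccentricity, 6),
                    "centroid_row": round(roi.centroid[0], 3),
                    "centroid_col": round(roi.centroid[1], 3),
                    "kept": bool(kept),
                    "source_roi_id": roi.source_roi_id,
                }
            )
    return pd.DataFrame(rows)


def _feature_table(detections: list[SliceDetection], config: PipelineConfig) -> pd.DataFrame:
    names = feature_names(config.features.distances, config.features.include_extras)
    rows = []
    for si, det in enumerate(detections):
        phase0 = to_unit_range(det.segmentation.cropped_phase0)
        for roi in det.kept + det.controls:
            vec = extract_feature_vector(phase0, roi, config.features)
            row = {"slice": si, "roi_id": roi.roi_id, "provenance": roi.provenance,
                   "label": roi.label}
            row.update({n: round(v, 10) for n, v in zip(names, vec.values)})
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    slices,
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir=None,
    stop_after: str | None = None,
) -> PipelineResult:
    """Execute the pipeline over ``slices``.

    ``slices`` is a list of ``DcePhaseStack`` or ``(stack, truth)`` pairs;
    truths enable synthetic-mode labelling and control validation.
    ``stop_after`` names a stage from :data:`STAGES` to end the run early
    (artifacts up to that stage are still written).
    """
    config = config or PipelineConfig()
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; choose from {STAGES}")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    pairs = [(s, None) if isinstance(s, DcePhaseStack) else tuple(s) for s in slices]
    detections = [detect_slice(stack, config, truth) for stack, truth in pairs]

    if out is not None:
        for si, det in enumerate(detections):
            (out / f"slice{si:03d}_window.json").write_text(
                json.dumps(det.segmentation.window.to_dict())
            )
            from .io import write_mask_png

            write_mask_png(det.segmentation.mask.values, out / f"slice{si:03d}_otsu.png")

    counters: dict = {}
    for det in detections:
        for k, v in det.counters.items():
            counters[k] = counters.get(k, 0) + v

    roi_table = _roi_table(detections)
    if out is not None:
        roi_table.to_csv(out / "rois.csv", index=False)
    if stop_after in ("crop", "segment", "detect", "controls"):
        return PipelineResult(detections, roi_table, None, None, None, counters)

    feature_table = _feature_table(detections, config)
    if out is not None:
        feature_table.to_csv(out / "features.csv", index=False)
    if stop_after == "features":
        return PipelineResult(detections, roi_table, feature_table, None, None, counters)

    names = feature_names(config.features.distances, config.features.include_extras)
    if feature_table.empty:
        labelled = feature_table
        y = np.zeros(0, dtype=int)
        X = np.zeros((0, len(names)))
    else:
        labelled = feature_table[feature_table["label"].isin(["lesion", "healthy"])]
        y = (labelled["label"] == "lesion").to_numpy().astype(int)
        X = labelled[names].to_numpy()
    class_counts = np.bincount(y, minlength=2)
    selection = None
    report = None
    if class_counts.min() >= config.min_samples_per_class:
        sel = sequential_backward_select(X, y, seed=seed)
        selection = sel.to_dict()
        X_sel = X[:, sel.selected]
        report = EvalReport()
        ann_preds = {}
        for h in config.hidden_sizes:
            rep, test_idx, y_pred = train_eval_ffbpn(
                X_sel, y, hidden_n=h, repeats=config.ffbpn_repeats, seed=seed
            )
            report.classifiers[rep.name] = rep
            ann_preds[h] = (test_idx, y_pred)
        svm_rep, _, svm_pred = train_eval_svm(
            X_sel, y, folds=config.svm_folds, seed=seed
        )
        report.classifiers[svm_rep.name] = svm_rep
        # McNemar pairs SVM (A) against each ANN on the ANN's held-out
        # samples, using the SVM's out-of-fold predictions for those rows
        for h, (test_idx, ann_pred) in ann_preds.items():
            for variant in ("exact-conditional", "mid-p"):
                res = mcnemar(y[test_idx], svm_pred[test_idx], ann_pred,
                              variant=variant, alternative="A-better")
                res.variant = f"{variant} vs ANN(n={h})"
                report.mcnemar_tests.append(res)
        if out is not None:
            (out / "selection.json").write_text(json.dumps(selection, indent=2))
            from .io import write_report

            write_report(report, out / "report")
    else:
        logger.warning(
            "class counts %s below minimum %d; classification stage skipped",
            class_counts.tolist(), config.min_samples_per_class,
        )
        if out is not None:
            (out / "report.json").write_text(json.dumps({"skipped": "too few samples"}))

    return PipelineResult(detections, roi_table, feature_table, selection, report, counters)
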