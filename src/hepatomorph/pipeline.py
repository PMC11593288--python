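"""End-to-end analysis pipeline on a synthetic cohort.

Mirrors the study flow: generate (or load) a cohort, segment the
pseudo-B-mode images with the baseline segmenter and score the masks
against truth, extract the 16 morphometric features, classify rear-surface
roughness with the calibrated score, and run the trend/diagnostic
statistics.  All outputs are plain text (CSV/JSON) plus 8-bit PNGs, and a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, maskops, segeval, shapes, stats, surface, synth

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

ENDPOINT_CUTS = {"F1": 1, "F2": 2, "F3": 3, "F4": 4}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    threshold: float = 128.0
    smooth_window: int = surface.DEFAULT_SMOOTH_WINDOW
    focal_gamma: float = 2.0
    endpoints: tuple[str, ...] = ("F3", "F4")
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        for e in self.endpoints:
            if e not in ENDPOINT_CUTS:
                raise ValueError(f"unknown endpoint {e!r}; choose from F1..F4")


def stage_seed(seed: int, stage_name: str) -> int:
    """Derive a stable per-stage child seed (< 2^31) from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _endpoint_label(stage: int, endpoint: str) -> bool:
    cut = ENDPOINT_CUTS[endpoint]
    return stage >= cut if endpoint != "F4" else stage >= 4


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full analysis; write all reports under ``out_dir``.

    Outputs
    -------
    ``masks/``, ``images/``, ``contours/``, ``contours_augmented/`` (PNG);
    ``cohort.csv`` (subject manifest with truth parameters);
    ``segmentation.csv`` (per-subject TP/FP/FN/IoU/F/DiceLoss + mean row);
    ``features.csv`` (16 morphometric columns per subject);
    ``surface_report.csv`` (per-class and overall roughness accuracy for the
    calibration and evaluation cohorts); ``trend.csv`` (feature, JT p);
    ``diagnostics.csv`` (sens/spec/F1/AUROC per feature and endpoint);
    ``manifest.json`` (config, seed, versions, warnings).

    Returns the manifest dict.
    """
    config.validate()
    out = Path(out_dir)
    for sub in ("masks", "images", "contours", "contours_augmented"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    # --- cohort ------------------------------------------------------------
    cohort_cfg = dataclasses.replace(
        config.cohort, seed=stage_seed(config.seed, "synth")
    )
    records = synth.generate_cohort(cohort_cfg)
    rows = []
    for rec in records:
        maskops.write_mask(out / "masks" / f"{rec.subject_id}.png", rec.mask)
        maskops.write_image(out / "images" / f"{rec.subject_id}.png", rec.image)
        t = rec.truth
        rows.append(
            dict(
                subject_id=rec.subject_id,
                stage=rec.stage,
                rough_label=rec.rough_label,
                semi_major=round(t.semi_major, 3),
                semi_minor=round(t.semi_minor, 3),
                bluntness=round(t.bluntness, 3),
                rough_amplitude=round(t.rough_amplitude, 3),
                rough_n_waves=t.rough_n_waves,
                rotation_deg=round(t.rotation_deg, 3),
                center_x=round(t.center[0], 3),
                center_y=round(t.center[1], 3),
            )
        )
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)

    # --- segmentation ------------------------------------------------------
    seg_rows = []
    pred_masks: dict[str, np.ndarray] = {}
    for rec in records:
        try:
            pred = segeval.baseline_segmenter(rec.image)
        except ValueError as exc:
            raise RuntimeError(
                f"segmentation failed for subject {rec.subject_id}: {exc}"
            ) from exc
        pred_masks[rec.subject_id] = pred
        m = segeval.seg_metrics(pred, rec.mask)
        seg_rows.append(
            dict(subject_id=rec.subject_id, TP=m.TP, FP=m.FP, FN=m.FN,
                 IoU=round(m.IoU, 4), F=round(m.F, 4),
                 DiceLoss=round(m.DiceLoss, 4))
        )
    seg_df = pd.DataFrame(seg_rows)
    mean_row = {c: round(float(seg_df[c].mean()), 4)
                for c in ("IoU", "F", "DiceLoss")}
    seg_df = pd.concat(
        [seg_df, pd.DataFrame([dict(subject_id="mean", **mean_row)])],
        ignore_index=True,
    )
    for col in ("TP", "FP", "FN"):
        seg_df[col] = seg_df[col].astype("Int64")
    seg_df.to_csv(out / "segmentation.csv", index=False)

    # --- morphometric features (from the predicted masks) ------------------
    feat_rows = []
    for rec in records:
        try:
            feats = shapes.shape_features(pred_masks[rec.subject_id])
        except ValueError as exc:
            raise RuntimeError(
                f"feature extraction failed for subject {rec.subject_id}: {exc}"
            ) from exc
        row = {"subject_id": rec.subject_id, "stage": rec.stage}
        row.update({k: round(v, 4) for k, v in feats.to_dict().items()})
        feat_rows.append(row)
    feat_df = pd.DataFrame(feat_rows)
    feat_df.to_csv(out / "features.csv", index=False)

    # --- rear-surface roughness --------------------------------------------
    def rear_score(mask: np.ndarray) -> float:
        contour = maskops.trace_contour(mask)
        _, rear = surface.split_front_rear(contour)
        return surface.roughness_score(
            rear, smooth_window=config.smooth_window
        ).rms_residual

    calib_cfg = dataclasses.replace(
        config.cohort, seed=stage_seed(config.seed, "surface_calibration")
    )
    calib = synth.generate_cohort(calib_cfg, render_images=False)
    calib_scores = [rear_score(r.mask) for r in calib]
    calib_labels = [r.rough_label for r in calib]
    try:
        thr = surface.calibrate_threshold(calib_scores, calib_labels)
    except ValueError:
        thr = surface.DEFAULT_ROUGH_THRESHOLD
        warnings_log.append(
            "surface calibration cohort had a single class; "
            "fell back to the default threshold"
        )

    eval_scores = [rear_score(r.mask) for r in records]
    eval_labels = [r.rough_label for r in records]

    def classify(scores):
        return ["rough" if s >= thr else "smooth" for s in scores]

    report_rows = []
    for name, scores, labels in (
        ("calibration", calib_scores, calib_labels),
        ("evaluation", eval_scores, eval_labels),
    ):
        try:
            rep = surface.evaluate_classifier(classify(scores), labels)
        except ValueError as exc:
            warnings_log.append(f"surface evaluation skipped on {name}: {exc}")
            continue
        report_rows.append(
            dict(dataset=name, smooth_acc_pct=rep.smooth_acc_pct,
                 rough_acc_pct=rep.rough_acc_pct,
                 overall_acc_pct=rep.overall_acc_pct,
                 n_smooth=rep.n_smooth, n_rough=rep.n_rough,
                 threshold=round(thr, 4))
        )
    pd.DataFrame(report_rows).to_csv(out / "surface_report.csv", index=False)

    # contour-side images; the rough class additionally gets one bounded
    # affine-augmented copy (rotation/translation only)
    aug_seed = stage_seed(config.seed, "augment")
    for rec in records:
        contour = maskops.trace_contour(rec.mask)
        front, rear = surface.split_front_rear(contour)
        img = surface.render_contour_image(front, rear, rec.mask.shape)
        maskops.write_image(out / "contours" / f"{rec.subject_id}.png", img)
        if rec.rough_label == "rough":
            aug = surface.affine_augment(
                img, seed=aug_seed + int(rec.subject_id[1:])
            )
            maskops.write_image(
                out / "contours_augmented" / f"{rec.subject_id}.png", aug
            )

    # --- statistics --------------------------------------------------------
    stages = feat_df["stage"].to_numpy()
    trend = stats.stage_feature_table(feat_df, stages)
    trend.to_csv(out / "trend.csv", index=False)

    diag_rows = []
    for endpoint in config.endpoints:
        labels = np.array([_endpoint_label(s, endpoint) for s in stages])
        if labels.all() or not labels.any():
            warnings_log.append(
                f"endpoint {endpoint} has a single class in this cohort; skipped"
            )
            continue
        for col in shapes.FEATURE_COLUMNS:
            d = stats.roc_auc(feat_df[col].to_numpy(dtype=float), labels)
            diag_rows.append(
                dict(endpoint=f">={endpoint}" if endpoint != "F4" else "F4",
                     feature=col,
                     sensitivity=round(d.sensitivity, 3),
                     specificity=round(d.specificity, 3),
                     f1=round(d.f1, 3),
                     auroc=round(d.auroc, 3),
                     cutoff=round(d.cutoff, 3),
                     orientation=d.orientation)
            )
    pd.DataFrame(diag_rows).to_csv(out / "diagnostics.csv", index=False)

    # --- manifest ----------------------------------------------------------
    import scipy
    import skimage

    manifest = {
        "package": "hepatomorph",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "cohort": dataclasses.asdict(config.cohort),
            "threshold": config.threshold,
            "smooth_window": config.smooth_window,
            "focal_gamma": config.focal_gamma,
            "endpoints": list(config.endpoints),
        },
        "child_seeds": {
            name: stage_seed(config.seed, name)
            for name in ("synth", "surface_calibration", "augment")
        },
        "surface_threshold": round(thr, 6),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
        },
        "warnings": warnings_log,
        "n_subjects": len(records),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
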