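"""Per-plate aggregation, classifier evaluation and the full pipeline.

The per-plate statistic of the assay is the non-white percentage:

    pct_non_white = 100 * (red + pink + variegating)
                    / (all properly segmented colonies)

where properly segmented excludes the bad-segmentation class (clusters of
overlapping colonies).  Plates with no properly segmented colonies are
reported as undefined, never as 0%.

``run_pipeline`` chains every stage: center-crop/resize, mask prediction,
resize back, border clearing, morphological opening, labelling, the
roundness/size filter, colony cropping, classification with optional
test-time augmentation, and aggregation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import confusion_matrix

from .classification import SmallCNN, classify_crops, load_classifier
from .postprocess import (
    AREA_MIN_DEFAULT,
    ECC_MAX_DEFAULT,
    center_crop_resize,
    clear_border,
    crop_colonies,
    filter_regions,
    label_regions,
    morphological_open,
    resize_mask_to_original,
)
from .segmentation import PlateImage, Segmenter, binarize, load_segmenter, predict_mask
from .synthgen import CLASS_NAMES

__all__ = [
    "PlateSummary",
    "EvaluationReport",
    "aggregate_plate",
    "evaluate_classifier",
    "compare_to_truth",
    "run_pipeline",
    "pooled_binary_labels",
]

_NONWHITE = {"red", "pink", "variegating"}


@dataclass
class PlateSummary:
    plate_id: str
    counts: dict[str, int]
    n_properly_segmented: int
    pct_non_white: float | None

    def as_row(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "n_white": self.counts["white"],
            "n_red": self.counts["red"],
            "n_pink": self.counts["pink"],
            "n_variegating": self.counts["variegating"],
            "n_bad": self.counts["bad_segmentation"],
            "n_properly_segmented": self.n_properly_segmented,
            "pct_non_white": np.nan if self.pct_non_white is None else self.pct_non_white,
            "status": "ok" if self.pct_non_white is not None else "undefined",
        }


def aggregate_plate(predictions: pd.DataFrame) -> PlateSummary:
    """Aggregate per-colony predictions of one plate into a summary.

    All rows must share one plate_id; rows flagged with a non-ok status
    are excluded from the counts.  A plate whose properly-segmented count
    is zero gets ``pct_non_white=None`` (undefined), not 0.
    """
    ids = set(predictions["plate_id"].unique())
    if len(ids) > 1:
        raise ValueError(f"predictions mix multiple plate_ids: {sorted(ids)}")
    plate_id = next(iter(ids)) if ids else ""
    ok = predictions
    if "status" in predictions.columns:
        ok = predictions[predictions["status"] == "ok"]
    counts = {name: int((ok["label"] == name).sum()) for name in CLASS_NAMES}
    denom = sum(counts.values()) - counts["bad_segmentation"]
    if denom > 0:
        pct = 100.0 * (counts["red"] + counts["pink"] + counts["variegating"]) / denom
    else:
        pct = None
    return PlateSummary(plate_id, counts, denom, pct)


@dataclass
class EvaluationReport:
    """Confusion matrix (rows = true, cols = predicted) and derived metrics."""

    confusion: np.ndarray  # 5 x 5 counts in fixed class order
    per_class: pd.DataFrame  # sensitivity, specificity, precision per class
    accuracy: float
    pooled_binary_accuracy: float
    n_evaluated: int
    n_pooled: int


def _check_labels(labels) -> list[str]:
    out = list(labels)
    for l in out:
        if l not in CLASS_NAMES:
            raise ValueError(f"unknown class label: {l!r}")
    return out


def pooled_binary_labels(truth, pred) -> tuple[list[str], list[str]]:
    """Merge red/pink/variegating into 'non-white'; drop true bad-segmentation."""
    t_out, p_out = [], []
    for t, p in zip(truth, pred):
        if t == "bad_segmentation":
            continue
        t_out.append("non-white" if t in _NONWHITE else t)
        p_out.append("non-white" if p in _NONWHITE else p)
    return t_out, p_out


def evaluate_classifier(truth, pred) -> EvaluationReport:
    """Five-class and pooled white/non-white evaluation of paired labels.

    Pooling merges the three non-white classes; pairs whose *true* label
    is bad_segmentation are dropped from the pooled metric, mirroring
    their exclusion from the plate denominator.
    """
    truth = _check_labels(truth)
    pred = _check_labels(pred)
    if len(truth) != len(pred):
        raise ValueError(f"label lists differ in length: {len(truth)} vs {len(pred)}")
    cm = confusion_matrix(truth, pred, labels=list(CLASS_NAMES))
    total = cm.sum()
    acc = float(np.trace(cm) / total) if total else float("nan")
    rows = []
    for i, name in enumerate(CLASS_NAMES):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        rows.append(
            {
                "class": name,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
                "precision": tp / (tp + fp) if tp + fp else np.nan,
            }
        )
    t_bin, p_bin = pooled_binary_labels(truth, pred)
    pooled = (
        float(np.mean([t == p for t, p in zip(t_bin, p_bin)])) if t_bin else float("nan")
    )
    return EvaluationReport(
        confusion=cm,
        per_class=pd.DataFrame(rows),
        accuracy=acc,
        pooled_binary_accuracy=pooled,
        n_evaluated=int(total),
        n_pooled=len(t_bin),
    )


def compare_to_truth(
    summaries: pd.DataFrame, truth: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Per-plate signed/absolute difference in non-white percentage points.

    ``summaries`` needs columns (plate_id, pct_non_white); ``truth`` needs
    (plate_id, true_nonwhite_pct).  Plates undefined on either side are
    kept in the table but excluded from the mean absolute difference.
    """
    s_ids = set(summaries["plate_id"])
    t_ids = set(truth["plate_id"])
    if s_ids != t_ids:
        raise ValueError(
            f"plate_id mismatch; only in summaries: {sorted(s_ids - t_ids)}, "
            f"only in truth: {sorted(t_ids - s_ids)}"
        )
    merged = summaries[["plate_id", "pct_non_white"]].merge(
        truth[["plate_id", "true_nonwhite_pct"]], on="plate_id"
    )
    merged["diff"] = merged["pct_non_white"] - merged["true_nonwhite_pct"]
    merged["abs_diff"] = merged["diff"].abs()
    valid = merged["abs_diff"].dropna()
    mean_abs = float(valid.mean()) if len(valid) else float("nan")
    return merged, mean_abs


def _scaled_open_radius(side: int) -> int:
    # disk radius 2 at the 1024-px working resolution, scaled proportionally
    return max(1, int(round(2 * side / 1024)))


def run_pipeline(
    images_dir: str | Path,
    seg_model: Segmenter | str | Path,
    clf_model: SmallCNN | str | Path,
    out_dir: str | Path,
    tta: bool = True,
    ecc_max: float = ECC_MAX_DEFAULT,
    area_min: int = AREA_MIN_DEFAULT,
    threshold: float = 0.5,
    seed: int = 0,
    crop_padding: int | None = None,
) -> pd.DataFrame:
    """Run the full prediction pipeline over a directory of plate images.

    Writes the per-plate report, a region table, all colony crops and the
    per-colony prediction table under ``out_dir``; returns the report.
    Per-image failures are logged in the report's status column and do
    not stop the run.
    """
    images_dir = Path(images_dir)
    out_dir = Path(out_dir)
    (out_dir / "crops").mkdir(parents=True, exist_ok=True)
    if not isinstance(seg_model, Segmenter):
        seg_model = load_segmenter(seg_model)
    if not isinstance(clf_model, SmallCNN):
        clf_model = load_classifier(clf_model)

    paths = sorted(
        p for p in images_dir.iterdir() if p.suffix.lower() in (".jpg", ".jpeg", ".png")
        and not p.stem.endswith("_mask")
    )
    report_rows, region_rows, pred_tables = [], [], []
    for plate_index, path in enumerate(paths):
        plate_id = path.stem
        try:
            raw = np.asarray(Image.open(path).convert("RGB"))
            plate = center_crop_resize(PlateImage(raw, plate_id), seg_model.input_size)
            side = min(raw.shape[:2])
            prob = predict_mask(seg_model, plate)
            mask = binarize(prob, threshold)
            mask = resize_mask_to_original(mask, (side, side))
            mask = clear_border(mask)
            mask = morphological_open(mask, _scaled_open_radius(side))
            regions = label_regions(mask, plate_id=plate_id)
            kept, rejected = filter_regions(regions, ecc_max=ecc_max, area_min=area_min)
            for r in regions:
                region_rows.append(
                    {
                        "plate_id": plate_id,
                        "region_id": r.region_id,
                        "row_min": r.bbox[0],
                        "col_min": r.bbox[1],
                        "row_max": r.bbox[2],
                        "col_max": r.bbox[3],
                        "area": r.area,
                        "eccentricity": r.eccentricity,
                        "kept": r in kept,
                    }
                )
            original = center_crop_resize(PlateImage(raw, plate_id), side)
            crops = crop_colonies(original, kept, padding=crop_padding)
            for crop in crops:
                Image.fromarray(crop.pixels).save(out_dir / "crops" / crop.name, quality=95)
            plate_seed = int(np.random.default_rng([seed, plate_index]).integers(2**31))
            if crops:
                preds = classify_crops(clf_model, crops, tta=tta, seed=plate_seed)
                pred_tables.append(preds)
            else:
                preds = pd.DataFrame({"plate_id": pd.Series(dtype=str), "label": pd.Series(dtype=str), "status": pd.Series(dtype=str)})
            summary = aggregate_plate(preds)
            row = summary.as_row()
            row["plate_id"] = plate_id
            report_rows.append(row)
        except Exception as e:  # per-image failure: log and continue
            report_rows.append(
                {
                    "plate_id": plate_id,
                    "n_white": 0,
                    "n_red": 0,
                    "n_pink": 0,
                    "n_variegating": 0,
                    "n_bad": 0,
                    "n_properly_segmented": 0,
                    "pct_non_white": np.nan,
                    "status": f"error: {e}",
                }
            )

    report = pd.DataFrame(
        report_rows,
        columns=[
            "plate_id",
            "n_white",
            "n_red",
            "n_pink",
            "n_variegating",
            "n_bad",
            "n_properly_segmented",
            "pct_non_white",
            "status",
        ],
    )
    _write_csv_with_seed(report, out_dir / "plate_report.csv", seed)
    _write_csv_with_seed(pd.DataFrame(region_rows), out_dir / "regions.csv", seed)
    if pred_tables:
        _write_csv_with_seed(pd.concat(pred_tables, ignore_index=True), out_dir / "predictions.csv", seed)
    return report


def _write_csv_with_seed(df: pd.DataFrame, path: Path, seed: int) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)
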