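"""End-to-end orchestration: preprocess, detect, threshold-sweep, segment,
evaluate, report.

The run mirrors a two-stage screening pipeline: candidate boxes come from a
pluggable detector (ground-truth oracle, classical blob baseline, or
external label files), a confidence-threshold sweep over 0.4-0.9 scores
detection quality fold-wise (mAP50 / precision / recall, with a rank-sum
comparison of every threshold against the best one), and at the selected
operating threshold each candidate ROI is cropped, CLAHE + median
preprocessed, segmented with the Chan-Vese model, and pasted back into the
full frame for DICE / HD95 scoring against the composite ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .chanvese import ChanVeseParams, segment_roi
from .detection import (
    BlobDetectorParams,
    DetectionSet,
    apply_threshold,
    blob_detect,
    oracle_detect,
    read_yolo_labels,
)
from .metrics import (
    FoldScores,
    average_precision,
    dice,
    hd95,
    match,
    precision_recall,
    rank_sum_test,
    stratified_kfold,
)
from .prep import (
    Box,
    ImageGrid,
    SegMask,
    clahe,
    crop_roi,
    median3,
    paste_mask,
    resize_mask,
    resize_to,
    scale_box,
)

__all__ = ["PipelineConfig", "SweepReport", "run_pipeline", "threshold_sweep",
           "summarize"]

logger = logging.getLogger(__name__)

DEFAULT_CONF_GRID = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from a single YAML file."""

    images: str | None = None
    labels: str | None = None
    masks: str | None = None
    out: str | None = None

    detector: str = "oracle"
    oracle_jitter_px: float = 0.0
    oracle_drop_prob: float = 0.0
    blob: BlobDetectorParams = field(default_factory=BlobDetectorParams)
    external_labels: str | None = None

    conf_grid: tuple[float, ...] = DEFAULT_CONF_GRID
    chanvese: ChanVeseParams = field(default_factory=ChanVeseParams)

    resize_px: int = 640
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    roi_pad_px: int = 12

    iou_thresh: float = 0.5
    max_det: int = 10
    hd95_mode: str = "pooled"

    k_folds: int = 10
    operating_threshold: float | None = None  # None -> sweep pivot
    n_overlays: int = 8

    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.conf_grid)
        if not grid:
            raise ValueError("conf_grid must be nonempty")
        if any(t2 <= t1 for t1, t2 in zip(grid, grid[1:])):
            raise ValueError("conf_grid must be strictly increasing")
        if not all(0.0 < t < 1.0 for t in grid):
            raise ValueError("conf_grid values must lie in (0, 1)")
        if self.detector not in ("oracle", "blob", "external"):
            raise ValueError(f"unknown detector {self.detector!r}")
        object.__setattr__(self, "conf_grid", grid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "blob" in kwargs and isinstance(kwargs["blob"], dict):
            kwargs["blob"] = BlobDetectorParams(**kwargs["blob"])
        if "chanvese" in kwargs and isinstance(kwargs["chanvese"], dict):
            kwargs["chanvese"] = ChanVeseParams(**kwargs["chanvese"])
        for key in ("conf_grid", "clahe_tiles"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class SweepReport:
    """Per-threshold detection scores plus the segmentation summary."""

    thresholds: tuple[float, ...]
    map50: dict[float, FoldScores]
    precision: dict[float, FoldScores]
    recall: dict[float, FoldScores]
    pivot_threshold: float
    p_values: dict[float, float]
    operating_threshold: float
    seg_table: pd.DataFrame
    seg_summary: dict[str, float]
    failures: list[str] = field(default_factory=list)
    overlays: list[tuple] = field(default_factory=list)

    def sweep_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.thresholds:
            rows.append(
                {
                    "threshold": t,
                    "mAP50_mean": self.map50[t].mean,
                    "mAP50_sd": self.map50[t].sd,
                    "PRE_mean": self.precision[t].mean,
                    "PRE_sd": self.precision[t].sd,
                    "REC_mean": self.recall[t].mean,
                    "REC_sd": self.recall[t].sd,
                    "p_vs_pivot": self.p_values[t],
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sweep


def threshold_sweep(
    dets: dict[str, DetectionSet],
    gts: dict[str, list[Box]],
    grid: tuple[float, ...],
    folds: dict[str, int],
    iou_thresh: float = 0.5,
) -> tuple[dict[float, FoldScores], dict[float, FoldScores],
           dict[float, FoldScores], float, dict[float, float]]:
    """Fold-wise mAP50/PRE/REC per confidence threshold, pivot and p-values.

    The pivot is the threshold of maximal mean mAP50 (ties go to the lower
    threshold); each threshold's fold-wise mAP50 values are compared with
    the pivot's by the two-sided rank-sum test. Folds without any ground
    truth are excluded with a warning.
    """
    if not grid:
        raise ValueError("empty threshold grid")
    fold_ids = sorted(set(folds.values()))
    usable_folds = []
    for f in fold_ids:
        imgs = [i for i, fi in folds.items() if fi == f]
        if sum(len(gts[i]) for i in imgs) == 0:
            logger.warning("fold %d has no ground truths; excluded", f)
            continue
        usable_folds.append((f, imgs))
    if not usable_folds:
        raise ValueError("no fold contains any ground truth")

    map50: dict[float, FoldScores] = {}
    pre: dict[float, FoldScores] = {}
    rec: dict[float, FoldScores] = {}
    for t in grid:
        ap_vals, pre_vals, rec_vals = [], [], []
        for _f, imgs in usable_folds:
            filtered = {i: apply_threshold(dets[i], t) for i in imgs}
            ap_vals.append(
                average_precision(filtered, {i: gts[i] for i in imgs}, iou_thresh)
            )
            tp = fp = fn = 0
            for i in imgs:
                m = match(filtered[i], gts[i], iou_thresh)
                tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
            p = tp / (tp + fp) if tp + fp else 1.0
            r = tp / (tp + fn) if tp + fn else 1.0
            pre_vals.append(p)
            rec_vals.append(r)
        map50[t] = FoldScores.from_values("mAP50", ap_vals)
        pre[t] = FoldScores.from_values("PRE", pre_vals)
        rec[t] = FoldScores.from_values("REC", rec_vals)

    pivot = max(grid, key=lambda t: (map50[t].mean, -t))
    p_values = {}
    for t in grid:
        if t == pivot:
            p_values[t] = 1.0
        else:
            p_values[t] = rank_sum_test(map50[t].values, map50[pivot].values)
    return map50, pre, rec, pivot, p_values


# ---------------------------------------------------------------------------
# Full run


def _load_records(cfg: PipelineConfig) -> list[dict]:
    from .prep import load_image, load_mask

    if cfg.images is None:
        raise ValueError("no input images configured")
    images_dir = Path(cfg.images)
    if not images_dir.is_dir():
        raise FileNotFoundError(f"images directory {images_dir} not found")
    records = []
    manifest = None
    manifest_path = images_dir.parent / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
    missing: list[str] = []
    for img_path in sorted(images_dir.glob("*.png")) + sorted(
        images_dir.glob("*.tif*")
    ):
        image_id = img_path.stem
        image = load_image(img_path)
        boxes: list[Box] = []
        if cfg.labels:
            lp = Path(cfg.labels) / f"{image_id}.txt"
            if lp.exists():
                boxes = read_yolo_labels(lp, (image.width, image.height))
            else:
                missing.append(str(lp))
        masks: list[SegMask] = []
        if cfg.masks:
            masks = [
                load_mask(p)
                for p in sorted(Path(cfg.masks).glob(f"{image_id}_*.png"))
            ]
        severities = ["unknown"] * len(masks)
        if manifest is not None:
            sub = manifest[manifest["image_id"] == image_id]
            severities = [
                str(sub[sub["lesion_id"] == k]["severity"].iloc[0])
                if not sub[sub["lesion_id"] == k].empty
                else "unknown"
                for k in range(len(masks))
            ]
        records.append(
            {
                "image_id": image_id,
                "image": image,
                "boxes": boxes,
                "masks": masks,
                "severities": severities,
            }
        )
    if missing:
        raise FileNotFoundError(
            f"missing label files for {len(missing)} images: {missing[:5]}"
        )
    if not records:
        raise FileNotFoundError(f"no images found under {images_dir}")
    return records


def _resize_record(rec: dict, size: int) -> dict:
    image = rec["image"]
    if image.shape == (size, size):
        return rec
    from_shape = image.shape
    return {
        **rec,
        "image": resize_to(image, size),
        "boxes": [scale_box(b, from_shape, (size, size)) for b in rec["boxes"]],
        "masks": [resize_mask(m, size) for m in rec["masks"]],
    }


def _detect(cfg: PipelineConfig, records: list[dict]) -> dict[str, DetectionSet]:
    dets: dict[str, DetectionSet] = {}
    for i, rec in enumerate(records):
        image_id = rec["image_id"]
        if cfg.detector == "oracle":
            dets[image_id] = oracle_detect(
                rec["boxes"],
                jitter_px=cfg.oracle_jitter_px,
                drop_prob=cfg.oracle_drop_prob,
                seed=(cfg.seed + 7919 * i) % (2**31),
                image_id=image_id,
                max_detections=cfg.max_det,
            )
        elif cfg.detector == "blob":
            params = dataclasses.replace(cfg.blob, max_detections=cfg.max_det)
            dets[image_id] = blob_detect(rec["image"], params, image_id=image_id)
        else:  # external
            if not cfg.external_labels:
                raise ValueError("external detector needs external_labels dir")
            lp = Path(cfg.external_labels) / f"{image_id}.txt"
            boxes = (
                read_yolo_labels(lp, (rec["image"].width, rec["image"].height))
                if lp.exists()
                else []
            )
            dets[image_id] = DetectionSet(
                image_id=image_id, boxes=tuple(boxes), max_detections=cfg.max_det
            )
    return dets


def _strat_labels(records: list[dict]) -> list[str]:
    """Stratification key: severity mix when known, else lesion count."""
    labels = []
    for rec in records:
        sev = set(rec["severities"])
        if sev and sev != {"unknown"}:
            labels.append("malignant" if "malignant" in sev else "benign")
        else:
            labels.append(f"n{len(rec['boxes'])}")
    return labels


def _segment_image(
    cfg: PipelineConfig, rec: dict, dets: DetectionSet
) -> tuple[SegMask, int]:
    """Crop + preprocess + Chan-Vese each detected ROI, composite full-frame."""
    image = rec["image"]
    h, w = image.shape
    composite = np.zeros((h, w), dtype=bool)
    n_rois = 0
    for box in dets.boxes:
        roi_box = box.clipped(h, w).padded(cfg.roi_pad_px, h, w)
        x0, y0, x1, y1 = roi_box.as_int()
        if x1 - x0 < 3 or y1 - y0 < 3:
            continue
        roi = crop_roi(image, roi_box)
        tiles = (
            min(cfg.clahe_tiles[0], max(1, roi.height // 8)),
            min(cfg.clahe_tiles[1], max(1, roi.width // 8)),
        )
        roi = clahe(roi, clip_limit=cfg.clahe_clip, tiles=tiles)
        roi = median3(roi)
        mask = segment_roi(roi, cfg.chanvese)
        composite |= paste_mask((h, w), mask, roi_box).pixels
        n_rois += 1
    return SegMask(composite, frame="full"), n_rois


def run_pipeline(
    cfg: PipelineConfig, records: list[dict] | None = None
) -> SweepReport:
    """Execute the full detect -> sweep -> segment -> evaluate run.

    ``records`` may be passed directly (e.g. from
    :func:`masseg.phantom.read_dataset` or in-memory phantom cases turned
    into records); otherwise they are loaded from the configured paths.
    Per-image segmentation failures are collected, not fatal.
    """
    t_start = time.perf_counter()
    log_events: list[dict] = []

    if records is None:
        records = _load_records(cfg)
    records = [_resize_record(r, cfg.resize_px) for r in records]
    log_events.append({"stage": "load", "n_images": len(records),
                       "elapsed_s": round(time.perf_counter() - t_start, 3)})

    t0 = time.perf_counter()
    dets = _detect(cfg, records)
    log_events.append({"stage": "detect", "detector": cfg.detector,
                       "elapsed_s": round(time.perf_counter() - t0, 3)})

    gts = {r["image_id"]: r["boxes"] for r in records}
    labels = _strat_labels(records)
    k = min(cfg.k_folds, len(records))
    fold_arr = stratified_kfold(labels, k, cfg.seed)
    folds = {r["image_id"]: int(f) for r, f in zip(records, fold_arr)}

    t0 = time.perf_counter()
    map50, pre, rec_scores, pivot, p_values = threshold_sweep(
        dets, gts, cfg.conf_grid, folds, cfg.iou_thresh
    )
    log_events.append({"stage": "sweep", "pivot": pivot,
                       "elapsed_s": round(time.perf_counter() - t0, 3)})

    operating = (
        cfg.operating_threshold if cfg.operating_threshold is not None else pivot
    )

    t0 = time.perf_counter()
    seg_rows = []
    failures: list[str] = []
    overlays: list[tuple] = []
    for rec in records:
        image_id = rec["image_id"]
        gt_masks = rec["masks"]
        gt_composite = np.zeros(rec["image"].shape, dtype=bool)
        for m in gt_masks:
            gt_composite |= m.pixels
        filtered = apply_threshold(dets[image_id], operating)
        try:
            pred, n_rois = _segment_image(cfg, rec, filtered)
        except Exception as exc:  # failure isolation: tabulate and continue
            logger.warning("segmentation failed on %s: %s", image_id, exc)
            failures.append(f"{image_id}: {exc}")
            pred, n_rois = SegMask(np.zeros(rec["image"].shape, bool)), 0
        seg_rows.append(
            {
                "image_id": image_id,
                "n_detections": len(filtered),
                "n_rois_segmented": n_rois,
                "dice": dice(pred, gt_composite),
                "hd95": hd95(pred, gt_composite, mode=cfg.hd95_mode),
            }
        )
        if len(overlays) < cfg.n_overlays:
            overlays.append((image_id, rec["image"], list(filtered.boxes), pred))
    seg_table = pd.DataFrame(
        seg_rows,
        columns=["image_id", "n_detections", "n_rois_segmented", "dice", "hd95"],
    )
    seg_summary = {
        "mean_dice": float(seg_table["dice"].mean()) if len(seg_table) else float("nan"),
        "mean_hd95": float(seg_table["hd95"].mean()) if len(seg_table) else float("nan"),
        "median_hd95": float(seg_table["hd95"].median()) if len(seg_table) else float("nan"),
    }
    log_events.append({"stage": "segment", "n_failures": len(failures),
                       "elapsed_s": round(time.perf_counter() - t0, 3)})

    report = SweepReport(
        thresholds=cfg.conf_grid,
        map50=map50,
        precision=pre,
        recall=rec_scores,
        pivot_threshold=pivot,
        p_values=p_values,
        operating_threshold=float(operating),
        seg_table=seg_table,
        seg_summary=seg_summary,
        failures=failures,
        overlays=overlays,
    )
    if cfg.out:
        summarize(report, cfg.out, cfg=cfg, log_events=log_events)
    return report


def summarize(
    report: SweepReport,
    out: str | Path,
    cfg: PipelineConfig | None = None,
    log_events: list[dict] | None = None,
) -> None:
    """Write sweep.csv, segmentation.csv, run.json, the JSON-lines log and
    per-image overlay PNGs (detected boxes plus segmentation contour)."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    report.sweep_frame().to_csv(out / "sweep.csv", index=False)
    if report.seg_table.empty:
        logger.warning("no segmentation results; segmentation.csv is header-only")
    report.seg_table.to_csv(out / "segmentation.csv", index=False)

    meta = {
        "version": _pkg_version,
        "pivot_threshold": report.pivot_threshold,
        "operating_threshold": report.operating_threshold,
        "segmentation_summary": report.seg_summary,
        "failures": report.failures,
    }
    if cfg is not None:
        meta["config"] = cfg.to_dict()
        meta["seed"] = cfg.seed
    (out / "run.json").write_text(json.dumps(meta, indent=2, default=str))

    if log_events:
        with (out / "run.log.jsonl").open("w") as fh:
            for ev in log_events:
                fh.write(json.dumps(ev) + "\n")

    if report.overlays:
        _write_overlays(report.overlays, out / "overlays")


def _write_overlays(overlays: list[tuple], out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.patches as mpatches
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    for image_id, image, boxes, pred in overlays:
        fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
        ax.imshow(image.pixels, cmap="gray", vmin=0, vmax=1)
        for b in boxes:
            ax.add_patch(
                mpatches.Rectangle(
                    (b.x0, b.y0), b.width, b.height,
                    fill=False, edgecolor="tab:orange", linewidth=1.2,
                )
            )
        if pred.pixels.any():
            ax.contour(pred.pixels.astype(float), levels=[0.5],
                       colors="tab:red", linewidths=1.0)
        ax.set_axis_off()
        fig.savefig(out_dir / f"{image_id}.png", bbox_inches="tight")
        plt.close(fig)
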