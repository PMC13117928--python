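"""Detection and segmentation evaluation: IoU/GIoU, greedy matching,
precision/recall, average precision at IoU 0.5, DICE, HD95, the two-sample
rank-sum test, and stratified k-fold assignment.

Conventions: precision and recall use the 0/0 := 1 rule (an empty prediction
set issues no false alarms); average precision is all-point interpolated
(area under the precision envelope over recall); HD95 pools the two directed
boundary-distance multisets before taking the 95th percentile (a
``max_directed`` variant is available); an empty-vs-nonempty mask pair gets
the frame diagonal as a bounded sentinel distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .prep import Box, SegMask

__all__ = [
    "MatchResult",
    "FoldScores",
    "iou",
    "giou",
    "match",
    "precision_recall",
    "average_precision",
    "dice",
    "hd95",
    "rank_sum_test",
    "stratified_kfold",
]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching predictions to ground truths at one IoU cutoff."""

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if self.tp != len(self.pairs):
            raise ValueError("tp must equal the number of matched pairs")


@dataclass(frozen=True)
class FoldScores:
    """A metric's per-fold values with their mean and standard deviation."""

    name: str
    values: tuple[float, ...]
    mean: float
    sd: float

    @classmethod
    def from_values(cls, name: str, values) -> "FoldScores":
        vals = tuple(float(v) for v in values)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return cls(name=name, values=vals, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# Box overlap


def _check_box(b: Box) -> None:
    if not (b.x0 < b.x1 and b.y0 < b.y1):
        raise ValueError(f"degenerate box {(b.x0, b.y0, b.x1, b.y1)}")


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two half-open boxes; 0 when disjoint."""
    _check_box(a)
    _check_box(b)
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def giou(a: Box, b: Box) -> float:
    """Generalized IoU: IoU minus the enclosing-box slack; range (-1, 1]."""
    _check_box(a)
    _check_box(b)
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    cw = max(a.x1, b.x1) - min(a.x0, b.x0)
    ch = max(a.y1, b.y1) - min(a.y0, b.y0)
    c_area = cw * ch
    return inter / union - (c_area - union) / c_area


# ---------------------------------------------------------------------------
# Matching and detection metrics


def _boxes_of(dets) -> list[Box]:
    """Accept a DetectionSet-like object or a plain list of boxes."""
    return list(getattr(dets, "boxes", dets))


def match(dets, gts: list[Box], iou_thresh: float) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truths.

    Predictions in descending confidence claim the unmatched ground truth of
    highest IoU >= ``iou_thresh``; leftover predictions are false positives,
    leftover ground truths false negatives.
    """
    if not (0.0 < iou_thresh < 1.0):
        raise ValueError("iou_thresh must be in (0, 1)")
    preds = _boxes_of(dets)
    order = sorted(
        range(len(preds)),
        key=lambda i: (-(preds[i].confidence or 0.0), preds[i].x0, preds[i].y0),
    )
    taken = [False] * len(gts)
    pairs: list[tuple[int, int, float]] = []
    for pi in order:
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            v = iou(preds[pi], g)
            if v >= iou_thresh and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            pairs.append((pi, best_j, best_iou))
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(preds) - tp, fn=len(gts) - tp, pairs=tuple(pairs)
    )


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """(precision, recall) with the 0/0 := 1 convention."""
    pre = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 1.0
    rec = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 1.0
    return pre, rec


def average_precision(
    all_preds: dict, all_gts: dict[str, list[Box]], iou_thresh: float = 0.5
) -> float:
    """All-point interpolated average precision over a set of images.

    Predictions are pooled across images, sorted by descending confidence,
    and matched greedily within their image (one match per ground truth).
    With a single class this is the mAP at the given IoU threshold.
    """
    n_gt = sum(len(g) for g in all_gts.values())
    if n_gt == 0:
        raise ValueError("average precision undefined with zero ground truths")
    pooled: list[tuple[float, str, Box]] = []
    for image_id, dets in all_preds.items():
        for b in _boxes_of(dets):
            pooled.append((b.confidence if b.confidence is not None else 0.0,
                           str(image_id), b))
    pooled.sort(key=lambda t: (-t[0], t[1], t[2].x0, t[2].y0))
    taken = {img: [False] * len(g) for img, g in all_gts.items()}
    tps = np.zeros(len(pooled))
    for i, (_, img, b) in enumerate(pooled):
        gts = all_gts.get(img, [])
        flags = taken.get(img, [])
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if flags[j]:
                continue
            v = iou(b, g)
            if v >= iou_thresh and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            flags[best_j] = True
            tps[i] = 1.0
    if len(pooled) == 0:
        return 0.0
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(1.0 - tps)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope: running max from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


# ---------------------------------------------------------------------------
# Segmentation metrics


def _mask_pixels(m) -> np.ndarray:
    return m.pixels if isinstance(m, SegMask) else np.asarray(m, dtype=bool)


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1."""
    pa, pb = _mask_pixels(a), _mask_pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"mask shapes differ: {pa.shape} vs {pb.shape}")
    sa, sb = int(pa.sum()), int(pb.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((pa & pb).sum()) / (sa + sb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one 4-neighbor outside the mask."""
    if not mask.any():
        return np.zeros_like(mask)
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~interior


def hd95(a, b, mode: str = "pooled") -> float:
    """95th percentile Hausdorff distance between two mask boundaries (px).

    ``pooled`` (default) takes the 95th percentile of the two directed
    nearest-neighbor distance multisets pooled together; ``max_directed``
    takes the max of the two directed 95th percentiles. If exactly one mask
    is empty the frame diagonal is returned as a bounded sentinel; two empty
    masks score 0.
    """
    pa, pb = _mask_pixels(a), _mask_pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"mask shapes differ: {pa.shape} vs {pb.shape}")
    ea, eb = not pa.any(), not pb.any()
    if ea and eb:
        return 0.0
    if ea or eb:
        return float(np.hypot(*pa.shape))
    pts_a = np.argwhere(_boundary(pa))
    pts_b = np.argwhere(_boundary(pb))
    d_ab = cKDTree(pts_b).query(pts_a)[0]
    d_ba = cKDTree(pts_a).query(pts_b)[0]
    if mode == "pooled":
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    if mode == "max_directed":
        return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))
    raise ValueError(f"unknown hd95 mode {mode!r}")


# ---------------------------------------------------------------------------
# Statistics and cross-validation splitting


def rank_sum_test(x, y) -> float:
    """Two-sided Mann-Whitney U test p-value.

    Uses the exact null distribution when the smaller sample has <= 10
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections. Identical constant samples give
    p = 1 (the tie-corrected statistic is exactly its null mean).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("rank_sum_test requires at least 2 values per sample")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def stratified_kfold(labels, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Items of each class are shuffled with the seed and dealt round-robin
    onto the folds with a counter that carries over between classes, so both
    the per-fold class counts and the fold sizes stay within one item of
    perfect proportionality.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} items available")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    counter = 0
    for cls in sorted(np.unique(labels).tolist()):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i in idx:
            assignment[i] = counter % k
            counter += 1
    return assignment
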