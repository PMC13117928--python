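"""Candidate-mass detection: oracle and classical blob-detector front ends,
non-maximum suppression, confidence-threshold filtering, and YOLO-label I/O.

The trained neural detector of a production deployment sits behind a small
seam: ``oracle_detect`` replays (optionally jittered) ground truth so the
segmentation stage can be evaluated independently of detector quality;
``blob_detect`` is a deterministic multi-scale Laplacian-of-Gaussian
baseline; the ``external`` route reads boxes (with an optional confidence
column) from YOLO-format label files written by any third-party detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .metrics import iou
from .prep import Box, ImageGrid

__all__ = [
    "DetectionSet",
    "BlobDetectorParams",
    "YoloParseError",
    "oracle_detect",
    "blob_detect",
    "nms",
    "apply_threshold",
    "read_yolo_labels",
    "write_yolo_labels",
]


class YoloParseError(ValueError):
    """A YOLO label line could not be parsed."""


@dataclass(frozen=True)
class DetectionSet:
    """Scored candidate boxes for one image.

    Boxes are kept sorted by descending confidence and capped at
    ``max_detections`` (default 10, enough to scan dense tissue without
    flooding the downstream stages).
    """

    image_id: str
    boxes: tuple[Box, ...] = ()
    max_detections: int = 10

    def __post_init__(self) -> None:
        boxes = sorted(
            self.boxes,
            key=lambda b: (-(b.confidence if b.confidence is not None else 0.0),
                           b.x0, b.y0),
        )
        object.__setattr__(self, "boxes", tuple(boxes[: self.max_detections]))

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass(frozen=True)
class BlobDetectorParams:
    """Multi-scale LoG baseline parameters.

    The per-image confidence is the blob's scale-normalized response divided
    by the image's maximal response, giving a usable [0, 1] score for the
    threshold sweep; it is not calibrated across images.
    """

    sigma_min: float = 8.0
    sigma_max: float = 24.0
    n_scales: int = 6
    response_floor: float = 0.02
    nms_iou: float = 0.5
    max_detections: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.sigma_min < self.sigma_max):
            raise ValueError("require 0 < sigma_min < sigma_max")
        if not (0 < self.nms_iou < 1):
            raise ValueError("nms_iou must be in (0, 1)")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")


def oracle_detect(
    gt_boxes: list[Box],
    jitter_px: float = 0.0,
    drop_prob: float = 0.0,
    seed: int = 0,
    image_id: str = "",
    max_detections: int = 10,
) -> DetectionSet:
    """Ground-truth replay detector with controllable degradation.

    Each surviving ground-truth box has its corners perturbed by independent
    uniform noise in [-jitter_px, jitter_px]; its confidence is
    ``1 - max|perturbation| / jitter_px`` (1.0 when jitter is disabled), so
    heavier jitter maps to lower confidence. Deterministic under ``seed``.
    """
    if jitter_px < 0:
        raise ValueError("jitter_px must be >= 0")
    if not (0.0 <= drop_prob < 1.0):
        raise ValueError("drop_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out: list[Box] = []
    for g in gt_boxes:
        u = rng.uniform()
        deltas = rng.uniform(-jitter_px, jitter_px, size=4)
        if u < drop_prob:
            continue
        if jitter_px > 0:
            x0 = g.x0 + deltas[0]
            y0 = g.y0 + deltas[1]
            x1 = g.x1 + deltas[2]
            y1 = g.y1 + deltas[3]
            if x1 - x0 < 1.0:  # keep the box valid under extreme jitter
                cx = 0.5 * (x0 + x1)
                x0, x1 = cx - 0.5, cx + 0.5
            if y1 - y0 < 1.0:
                cy = 0.5 * (y0 + y1)
                y0, y1 = cy - 0.5, cy + 0.5
            conf = 1.0 - float(np.abs(deltas).max()) / jitter_px
            out.append(Box(x0, y0, x1, y1, confidence=conf))
        else:
            out.append(replace(g, confidence=1.0))
    return DetectionSet(image_id=image_id, boxes=tuple(out),
                        max_detections=max_detections)


def blob_detect(
    image: ImageGrid,
    params: BlobDetectorParams = BlobDetectorParams(),
    image_id: str = "",
) -> DetectionSet:
    """Multi-scale Laplacian-of-Gaussian blob detection (deterministic).

    Bright blobs yield local maxima of the scale-normalized negative LoG
    response; each maximum above ``response_floor`` becomes a box of side
    2*sqrt(2)*sigma centered on it, then NMS and the top-k cap are applied.
    """
    px = image.pixels
    sigmas = np.geomspace(params.sigma_min, params.sigma_max, params.n_scales)
    stack = np.stack(
        [-(s**2) * ndimage.gaussian_laplace(px, s, mode="reflect") for s in sigmas]
    )
    max_resp = float(stack.max())
    if max_resp <= params.response_floor:
        return DetectionSet(image_id=image_id, boxes=(),
                            max_detections=params.max_detections)
    peaks = peak_local_max(
        stack, threshold_abs=params.response_floor, exclude_border=False
    )
    h, w = px.shape
    boxes: list[Box] = []
    for si, py, pxl in peaks:
        s = sigmas[si]
        half = np.sqrt(2.0) * s
        x0, x1 = pxl - half, pxl + half
        y0, y1 = py - half, py + half
        x0, y0 = max(0.0, x0), max(0.0, y0)
        x1, y1 = min(float(w), x1), min(float(h), y1)
        if x1 - x0 < 1 or y1 - y0 < 1:
            continue
        conf = float(stack[si, py, pxl]) / max_resp
        boxes.append(Box(x0, y0, x1, y1, confidence=min(1.0, max(0.0, conf))))
    dets = DetectionSet(image_id=image_id, boxes=tuple(boxes),
                        max_detections=max(params.max_detections, len(boxes)))
    dets = nms(dets, params.nms_iou)
    return DetectionSet(image_id=image_id, boxes=dets.boxes,
                        max_detections=params.max_detections)


def nms(dets: DetectionSet, iou_thresh: float) -> DetectionSet:
    """Greedy non-maximum suppression.

    Boxes are visited in descending confidence (ties broken by smaller
    (x0, y0) lexicographically, for reproducibility); a box is suppressed
    iff its IoU with an already-kept box exceeds ``iou_thresh``.
    """
    if not (0.0 < iou_thresh < 1.0):
        raise ValueError("iou_thresh must be in (0, 1)")
    kept: list[Box] = []
    for b in dets.boxes:  # already sorted desc confidence, lexicographic ties
        if all(iou(b, k) <= iou_thresh for k in kept):
            kept.append(b)
    return DetectionSet(
        image_id=dets.image_id, boxes=tuple(kept),
        max_detections=dets.max_detections,
    )


def apply_threshold(dets: DetectionSet, t: float) -> DetectionSet:
    """Keep detections with confidence >= t (order preserved)."""
    if not (0.0 <= t <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    kept = tuple(
        b for b in dets.boxes
        if (b.confidence if b.confidence is not None else 0.0) >= t
    )
    return DetectionSet(
        image_id=dets.image_id, boxes=kept, max_detections=dets.max_detections
    )


# ---------------------------------------------------------------------------
# YOLO label I/O
#
# One line per object: "class cx cy w h [conf]", all normalized to [0, 1];
# the class is fixed to 0 (mass). Values are written with 10 decimals so a
# write -> read roundtrip is exact to well under 1e-4 px at 640 px.


def read_yolo_labels(path: str | Path, image_size: int | tuple[int, int]) -> list[Box]:
    """Parse a YOLO label file into pixel-corner boxes.

    ``image_size`` is the target frame, either a square side or (w, h).
    Confidence is read from an optional sixth column.
    """
    w, h = (image_size, image_size) if isinstance(image_size, int) else image_size
    boxes: list[Box] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise YoloParseError(f"{path}:{lineno}: expected 5 or 6 fields, "
                                 f"got {len(parts)}")
        try:
            vals = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise YoloParseError(f"{path}:{lineno}: {exc}") from exc
        cx, cy, bw, bh = vals[:4]
        if not all(0.0 <= v <= 1.0 for v in (cx, cy, bw, bh)):
            raise YoloParseError(f"{path}:{lineno}: normalized values outside [0, 1]")
        conf = vals[4] if len(vals) == 5 else None
        boxes.append(Box.from_yolo(cx, cy, bw, bh, w, h, confidence=conf))
    return boxes


def write_yolo_labels(
    boxes: list[Box],
    image_size: int | tuple[int, int],
    path: str | Path,
    with_confidence: bool = False,
) -> None:
    """Write boxes as normalized YOLO label lines (class fixed to 0)."""
    w, h = (image_size, image_size) if isinstance(image_size, int) else image_size
    lines = []
    for b in boxes:
        cx, cy, bw, bh = b.to_yolo(w, h)
        line = f"0 {cx:.10f} {cy:.10f} {bw:.10f} {bh:.10f}"
        if with_confidence and b.confidence is not None:
            line += f" {b.confidence:.10f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
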