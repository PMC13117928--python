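"""Image containers, I/O and ROI preprocessing.

Images are held as 2-D float arrays with intensities normalized to [0, 1];
conversion from 8/16-bit encodings happens only at the I/O boundary.
Coordinates are 0-based and half-open: ``x`` indexes columns (rightward),
``y`` indexes rows (downward), and a box ``(x0, y0, x1, y1)`` covers pixels
``x0 <= x < x1``, ``y0 <= y < y1``.

The preprocessing chain applied to each detected region of interest (ROI)
is contrast-limited adaptive histogram equalization (CLAHE) followed by a
3x3 median filter, the standard denoise-while-keeping-edges combination for
low-contrast mammographic ROIs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import exposure, transform

__all__ = [
    "ImageGrid",
    "Box",
    "SegMask",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "resize_to",
    "resize_mask",
    "scale_box",
    "clahe",
    "median3",
    "crop_roi",
    "paste_mask",
]


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D grayscale intensity field (the image domain the model works on).

    Parameters
    ----------
    pixels
        2-D float array of intensities.
    value_range
        Nominal (min, max) of the encoding; internal arrays use (0, 1).
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("ImageGrid requires a nonempty 2-D array")
        lo, hi = self.value_range
        if px.min() < lo - 1e-9 or px.max() > hi + 1e-9:
            raise ValueError(
                f"intensities [{px.min():.4g}, {px.max():.4g}] outside "
                f"value_range {self.value_range}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with 0-based half-open pixel corners."""

    x0: float
    y0: float
    x1: float
    y1: float
    confidence: float | None = None
    frame: str = "full"

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {(self.x0, self.y0, self.x1, self.y1)}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.frame not in ("full", "roi"):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) of the box center."""
        return (0.5 * (self.y0 + self.y1), 0.5 * (self.x0 + self.x1))

    def as_int(self) -> tuple[int, int, int, int]:
        """Corners rounded to integer pixel indices (x0, y0, x1, y1)."""
        return (
            int(round(self.x0)),
            int(round(self.y0)),
            int(round(self.x1)),
            int(round(self.y1)),
        )

    def clipped(self, height: int, width: int) -> "Box":
        """Box intersected with the image bounds."""
        return dataclasses.replace(
            self,
            x0=max(0.0, self.x0),
            y0=max(0.0, self.y0),
            x1=min(float(width), self.x1),
            y1=min(float(height), self.y1),
        )

    def padded(self, pad: float, height: int, width: int) -> "Box":
        """Box expanded by ``pad`` pixels on every side, clipped to bounds."""
        return dataclasses.replace(
            self,
            x0=max(0.0, self.x0 - pad),
            y0=max(0.0, self.y0 - pad),
            x1=min(float(width), self.x1 + pad),
            y1=min(float(height), self.y1 + pad),
        )

    def to_yolo(self, image_w: int, image_h: int) -> tuple[float, float, float, float]:
        """Normalized (cx, cy, w, h) of the YOLO label dialect."""
        return (
            0.5 * (self.x0 + self.x1) / image_w,
            0.5 * (self.y0 + self.y1) / image_h,
            self.width / image_w,
            self.height / image_h,
        )

    @classmethod
    def from_yolo(
        cls,
        cx: float,
        cy: float,
        w: float,
        h: float,
        image_w: int,
        image_h: int,
        confidence: float | None = None,
    ) -> "Box":
        return cls(
            x0=(cx - w / 2) * image_w,
            y0=(cy - h / 2) * image_h,
            x1=(cx + w / 2) * image_w,
            y1=(cy + h / 2) * image_h,
            confidence=confidence,
        )


@dataclass(frozen=True)
class SegMask:
    """Binary mask together with the coordinate frame it lives in.

    ``frame`` is "roi" for a mask local to a cropped box (whose position is
    recorded in ``source_box``) and "full" for a mask in image coordinates.
    """

    pixels: np.ndarray
    frame: str = "full"
    source_box: Box | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("SegMask requires a 2-D array")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be binary")
            px = px.astype(bool)
        if self.frame not in ("full", "roi"):
            raise ValueError(f"unknown frame {self.frame!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def tight_box(self) -> Box:
        """Minimal axis-aligned box containing the mask (half-open corners)."""
        rows, cols = np.nonzero(self.pixels)
        if rows.size == 0:
            raise ValueError("empty mask has no bounding box")
        return Box(
            x0=float(cols.min()),
            y0=float(rows.min()),
            x1=float(cols.max() + 1),
            y1=float(rows.max() + 1),
            frame=self.frame,
        )


# ---------------------------------------------------------------------------
# I/O


def load_image(path: str | Path) -> ImageGrid:
    """Read an 8- or 16-bit grayscale PNG/TIFF and normalize to [0, 1]."""
    with Image.open(path) as im:
        if im.mode not in ("L", "I;16", "I", "F"):
            im = im.convert("L")
        arr = np.asarray(im)
    arr = arr.astype(float)
    if arr.max() > 255:
        arr /= 65535.0
    elif arr.max() > 1.0:
        arr /= 255.0
    return ImageGrid(np.clip(arr, 0.0, 1.0))


def save_image(image: ImageGrid, path: str | Path) -> None:
    """Write as 8-bit grayscale PNG."""
    arr = np.clip(image.pixels, 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def load_mask(path: str | Path) -> SegMask:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return SegMask(arr >= 128)


def save_mask(mask: SegMask, path: str | Path) -> None:
    """Masks are stored as {0, 255} 8-bit PNG."""
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


# ---------------------------------------------------------------------------
# Preprocessing


def resize_to(image: ImageGrid, size: int) -> ImageGrid:
    """Resize to ``size`` x ``size`` with bilinear interpolation.

    The resize is anisotropic (no letterboxing): each axis is scaled
    independently to the target size.
    """
    if size < 1:
        raise ValueError(f"target size must be >= 1, got {size}")
    out = transform.resize(
        image.pixels, (size, size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return ImageGrid(np.clip(out, *image.value_range), image.value_range)


def resize_mask(mask: SegMask, size: int) -> SegMask:
    """Nearest-neighbor companion resize for binary masks."""
    if size < 1:
        raise ValueError(f"target size must be >= 1, got {size}")
    out = transform.resize(
        mask.pixels.astype(float), (size, size), order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return SegMask(out >= 0.5, frame=mask.frame, source_box=mask.source_box)


def scale_box(box: Box, from_shape: tuple[int, int], to_shape: tuple[int, int]) -> Box:
    """Rescale box corners between image shapes given as (height, width)."""
    sy = to_shape[0] / from_shape[0]
    sx = to_shape[1] / from_shape[1]
    return dataclasses.replace(
        box, x0=box.x0 * sx, y0=box.y0 * sy, x1=box.x1 * sx, y1=box.y1 * sy
    )


def clahe(
    image: ImageGrid,
    clip_limit: float = 2.0,
    tiles: tuple[int, int] = (8, 8),
) -> ImageGrid:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` follows the common integer-histogram convention (default
    2.0); it is mapped to the normalized clip fraction ``clip_limit / 256``
    of the underlying implementation. ``tiles`` is the equalization grid.
    """
    h, w = image.shape
    kh, kw = h // tiles[0], w // tiles[1]
    if kh < 1 or kw < 1:
        raise ValueError(f"tile grid {tiles} larger than image {image.shape}")
    if np.ptp(image.pixels) < 1e-12:
        return ImageGrid(image.pixels.copy(), image.value_range)
    out = exposure.equalize_adapthist(
        np.clip(image.pixels, 0.0, 1.0),
        kernel_size=(kh, kw),
        clip_limit=min(1.0, clip_limit / 256.0),
    )
    return ImageGrid(np.clip(out, *image.value_range), image.value_range)


def median3(image: ImageGrid) -> ImageGrid:
    """3x3 median filter with reflection padding at the edges."""
    if min(image.shape) < 3:
        raise ValueError(f"image {image.shape} smaller than the 3x3 kernel")
    out = ndimage.median_filter(image.pixels, size=3, mode="reflect")
    return ImageGrid(out, image.value_range)


def crop_roi(image: ImageGrid, box: Box) -> ImageGrid:
    """Extract the sub-image under ``box`` (pure copy, no resampling)."""
    if box.frame != "full":
        raise ValueError("crop_roi expects a box in the full-image frame")
    x0, y0, x1, y1 = box.as_int()
    h, w = image.shape
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(f"box {(x0, y0, x1, y1)} out of bounds for {image.shape}")
    return ImageGrid(image.pixels[y0:y1, x0:x1].copy(), image.value_range)


def paste_mask(shape: tuple[int, int], roi_mask: SegMask, box: Box) -> SegMask:
    """Embed an ROI-local mask into a full-frame mask (zero outside the box).

    Overlapping pastes combine by logical OR, so compositing several lesion
    masks is associative.
    """
    x0, y0, x1, y1 = box.as_int()
    if roi_mask.shape != (y1 - y0, x1 - x0):
        raise ValueError(
            f"roi mask {roi_mask.shape} does not match box {(y1 - y0, x1 - x0)}"
        )
    if x0 < 0 or y0 < 0 or x1 > shape[1] or y1 > shape[0]:
        raise ValueError(f"box {(x0, y0, x1, y1)} out of bounds for {shape}")
    full = np.zeros(shape, dtype=bool)
    full[y0:y1, x0:x1] = roi_mask.pixels
    return SegMask(full, frame="full")
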