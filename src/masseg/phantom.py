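"""Synthetic mammogram-like phantom generation.

Real screening mammograms show a bright breast region on a dark background,
fibroglandular texture at a characteristic spatial scale, and low-contrast
masses whose margins carry the diagnostic signal: round, well-circumscribed
contours read as benign while spiculated, irregular contours read as
malignant. The phantoms reproduce exactly those statistics — a half-ellipse
"breast" support filled with a smoothed random texture, additive Gaussian
noise, and star-shaped lesions

    r(theta) = base_radius * (1 + spiculation_amplitude
                              * cos(spiculation_count * theta))

whose spiculation count/amplitude span the benign (round, count = 0) to
malignant (count >= 5) contour axis. Every case carries exact per-lesion
masks and tight YOLO-format boxes, so detector and segmenter can be scored
against analytic ground truth without any external dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .prep import Box, ImageGrid, SegMask, save_image, save_mask
from .detection import write_yolo_labels

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomCase",
    "PlacementError",
    "render_lesion",
    "generate_phantom",
    "write_dataset",
    "read_dataset",
    "make_disk_roi",
]


class PlacementError(RuntimeError):
    """Disjoint lesion placement failed within the retry budget."""


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and contrast of one synthetic mass.

    ``center`` is (row, col). ``intensity_offset`` is the additive contrast
    of the lesion over the local background, in normalized [0, 1] intensity
    units. ``edge_softness`` is the Gaussian sigma (px) applied to the
    intensity layer so the margin is not a hard step.
    """

    center: tuple[float, float]
    base_radius: float
    spiculation_count: int = 0
    spiculation_amplitude: float = 0.0
    intensity_offset: float = 0.5
    edge_softness: float = 1.5
    severity_label: str = "benign"

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be > 0")
        if not (0.0 <= self.spiculation_amplitude < 1.0):
            raise ValueError("spiculation_amplitude must be in [0, 1)")
        if not (0.0 < self.intensity_offset <= 1.0):
            raise ValueError("intensity_offset must be in (0, 1]")
        if self.spiculation_count < 0:
            raise ValueError("spiculation_count must be >= 0")
        if self.severity_label not in ("benign", "malignant"):
            raise ValueError(f"unknown severity {self.severity_label!r}")
        if self.severity_label == "benign" and self.spiculation_count != 0:
            raise ValueError("benign lesions are round (spiculation_count = 0)")
        if self.severity_label == "malignant" and self.spiculation_count < 5:
            raise ValueError("malignant lesions need spiculation_count >= 5")

    @property
    def outer_radius(self) -> float:
        """Radius of the disk that fully contains the star shape."""
        return self.base_radius * (1.0 + self.spiculation_amplitude)


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one generated dataset.

    Defaults emulate a desk-scale screening set: 640 px frames, one or two
    low-contrast lesions per image, fibroglandular-scale texture (sigma 12
    px), mild sensor noise, and a 40% malignant mix.
    """

    image_size: int = 640
    n_images: int = 30
    lesions_per_image: tuple[int, int] = (1, 2)
    background_texture_sigma: float = 12.0
    noise_sigma: float = 0.03
    contrast_range: tuple[float, float] = (0.4, 0.6)
    severity_mix: float = 0.4
    lesion_radius_range: tuple[float, float] = (18.0, 32.0)
    edge_softness: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.contrast_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("contrast_range must lie within (0, 1]")
        if self.lesions_per_image[0] > self.lesions_per_image[1]:
            raise ValueError("lesions_per_image range inverted")
        if self.lesions_per_image[0] < 0:
            raise ValueError("lesions_per_image must be >= 0")
        if not (0.0 <= self.severity_mix <= 1.0):
            raise ValueError("severity_mix must be in [0, 1]")
        if self.image_size < 32:
            raise ValueError("image_size too small")


@dataclass(frozen=True)
class PhantomCase:
    """One generated image with its per-lesion ground truth."""

    image_id: str
    image: ImageGrid
    lesions: tuple[LesionSpec, ...]
    masks: tuple[SegMask, ...]
    boxes: tuple[Box, ...]


def render_lesion(lesion: LesionSpec, size: int) -> tuple[SegMask, ImageGrid]:
    """Rasterize one lesion onto a ``size`` x ``size`` canvas.

    Returns the binary star-shape mask and the additive intensity layer
    (``intensity_offset`` inside the mask, Gaussian-blurred by
    ``edge_softness``).
    """
    cy, cx = lesion.center
    r_out = lesion.outer_radius
    if not (cy - r_out >= 0 and cx - r_out >= 0
            and cy + r_out < size and cx + r_out < size):
        raise ValueError(
            f"lesion at {lesion.center} with outer radius {r_out:.1f} "
            f"does not fit a {size}x{size} canvas"
        )
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_theta = lesion.base_radius * (
        1.0 + lesion.spiculation_amplitude
        * np.cos(lesion.spiculation_count * theta)
    )
    mask = dist <= r_theta
    layer = lesion.intensity_offset * mask.astype(float)
    if lesion.edge_softness > 0:
        layer = ndimage.gaussian_filter(layer, lesion.edge_softness)
    return SegMask(mask, frame="full"), ImageGrid(np.clip(layer, 0.0, 1.0))


def _breast_support(size: int) -> np.ndarray:
    """Half-ellipse breast region anchored to the left image edge."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = size / 2.0
    a = 0.92 * size   # horizontal semi-axis, from the left edge
    b = 0.47 * size   # vertical semi-axis
    return (xx / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


_MAX_PLACEMENT_RETRIES = 100


def generate_phantom(spec: PhantomSpec) -> list[PhantomCase]:
    """Generate a phantom dataset; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    support = _breast_support(size)
    cases: list[PhantomCase] = []
    for i in range(spec.n_images):
        texture = rng.standard_normal((size, size))
        texture = ndimage.gaussian_filter(texture, spec.background_texture_sigma)
        sd = texture.std()
        if sd > 0:
            texture = texture / sd
        background = np.where(support, 0.30 + 0.05 * texture, 0.02)

        n_lesions = int(rng.integers(spec.lesions_per_image[0],
                                     spec.lesions_per_image[1] + 1))
        lesions: list[LesionSpec] = []
        occupied = np.zeros((size, size), dtype=bool)
        for _k in range(n_lesions):
            lesion = _place_lesion(rng, spec, support, occupied, image_index=i)
            lesions.append(lesion)
            # reserve the outer disk plus a 4 px gap
            yy, xx = np.mgrid[0:size, 0:size].astype(float)
            occupied |= np.hypot(yy - lesion.center[0],
                                 xx - lesion.center[1]) <= lesion.outer_radius + 4.0

        image = background
        masks: list[SegMask] = []
        boxes: list[Box] = []
        for lesion in lesions:
            mask, layer = render_lesion(lesion, size)
            image = image + layer.pixels
            masks.append(mask)
            boxes.append(mask.tight_box())
        if spec.noise_sigma > 0:
            image = image + rng.normal(0.0, spec.noise_sigma, (size, size))
        image = np.clip(image, 0.0, 1.0)
        cases.append(
            PhantomCase(
                image_id=f"phantom_{i:04d}",
                image=ImageGrid(image),
                lesions=tuple(lesions),
                masks=tuple(masks),
                boxes=tuple(boxes),
            )
        )
    return cases


def _place_lesion(
    rng: np.random.Generator,
    spec: PhantomSpec,
    support: np.ndarray,
    occupied: np.ndarray,
    image_index: int,
) -> LesionSpec:
    """Rejection-sample one lesion that is inside the breast and disjoint."""
    size = spec.image_size
    for _ in range(_MAX_PLACEMENT_RETRIES):
        base_radius = float(rng.uniform(*spec.lesion_radius_range))
        malignant = bool(rng.random() < spec.severity_mix)
        if malignant:
            spic_count = int(rng.integers(5, 9))
            spic_amp = float(rng.uniform(0.15, 0.30))
        else:
            spic_count, spic_amp = 0, 0.0
        r_out = base_radius * (1.0 + spic_amp)
        margin = r_out + 4.0
        cy = float(rng.uniform(margin, size - margin))
        cx = float(rng.uniform(margin, size - margin))
        iy, ix = int(round(cy)), int(round(cx))
        # footprint must sit inside the breast and clear of other lesions
        ro = int(math.ceil(r_out + 2))
        y0, y1 = max(0, iy - ro), min(size, iy + ro + 1)
        x0, x1 = max(0, ix - ro), min(size, ix + ro + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        disk = np.hypot(yy - cy, xx - cx) <= r_out + 2
        if not support[y0:y1, x0:x1][disk].all():
            continue
        if occupied[y0:y1, x0:x1][disk].any():
            continue
        return LesionSpec(
            center=(cy, cx),
            base_radius=base_radius,
            spiculation_count=spic_count,
            spiculation_amplitude=spic_amp,
            intensity_offset=float(rng.uniform(*spec.contrast_range)),
            edge_softness=spec.edge_softness,
            severity_label="malignant" if malignant else "benign",
        )
    raise PlacementError(
        f"could not place a disjoint lesion in image {image_index} "
        f"after {_MAX_PLACEMENT_RETRIES} retries"
    )


def write_dataset(cases: list[PhantomCase], out_dir: str | Path) -> pd.DataFrame:
    """Write images/, masks/, labels/ and manifest.csv; returns the manifest.

    Layout: ``images/<id>.png`` (8-bit), ``masks/<id>_<k>.png`` ({0, 255}),
    ``labels/<id>.txt`` (YOLO normalized), ``manifest.csv`` with columns
    image_id, lesion_id, severity, cx, cy, w, h.
    """
    out = Path(out_dir)
    for sub in ("images", "masks", "labels"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        size = case.image.shape
        save_image(case.image, out / "images" / f"{case.image_id}.png")
        write_yolo_labels(
            list(case.boxes), (size[1], size[0]),
            out / "labels" / f"{case.image_id}.txt",
        )
        for k, (lesion, mask, box) in enumerate(
            zip(case.lesions, case.masks, case.boxes)
        ):
            save_mask(mask, out / "masks" / f"{case.image_id}_{k}.png")
            cx, cy, w, h = box.to_yolo(size[1], size[0])
            rows.append(
                {
                    "image_id": case.image_id,
                    "lesion_id": k,
                    "severity": lesion.severity_label,
                    "cx": cx,
                    "cy": cy,
                    "w": w,
                    "h": h,
                }
            )
    manifest = pd.DataFrame(
        rows, columns=["image_id", "lesion_id", "severity", "cx", "cy", "w", "h"]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_dataset(root: str | Path) -> list[dict]:
    """Load a dataset written by :func:`write_dataset`.

    Returns one record per image: id, image, ground-truth boxes, per-lesion
    masks and severities (from the manifest when present).
    """
    from .prep import load_image, load_mask
    from .detection import read_yolo_labels

    root = Path(root)
    severity: dict[tuple[str, int], str] = {}
    manifest_path = root / "manifest.csv"
    if manifest_path.exists():
        mf = pd.read_csv(manifest_path)
        for _, row in mf.iterrows():
            severity[(str(row["image_id"]), int(row["lesion_id"]))] = str(
                row["severity"]
            )
    records = []
    for img_path in sorted((root / "images").glob("*.png")):
        image_id = img_path.stem
        image = load_image(img_path)
        label_path = root / "labels" / f"{image_id}.txt"
        boxes = (
            read_yolo_labels(label_path, (image.width, image.height))
            if label_path.exists()
            else []
        )
        masks = [
            load_mask(p)
            for p in sorted((root / "masks").glob(f"{image_id}_*.png"))
        ]
        severities = [
            severity.get((image_id, k), "unknown") for k in range(len(masks))
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
    return records


def make_disk_roi(
    size: int = 128,
    radius: float = 30.0,
    contrast: float = 0.6,
    noise_sigma: float = 0.02,
    background: float = 0.2,
    edge_softness: float = 1.0,
    seed: int = 0,
) -> tuple[ImageGrid, SegMask]:
    """A single-disk ROI phantom with its analytic ground-truth mask.

    The workhorse fixture for segmentation benchmarks: a centered disk of
    the given radius and additive contrast over a flat background, mild
    Gaussian edge blur, and i.i.d. Gaussian noise.
    """
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    lesion = LesionSpec(
        center=center,
        base_radius=radius,
        intensity_offset=contrast,
        edge_softness=edge_softness,
    )
    mask, layer = render_lesion(lesion, size)
    rng = np.random.default_rng(seed)
    img = background + layer.pixels
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, (size, size))
    return ImageGrid(np.clip(img, 0.0, 1.0)), mask
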