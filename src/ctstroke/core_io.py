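"""Image and dataset I/O, label conventions, and dataset augmentation.

Conventions used throughout the package:

* images are 2-D :class:`numpy.ndarray` of floats on the 8-bit scale
  ``[0, 255]`` (full precision internally, quantized to integers on write);
* pixel coordinates are 0-based in ``(row, col)`` order;
* bounding boxes are half-open, ``[x_min, x_max) × [y_min, y_max)`` in
  column/row pixel indices.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "StrokeStage",
    "BoundingBox",
    "SampleRecord",
    "validate_image",
    "quantize",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "read_manifest",
    "write_manifest",
    "augment",
]


class StrokeStage(str, enum.Enum):
    """The five CT appearance categories: one normal class and four ischemic
    stroke stages ordered by increasing lesion conspicuity."""

    NORMAL = "normal"
    HYPER_ACUTE = "hyper_acute"
    ACUTE = "acute"
    SUB_ACUTE = "sub_acute"
    CHRONIC = "chronic"

    @classmethod
    def parse(cls, text: str) -> "StrokeStage":
        """Map a label string to a stage, case-insensitively, treating
        hyphens and spaces as underscores ("Hyper-Acute" -> HYPER_ACUTE)."""
        key = text.strip().lower().replace("-", "_").replace(" ", "_")
        for stage in cls:
            if stage.value == key:
                return stage
        raise ValueError(f"unknown stroke stage {text!r}")


#: the four lesion-bearing stages, easiest-to-subtlest reversed
STROKE_STAGES = (
    StrokeStage.HYPER_ACUTE,
    StrokeStage.ACUTE,
    StrokeStage.SUB_ACUTE,
    StrokeStage.CHRONIC,
)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box: columns ``[x_min, x_max)``, rows ``[y_min, y_max)``."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_min < self.x_max and 0 <= self.y_min < self.y_max):
            raise ValueError(f"degenerate bounding box {self}")

    @classmethod
    def parse(cls, text: str) -> "BoundingBox":
        """Parse the manifest encoding ``x_min:y_min:x_max:y_max``."""
        parts = text.strip().split(":")
        if len(parts) != 4:
            raise ValueError(f"box must be 'x_min:y_min:x_max:y_max', got {text!r}")
        x0, y0, x1, y1 = (int(p) for p in parts)
        return cls(x0, y0, x1, y1)

    def encode(self) -> str:
        return f"{self.x_min}:{self.y_min}:{self.x_max}:{self.y_max}"

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices selecting the box region of an image array."""
        return slice(self.y_min, self.y_max), slice(self.x_min, self.x_max)


@dataclass
class SampleRecord:
    """One manifest row: an image, its stage label, and optional lesion
    ground truth (mask file and bounding box)."""

    image_path: Path
    stage: StrokeStage
    mask_path: Path | None = None
    box: BoundingBox | None = None

    @property
    def sample_id(self) -> str:
        return Path(self.image_path).stem


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check the grayscale-image invariants and return the array as float64."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image must be a non-empty 2-D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(f"intensities outside [0, 255]: [{arr.min()}, {arr.max()}]")
    return arr


def quantize(image: np.ndarray) -> np.ndarray:
    """Quantize to 8-bit integers: round half away from zero, clip to [0, 255].

    Round-half-away-from-zero (rather than banker's rounding) keeps the
    result independent of platform rounding modes.
    """
    arr = np.asarray(image, dtype=float)
    rounded = np.copysign(np.floor(np.abs(arr) + 0.5), arr)
    return np.clip(rounded, 0, 255).astype(np.uint8)


def load_image(path: str | Path, target_size: tuple[int, int] | None = None) -> np.ndarray:
    """Load a JPEG/PNG file as an 8-bit grayscale image.

    Color inputs are converted with the ITU-R 601 luma weighting
    (0.299 R + 0.587 G + 0.114 B). If ``target_size`` (rows, cols) is given
    the image is bilinearly resampled to that size and requantized.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("L")  # Pillow 'L' is the ITU-R 601 luma transform
            arr = np.asarray(im, dtype=float)
    except (OSError, SyntaxError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if target_size is not None:
        rows, cols = target_size
        if rows < 1 or cols < 1:
            raise ValueError(f"target_size must be positive, got {target_size}")
        arr = _sk_resize(arr, (rows, cols), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        arr = quantize(arr).astype(float)
    return validate_image(arr)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write an image as 8-bit grayscale PNG (the canonical write format;
    JPEG recompression would not round-trip metric values)."""
    arr = quantize(validate_image(image))
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary lesion mask from PNG; any nonzero pixel is lesion."""
    arr = load_image(path)
    return (arr > 0).astype(np.uint8)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    save_image(np.where(mask > 0, 255.0, 0.0), path)


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read a dataset manifest CSV with header ``image,stage[,mask,box]``.

    Relative image/mask paths are resolved against the manifest's directory.
    Row order is preserved.
    """
    path = Path(path)
    records: list[SampleRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "image" not in reader.fieldnames:
            raise ValueError(f"manifest {path} lacks required 'image' column")
        if "stage" not in reader.fieldnames:
            raise ValueError(f"manifest {path} lacks required 'stage' column")
        for i, row in enumerate(reader, start=1):
            try:
                stage = StrokeStage.parse(row["stage"])
            except ValueError as exc:
                raise ValueError(f"manifest {path} row {i}: {exc}") from exc
            mask_text = (row.get("mask") or "").strip()
            box_text = (row.get("box") or "").strip()
            try:
                box = BoundingBox.parse(box_text) if box_text else None
            except ValueError as exc:
                raise ValueError(f"manifest {path} row {i}: {exc}") from exc
            records.append(
                SampleRecord(
                    image_path=path.parent / row["image"],
                    stage=stage,
                    mask_path=path.parent / mask_text if mask_text else None,
                    box=box,
                )
            )
    return records


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write records as a manifest CSV (paths stored relative to the CSV)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["image", "stage", "mask", "box"])
        for rec in records:
            writer.writerow(
                [
                    Path(rec.image_path).name,
                    rec.stage.value,
                    Path(rec.mask_path).name if rec.mask_path else "",
                    rec.box.encode() if rec.box else "",
                ]
            )


def _random_rotate(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import rotate

    angle = rng.uniform(-15.0, 15.0)
    out = rotate(image, angle, reshape=False, order=1, mode="reflect")
    return np.clip(out, 0, 255)


def _random_crop(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    m, n = image.shape
    area_frac = rng.uniform(0.85, 1.0)
    side_frac = float(np.sqrt(area_frac))
    ch = max(1, int(round(m * side_frac)))
    cw = max(1, int(round(n * side_frac)))
    top = int(rng.integers(0, m - ch + 1))
    left = int(rng.integers(0, n - cw + 1))
    crop = image[top : top + ch, left : left + cw]
    out = _sk_resize(crop, (m, n), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0, 255)


def augment(image: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    """Quadruple one image: original, horizontal flip, random rotation in
    [-15°, +15°] with reflective padding, and a random 85–100%-area crop
    resampled back to the original size. Deterministic given ``rng``."""
    image = validate_image(image)
    return [
        image.copy(),
        image[:, ::-1].copy(),
        _random_rotate(image, rng),
        _random_crop(image, rng),
    ]
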