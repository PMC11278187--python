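"""Dice-scored, box-guided lesion segmentation evaluation.

The evaluation harness mirrors a detector→segmenter hand-off (a bounding
box proposed per image, a segmenter that works only inside the box), with
the Dice similarity coefficient (DSC) as the overlap score. A classical
Otsu-threshold reference segmenter makes the harness fully testable
offline; foundation/detection models remain external behind the
:class:`Segmenter` interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ctstroke.core_io import BoundingBox, SampleRecord, StrokeStage, load_image, load_mask, validate_image
from ctstroke.spem import SPEMConfig, spem_enhance

__all__ = ["Segmenter", "DSCResult", "dsc", "otsu_box_segment", "OtsuBoxSegmenter", "evaluate_segmentation"]

logger = logging.getLogger(__name__)

#: 4-connectivity structuring element for connected-component filtering
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class Segmenter:
    """A named mapping (image, box) -> binary mask, empty outside the box."""

    name: str
    segment: Callable[[np.ndarray, BoundingBox], np.ndarray]


@dataclass
class DSCResult:
    """Per-sample Dice values plus per-stage means."""

    per_sample: list[tuple[str, float]]
    per_stage_mean: dict[StrokeStage, float]


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary (0/1)")
    return arr.astype(bool)


def dsc(a: np.ndarray, b: np.ndarray, empty_value: float = 1.0) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|), in [0, 1].

    When both masks are empty the score defaults to 1.0 — correct agreement
    on the absence of a lesion; pass ``empty_value=0.0`` for the strict
    benchmarking convention.
    """
    a = _as_binary(a, "A")
    b = _as_binary(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return empty_value
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def otsu_box_segment(
    image: np.ndarray, box: BoundingBox, polarity: str = "hypodense"
) -> np.ndarray:
    """Reference segmenter: Otsu threshold restricted to the box.

    The threshold is computed from the box pixels only (256 bins), so
    intensities outside the box — skull, background — cannot skew it.
    Pixels on the ``polarity`` side of the threshold (hypodense = below,
    the ischemic CT appearance) are kept, reduced to the largest
    4-connected component. The returned mask is empty outside the box; a
    constant box yields an empty mask.
    """
    image = validate_image(image)
    if polarity not in ("hypodense", "hyperdense"):
        raise ValueError(f"polarity must be 'hypodense' or 'hyperdense', got {polarity!r}")
    m, n = image.shape
    if box.x_max > n or box.y_max > m:
        raise ValueError(f"box {box} exceeds image shape {image.shape}")
    mask = np.zeros(image.shape, dtype=np.uint8)
    crop = image[box.slices()]
    if crop.min() == crop.max():
        logger.warning("degenerate box (single intensity); returning empty mask")
        return mask
    thr = threshold_otsu(crop, nbins=256)
    inside = crop < thr if polarity == "hypodense" else crop > thr
    if not inside.any():
        return mask
    labels, n_comp = ndimage.label(inside, structure=_FOUR_CONN)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = np.argmax(sizes)
    mask[box.slices()] = (labels == largest).astype(np.uint8)
    return mask


def OtsuBoxSegmenter(polarity: str = "hypodense") -> Segmenter:
    """Package the Otsu reference segmenter behind the Segmenter interface."""
    return Segmenter(
        name=f"otsu_box[{polarity}]",
        segment=lambda image, box: otsu_box_segment(image, box, polarity),
    )


def evaluate_segmentation(
    records: Sequence[SampleRecord],
    segmenter: Segmenter,
    enhance: SPEMConfig | None = None,
    images: Sequence[np.ndarray] | None = None,
    masks: Sequence[np.ndarray] | None = None,
) -> DSCResult:
    """Score a segmenter against ground-truth masks, per sample and per stage.

    Every record must carry a mask and a box. With ``enhance`` given, the
    segmenter sees the SPEM-enhanced image instead of the raw one (the
    ground truth is unchanged). ``images``/``masks`` may supply loaded
    arrays to skip file I/O.
    """
    per_sample: list[tuple[str, float]] = []
    by_stage: dict[StrokeStage, list[float]] = {}
    for i, rec in enumerate(records):
        if (masks is None and rec.mask_path is None) or rec.box is None:
            raise ValueError(f"record {rec.sample_id} lacks mask or box; cannot score segmentation")
        img = images[i] if images is not None else load_image(rec.image_path)
        truth = masks[i] if masks is not None else load_mask(rec.mask_path)
        if enhance is not None:
            img, _ = spem_enhance(img, enhance)
        pred = segmenter.segment(img, rec.box)
        score = dsc(pred, truth)
        per_sample.append((rec.sample_id, score))
        by_stage.setdefault(rec.stage, []).append(score)
    per_stage_mean = {stage: float(np.mean(vals)) for stage, vals in by_stage.items()}
    return DSCResult(per_sample=per_sample, per_stage_mean=per_stage_mean)
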