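"""Seeded brain-CT phantom generation with stage-dependent lesions.

Each phantom is a window-rendered-CT-like 8-bit slice: an elliptical bright
skull ring, noisy parenchyma, a symmetric pair of dark ventricles, and —
for the four stroke stages — a hypodense elliptical lesion whose contrast
and boundary sharpness depend on the stage. Hyper-acute lesions are faint
and diffuse (hardest to see), chronic lesions deep and sharp (easiest),
reproducing the clinical conspicuity gradient without claiming anatomical
realism.

The ground-truth mask is the half-peak contour of the *pre-noise* lesion
field, so it is independent of the noise draw; the bounding box is the
tight bounds of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ctstroke.core_io import (
    BoundingBox,
    SampleRecord,
    StrokeStage,
    STROKE_STAGES,
    save_image,
    save_mask,
    write_manifest,
)

__all__ = [
    "StageLesionParams",
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_samples",
    "generate_dataset",
    "brain_window_crop",
]


@dataclass(frozen=True)
class StageLesionParams:
    """Lesion appearance for one stroke stage.

    ``lesion_delta`` is the additive intensity offset realized as the mean
    contrast over the lesion mask (negative: ischemic lesions are
    hypodense), ``boundary_sigma`` the Gaussian blur of the lesion boundary
    in pixels, ``radius_range`` the admissible lesion semi-axis range in
    pixels.
    """

    lesion_delta: float
    boundary_sigma: float
    radius_range: tuple[float, float]


def _default_stage_params(size: int) -> dict[StrokeStage, StageLesionParams]:
    # Contrast deepens and the boundary sharpens from hyper-acute to chronic;
    # radii scale with the slice size (defaults quoted at size 128).
    r = (0.11 * size, 0.17 * size)
    return {
        StrokeStage.HYPER_ACUTE: StageLesionParams(-6.0, 4.0, r),
        StrokeStage.ACUTE: StageLesionParams(-15.0, 3.0, r),
        StrokeStage.SUB_ACUTE: StageLesionParams(-25.0, 2.0, r),
        StrokeStage.CHRONIC: StageLesionParams(-40.0, 1.0, r),
    }


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of the phantom (8-bit scale).

    The 128-pixel default keeps tests desk-scale; 640 mirrors the
    standardized clinical input size.
    """

    size: int = 128
    skull_intensity: float = 230.0
    skull_thickness: int | None = None  # None -> round(size / 24)
    parenchyma_mean: float = 100.0
    parenchyma_noise_sd: float = 8.0
    ventricle_intensity: float = 40.0
    stage_params: dict[StrokeStage, StageLesionParams] | None = None

    def __post_init__(self) -> None:
        if self.skull_thickness is None:
            self.skull_thickness = max(2, round(self.size / 24))
        if self.stage_params is None:
            self.stage_params = _default_stage_params(self.size)


@dataclass
class PhantomSample:
    """One synthetic slice with its label and lesion ground truth."""

    image: np.ndarray
    stage: StrokeStage
    mask: np.ndarray
    box: BoundingBox | None


def _ellipse(shape: tuple[int, int], center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / semi[0]) ** 2 + ((xx - center[1]) / semi[1]) ** 2 <= 1.0


def _geometry(cfg: PhantomConfig):
    s = cfg.size
    c = ((s - 1) / 2.0, (s - 1) / 2.0)
    outer = (0.46 * s, 0.38 * s)
    inner = (outer[0] - cfg.skull_thickness, outer[1] - cfg.skull_thickness)
    # lateral ventricle pair, symmetric under 180° rotation about the center
    vent_off = 0.085 * s
    vent_semi = (0.085 * s, 0.035 * s)
    vents = [
        (c[0], c[1] - vent_off),
        (c[0], c[1] + vent_off),
    ]
    return c, outer, inner, vents, vent_semi


def generate_phantom(
    stage: StrokeStage, cfg: PhantomConfig | None = None, rng: np.random.Generator | None = None
) -> PhantomSample:
    """Generate one phantom slice; deterministic given ``rng``.

    Lesions are placed uniformly at random inside the parenchyma, fully
    within the inner skull ellipse (retried with a 10% smaller radius up to
    10 times before erroring). The skull/parenchyma/ventricle base is
    symmetric under 180° rotation about the image center, so the rotated
    copy of the lesion mask is a matched lesion-free control region.
    """
    cfg = cfg or PhantomConfig()
    rng = rng if rng is not None else np.random.default_rng()
    s = cfg.size
    c, outer, inner, vents, vent_semi = _geometry(cfg)

    base = np.zeros((s, s))
    skull = _ellipse((s, s), c, outer)
    brain = _ellipse((s, s), c, inner)
    base[skull] = cfg.skull_intensity
    base[brain] = cfg.parenchyma_mean
    vent_region = np.zeros((s, s), dtype=bool)
    for vc in vents:
        vent_region |= _ellipse((s, s), vc, vent_semi)
    vent_region &= brain
    base[vent_region] = cfg.ventricle_intensity

    mask = np.zeros((s, s), dtype=np.uint8)
    box: BoundingBox | None = None
    if stage != StrokeStage.NORMAL:
        params = cfg.stage_params[stage]
        # placement margin uses the largest boundary sigma over all stages so
        # every stage draws lesion centers from the same region: difficulty
        # differences come from contrast/sharpness, not placement
        sigma_max = max(p.boundary_sigma for p in cfg.stage_params.values())
        field_map = _lesion_field(cfg, params, c, inner, sigma_max, rng)
        base = base + field_map
        half_peak = 0.5 * np.abs(field_map).max()
        mask = ((np.abs(field_map) >= half_peak) & brain).astype(np.uint8)
        rows, cols = np.nonzero(mask)
        box = BoundingBox(int(cols.min()), int(rows.min()), int(cols.max()) + 1, int(rows.max()) + 1)

    noise = rng.normal(0.0, cfg.parenchyma_noise_sd, size=(s, s))
    image = np.clip(base + noise * brain, 0, 255)
    return PhantomSample(image=image, stage=stage, mask=mask, box=box)


def _lesion_field(cfg, params, c, inner, sigma_max, rng):
    s = cfg.size
    r_lo, r_hi = params.radius_range
    radius = rng.uniform(r_lo, r_hi)
    for _ in range(10):
        semi = (radius * rng.uniform(0.7, 1.0), radius * rng.uniform(0.7, 1.0))
        margin = max(semi) + 2.0 * sigma_max
        cy = c[0] + rng.uniform(-1, 1) * max(inner[0] - margin, 0.0)
        cx = c[1] + rng.uniform(-1, 1) * max(inner[1] - margin, 0.0)
        # fully inside the inner ellipse (conservative: shrink by the margin)
        inside = (
            margin < min(inner)
            and ((cy - c[0]) / (inner[0] - margin)) ** 2 + ((cx - c[1]) / (inner[1] - margin)) ** 2 <= 1.0
        )
        if inside:
            indicator = _ellipse((s, s), (cy, cx), semi).astype(float)
            blurred = ndimage.gaussian_filter(indicator, params.boundary_sigma)
            # normalize so lesion_delta is the realized mean contrast over the
            # half-peak mask, not the (blur-diluted) indicator amplitude
            core = blurred >= 0.5 * blurred.max()
            return blurred * (params.lesion_delta / blurred[core].mean())
        radius *= 0.9
    raise RuntimeError(f"could not place a lesion of radius ~{radius:.1f}px after 10 attempts")


def brain_window_crop(image: np.ndarray, cfg: PhantomConfig | None = None) -> np.ndarray:
    """Central crop lying entirely inside the skull: a low-contrast image.

    A whole-head slice spans the full 0–255 range (air to bone), so global
    contrast metrics are dominated by the skull and background. The
    parenchymal interior — the clinically interesting, low-contrast part —
    is the right input for enhancement-quality measurements on phantoms.
    """
    cfg = cfg or PhantomConfig()
    s = cfg.size
    q = s // 4
    return image[q : s - q, q : s - q].copy()


def generate_samples(
    n_per_class: int,
    cfg: PhantomConfig | None = None,
    seed: int = 0,
    stages: tuple[StrokeStage, ...] = (StrokeStage.NORMAL, *STROKE_STAGES),
) -> list[PhantomSample]:
    """Generate ``n_per_class`` phantoms per stage (one shared seeded
    stream, so the full set is reproducible from the seed alone)."""
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(seed)
    return [generate_phantom(stage, cfg, rng) for stage in stages for _ in range(n_per_class)]


def generate_dataset(
    n_per_class: int,
    cfg: PhantomConfig | None = None,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> Path:
    """Write a phantom dataset as PNGs plus a manifest CSV.

    File naming is ``{stage}_{index:04d}.png`` (mask files with a ``_mask``
    suffix); normal samples carry no mask/box. Returns the manifest path;
    regeneration with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n_per_class, cfg, seed)
    records: list[SampleRecord] = []
    counters: dict[StrokeStage, int] = {}
    for sample in samples:
        idx = counters.get(sample.stage, 0)
        counters[sample.stage] = idx + 1
        stem = f"{sample.stage.value}_{idx:04d}"
        image_path = out_dir / f"{stem}.png"
        save_image(sample.image, image_path)
        mask_path = None
        if sample.stage != StrokeStage.NORMAL:
            mask_path = out_dir / f"{stem}_mask.png"
            save_mask(sample.mask, mask_path)
        records.append(
            SampleRecord(image_path=image_path, stage=sample.stage, mask_path=mask_path, box=sample.box)
        )
    manifest = out_dir / "manifest.csv"
    write_manifest(records, manifest)
    return manifest
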