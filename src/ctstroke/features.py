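"""Pluggable per-image feature extraction.

The classifier consumes fixed-length vectors per image. Two extractors are
provided: a deterministic block-statistics extractor for desk-scale work,
and a file adapter for embeddings computed by an external CNN (e.g. a
DenseNet121 transfer-learning stage run elsewhere), so the full
deep-feature pipeline stays reachable without bundling pretrained weights.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from ctstroke.core_io import SampleRecord, load_image, validate_image
from ctstroke.spem import SPEMConfig, _block_edges, spem_enhance

__all__ = ["FeatureExtractor", "BlockStatExtractor", "EmbeddingFileExtractor", "extract_matrix"]


class FeatureExtractor(Protocol):
    """A named, deterministic mapping from a grayscale image to a fixed
    length-``dim`` real vector."""

    name: str

    @property
    def dim(self) -> int: ...

    def extract(self, image: np.ndarray, sample_id: str | None = None) -> np.ndarray: ...


@dataclass
class BlockStatExtractor:
    """Per-block mean and standard deviation on a fixed grid, plus a global
    normalized intensity histogram.

    The grid partition matches the EME convention (last block absorbs
    remainder pixels); block standard deviation uses the population
    convention (divide by the block pixel count); the histogram is
    normalized to sum to 1 so features are image-size independent.
    dim = 2·g₁·g₂ + hist_bins.
    """

    grid: tuple[int, int] = (8, 8)
    hist_bins: int = 16
    name: str = "block_stats"

    @property
    def dim(self) -> int:
        return 2 * self.grid[0] * self.grid[1] + self.hist_bins

    def extract(self, image: np.ndarray, sample_id: str | None = None) -> np.ndarray:
        image = validate_image(image)
        g1, g2 = self.grid
        means, sds = [], []
        for r0, r1 in _block_edges(image.shape[0], g1):
            for c0, c1 in _block_edges(image.shape[1], g2):
                block = image[r0:r1, c0:c1]
                means.append(block.mean())
                sds.append(block.std())  # population SD
        hist, _ = np.histogram(image, bins=self.hist_bins, range=(0.0, 256.0))
        hist = hist / image.size
        return np.concatenate([means, sds, hist])


class EmbeddingFileExtractor:
    """Adapter for externally computed embeddings.

    Reads a CSV whose first column is a sample id (image path or stem) and
    whose remaining columns are the embedding vector; all vectors must have
    the same length.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.name = f"embedding:{self.path.name}"
        self._table: dict[str, np.ndarray] = {}
        with open(self.path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row:
                    continue
                vec = np.asarray([float(v) for v in row[1:]], dtype=float)
                self._table[row[0]] = vec
                self._table.setdefault(Path(row[0]).stem, vec)
        dims = {v.shape[0] for v in self._table.values()}
        if len(dims) != 1:
            raise ValueError(f"embedding file {self.path} has mixed vector lengths {sorted(dims)}")
        self._dim = dims.pop()

    @property
    def dim(self) -> int:
        return self._dim

    def extract(self, image: np.ndarray, sample_id: str | None = None) -> np.ndarray:
        if sample_id is None:
            raise ValueError("embedding lookup requires a sample id")
        try:
            return self._table[sample_id]
        except KeyError:
            raise KeyError(f"no embedding for sample id {sample_id!r} in {self.path}") from None


def extract_matrix(
    records: Sequence[SampleRecord],
    extractor: FeatureExtractor,
    enhance: SPEMConfig | None = None,
    images: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Stack per-record feature vectors, in record order.

    ``images`` may supply already-loaded arrays (one per record) to skip
    file I/O; otherwise each record's image is loaded from disk. When
    ``enhance`` is given, each image passes through SPEM first.
    """
    rows = []
    for i, rec in enumerate(records):
        img = images[i] if images is not None else load_image(rec.image_path)
        if enhance is not None:
            img, _ = spem_enhance(img, enhance)
        rows.append(extractor.extract(img, sample_id=rec.sample_id))
    return np.vstack(rows)
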