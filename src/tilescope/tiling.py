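"""Tile extraction by pixel density and site-segregated cohort splits.

Whole-slide images are processed as fixed-size tiles.  Tissue-rich tiles
are selected by ranking candidate windows on their pixel density — the
fraction of non-white pixels, where a pixel counts as non-white only when
all three RGB channels are strictly below 200.  Cohorts are split at the
level of tissue source sites so that no site (and hence no patient, and no
scanner/staining batch) contributes tiles to more than one partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SlideRecord",
    "TileCandidate",
    "SplitAssignment",
    "compute_density",
    "select_top_tiles",
    "assign_splits_by_site",
    "site_from_tcga_barcode",
    "WHITE_THRESHOLD",
    "DEFAULT_TILE_SIZE",
    "DEFAULT_TOP_K",
]

WHITE_THRESHOLD = 200
DEFAULT_TILE_SIZE = 224
DEFAULT_TOP_K = 200


@dataclass
class SlideRecord:
    """One slide with its patient, tissue source site and task labels."""

    patient_id: str
    slide_id: str
    site_id: str
    image_path: str | None = None
    magnification: str | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_id or not self.site_id:
            raise ValueError("patient_id and site_id must be non-empty")
        if self.magnification not in (None, "20x", "40x"):
            raise ValueError(f"unsupported magnification {self.magnification!r}")


@dataclass
class TileCandidate:
    """A tile window on a slide: half-open [row, row+T) x [col, col+T)."""

    slide_id: str
    origin: tuple[int, int]
    pixels: np.ndarray
    density: float

    @property
    def window(self) -> tuple[tuple[int, int], tuple[int, int]]:
        t = self.pixels.shape[0]
        r, c = self.origin
        return ((r, r + t), (c, c + t))


@dataclass
class SplitAssignment:
    """Mapping of tissue source sites to disjoint partitions."""

    site_to_partition: dict[str, str]
    realized_fractions: dict[str, float]

    def partition_of(self, site_id: str) -> str:
        return self.site_to_partition[site_id]

    def sites_in(self, partition: str) -> set[str]:
        return {s for s, p in self.site_to_partition.items() if p == partition}


def compute_density(pixels: np.ndarray) -> float:
    """Fraction of pixels whose R, G and B values are all strictly below 200."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[-1] != 3 or pixels.size == 0:
        raise ValueError("expected a non-empty HxWx3 RGB array")
    return float(np.all(pixels < WHITE_THRESHOLD, axis=-1).mean())


def _downsample2(image: np.ndarray) -> np.ndarray:
    """2x block-mean downsample (crop trailing odd row/col)."""
    h, w = image.shape[0] // 2 * 2, image.shape[1] // 2 * 2
    x = image[:h, :w].astype(np.float64)
    x = x.reshape(h // 2, 2, w // 2, 2, -1).mean(axis=(1, 3))
    return x.astype(image.dtype)


def select_top_tiles(
    image: np.ndarray,
    slide_id: str = "slide",
    k: int = DEFAULT_TOP_K,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int | None = None,
    magnification: str | None = None,
) -> list[TileCandidate]:
    """Extract the ``k`` densest tiles from a slide.

    Candidates are enumerated on a regular grid (default stride =
    ``tile_size``, i.e. non-overlapping); windows that do not fit entirely
    inside the slide are discarded.  The result is sorted by density
    descending with ties broken by row-major origin order.  Slides scanned
    at 40x are block-mean downsampled 2x first so tiles cover comparable
    tissue area to 20x.
    """
    if stride is None:
        stride = tile_size
    if stride < 1 or tile_size < 1:
        raise ValueError("tile_size and stride must be positive")
    if magnification == "40x":
        image = _downsample2(image)
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(
            f"slide {h}x{w} smaller than one {tile_size}x{tile_size} tile"
        )

    candidates: list[TileCandidate] = []
    for r in range(0, h - tile_size + 1, stride):
        for c in range(0, w - tile_size + 1, stride):
            window = image[r : r + tile_size, c : c + tile_size]
            candidates.append(
                TileCandidate(
                    slide_id=slide_id,
                    origin=(r, c),
                    pixels=window,
                    density=compute_density(window),
                )
            )
    if len(candidates) < k:
        warnings.warn(
            f"slide {slide_id}: only {len(candidates)} candidate tiles "
            f"(requested top {k})",
            stacklevel=2,
        )
    order = np.argsort([-t.density for t in candidates], kind="stable")
    return [candidates[i] for i in order[:k]]


def site_from_tcga_barcode(barcode: str) -> str:
    """Tissue source site from a TCGA-style barcode (second hyphen field)."""
    parts = barcode.split("-")
    if len(parts) < 2 or not parts[1]:
        raise ValueError(f"cannot parse tissue source site from {barcode!r}")
    return parts[1]


def assign_splits_by_site(
    records: list[SlideRecord],
    fractions: dict[str, float],
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole tissue-source sites to partitions.

    Sites are visited in seeded random order and each is placed in the
    partition with the largest remaining patient-count deficit relative to
    its target fraction (randomized greedy).  No site ever spans
    partitions, so tiles from one site cannot leak between train, test and
    validation.
    """
    if not records:
        raise ValueError("no records to split")
    total = sum(fractions.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"fractions must sum to 1 (got {total})")

    site_patients: dict[str, set[str]] = {}
    patient_site: dict[str, str] = {}
    for rec in records:
        prev = patient_site.setdefault(rec.patient_id, rec.site_id)
        if prev != rec.site_id:
            raise ValueError(
                f"patient {rec.patient_id} mapped to multiple sites"
            )
        site_patients.setdefault(rec.site_id, set()).add(rec.patient_id)

    sites = sorted(site_patients)
    if len(sites) == 1 and len(fractions) > 1:
        warnings.warn(
            "single tissue source site: all patients assigned to one partition",
            stacklevel=2,
        )
        target = max(fractions, key=lambda p: (fractions[p], p))
        return SplitAssignment({sites[0]: target}, {target: 1.0})

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sites))
    n_total = len(patient_site)
    partitions = sorted(fractions)
    assigned_counts = {p: 0 for p in partitions}
    site_to_partition: dict[str, str] = {}
    for idx in order:
        site = sites[idx]
        deficits = {
            p: fractions[p] * n_total - assigned_counts[p] for p in partitions
        }
        best = max(partitions, key=lambda p: (deficits[p], p))
        site_to_partition[site] = best
        assigned_counts[best] += len(site_patients[site])

    realized = {p: assigned_counts[p] / n_total for p in partitions}
    return SplitAssignment(site_to_partition, realized)
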