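"""Synthetic H&E-like slides, cohorts and expression matrices.

The generator emulates the statistical structure the downstream analysis
assumes: hematoxylin-and-eosin appearance (white glass background, pale pink
stroma, large pale tumor-nucleus ellipses, small dark near-circular
lymphocytes), patient cohorts drawn from multiple tissue-source sites, a
class-dependent lymphocyte infiltration rate, and expression matrices in
which class labels are driven jointly by a receptor gene and a correlated
immune gene program.

By default, class-conditional lymphocyte infiltration is the ONLY class
signal present in the images, so experiments that ablate or interpret the
trained classifiers have a known causal pathway back to lymphocyte
morphology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

from .tiling import SlideRecord

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticExpressionConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_expression",
    "render_slide",
    "render_objects",
    "sample_object_table",
    "write_cohort",
    "write_expression",
]

# Base stain colors (RGB).  Lymphocytes are small, round and darkly
# basophilic; tumor nuclei are larger, elliptical and palely stained.  Both
# fall below 200 in every channel so they register as "tissue" under the
# non-white pixel-density rule, while stroma and glass do not.
LYMPH_COLOR = np.array([62.0, 48.0, 122.0])
TUMOR_COLOR = np.array([182.0, 146.0, 192.0])
STROMA_COLOR = np.array([236.0, 208.0, 218.0])
GLASS_COLOR = np.array([252.0, 252.0, 252.0])

LYMPH_RADIUS = (3.0, 6.0)
TUMOR_RADIUS = (8.0, 16.0)


@dataclass
class SyntheticCohortConfig:
    """Parameters of a synthetic slide cohort.

    ``lymph_rate_by_class`` maps each class label to the expected fraction
    of cells that are lymphocytes for patients of that class; per-patient
    fractions are drawn from a Beta distribution centred on the class rate
    (concentration ``lymph_rate_concentration``) so that within-class
    distributions overlap, as real infiltration scores do.
    """

    n_patients: int = 40
    n_sites: int = 4
    slide_size: tuple[int, int] = (896, 896)
    tile_size: int = 224
    class_scheme: str = "binary"
    lymph_rate_by_class: dict[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.30}
    )
    nuclei_density: float = 35.0
    lymph_rate_concentration: float = 50.0
    tissue_margin: float = 0.04
    color_jitter: float = 10.0
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return {"binary": 2, "four_class": 4}[self.class_scheme]

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 1 <= self.n_sites <= self.n_patients:
            raise ValueError("need 1 <= n_sites <= n_patients")
        h, w = self.slide_size
        if h < self.tile_size or w < self.tile_size:
            raise ValueError("slide must be large enough for at least one tile")
        if self.class_scheme not in ("binary", "four_class"):
            raise ValueError(f"unknown class_scheme {self.class_scheme!r}")
        for cls in range(self.n_classes):
            rate = self.lymph_rate_by_class.get(cls)
            if rate is None:
                raise ValueError(f"lymph_rate_by_class missing class {cls}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("lymphocyte rates must lie in [0, 1]")


@dataclass
class SyntheticExpressionConfig:
    """Parameters of a synthetic gene-by-sample expression matrix.

    The receptor gene shifts by ``effect_size`` (in units of ``noise_sd``)
    between the two classes.  ``n_immune_genes`` further genes form an
    immune program: each shifts by the same effect size and shares a latent
    per-sample factor (``immune_correlation``), mimicking co-regulated
    immune-infiltration transcription.  All remaining genes are pure noise.
    """

    n_samples: int = 300
    n_genes: int = 2000
    receptor_gene_name: str = "ESR1"
    n_immune_genes: int = 19
    effect_size: float = 1.5
    noise_sd: float = 1.0
    immune_correlation: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_genes < 2:
            raise ValueError("need at least 2 samples and 2 genes")
        if self.n_immune_genes >= self.n_genes:
            raise ValueError("n_immune_genes must be smaller than n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.immune_correlation < 1.0:
            raise ValueError("immune_correlation must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Per-slide masks and per-patient truth for a generated cohort.

    ``lymph_masks``/``nuclei_masks`` map slide_id to boolean arrays aligned
    pixel-exact with the rendered slides; the nuclei mask is the union of
    ALL rendered objects, so the lymphocyte mask is always a subset of it.
    ``objects`` is one table for the whole cohort with object-level truth
    (slide, centroid, type, radii).
    """

    lymph_masks: dict[str, np.ndarray]
    nuclei_masks: dict[str, np.ndarray]
    lymph_fraction: dict[str, float]
    class_label: dict[str, int]
    objects: pd.DataFrame


def _sample_positions_in_mask(
    rng: np.random.Generator,
    mask: np.ndarray,
    n: int,
    margin: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample ``n`` uniform positions inside a boolean mask."""
    h, w = mask.shape
    rows = np.empty(0)
    cols = np.empty(0)
    while len(rows) < n:
        need = max(2 * (n - len(rows)), 16)
        r = rng.uniform(margin, h - margin, size=need)
        c = rng.uniform(margin, w - margin, size=need)
        ok = mask[r.astype(int), c.astype(int)]
        rows = np.concatenate([rows, r[ok]])
        cols = np.concatenate([cols, c[ok]])
    return rows[:n], cols[:n]


def sample_object_table(
    rng: np.random.Generator,
    rows: np.ndarray,
    cols: np.ndarray,
    lymph_fraction: float,
) -> pd.DataFrame:
    """Draw cell types and geometry for given positions."""
    n_cells = len(rows)
    is_lymph = rng.random(n_cells) < lymph_fraction
    r_major = np.where(
        is_lymph,
        rng.uniform(*LYMPH_RADIUS, size=n_cells),
        rng.uniform(*TUMOR_RADIUS, size=n_cells),
    )
    r_minor = np.where(
        is_lymph, r_major, rng.uniform(*TUMOR_RADIUS, size=n_cells)
    )
    orient = rng.uniform(0, np.pi, size=n_cells)
    return pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "cell_type": np.where(is_lymph, "lymphocyte", "tumor_nucleus"),
            "r_major": r_major,
            "r_minor": r_minor,
            "orientation": orient,
        }
    )


def render_objects(
    canvas: np.ndarray,
    objects: pd.DataFrame,
    rng: np.random.Generator,
    color_jitter: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint cells onto ``canvas`` in place; return (lymph_mask, nuclei_mask).

    Tumor nuclei are painted first and lymphocytes on top, so every
    lymphocyte-mask pixel belongs to a rendered lymphocyte disc even where
    objects overlap.
    """
    shape = canvas.shape[:2]
    lymph_mask = np.zeros(shape, dtype=bool)
    nuclei_mask = np.zeros(shape, dtype=bool)
    is_lymph = (objects["cell_type"].to_numpy() == "lymphocyte")
    rows = objects["row"].to_numpy()
    cols = objects["col"].to_numpy()
    r_major = objects["r_major"].to_numpy()
    r_minor = objects["r_minor"].to_numpy()
    orient = objects["orientation"].to_numpy()
    order = np.argsort(is_lymph, kind="stable")
    for idx in order:
        jitter = rng.uniform(-color_jitter, color_jitter, size=3)
        if is_lymph[idx]:
            rr, cc = disk((rows[idx], cols[idx]), r_major[idx], shape=shape)
            color = LYMPH_COLOR + jitter
        else:
            rr, cc = ellipse(
                rows[idx], cols[idx], r_major[idx], r_minor[idx],
                shape=shape, rotation=orient[idx],
            )
            color = TUMOR_COLOR + jitter
        canvas[rr, cc] = np.clip(color, 0, 199)
        nuclei_mask[rr, cc] = True
        if is_lymph[idx]:
            lymph_mask[rr, cc] = True
    return lymph_mask, nuclei_mask


def _tissue_mask(shape: tuple[int, int], margin_frac: float) -> np.ndarray:
    """Elliptical tissue section inscribed in the slide minus a glass margin."""
    h, w = shape
    mr, mc = margin_frac * h, margin_frac * w
    rr, cc = np.ogrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = h / 2.0 - mr, w / 2.0 - mc
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def render_slide(
    config: SyntheticCohortConfig,
    lymph_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one slide; return (image, lymph_mask, nuclei_mask, objects)."""
    h, w = config.slide_size
    tissue = _tissue_mask((h, w), config.tissue_margin)

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = GLASS_COLOR + rng.uniform(-2, 2, size=(h, w, 3))
    stroma = STROMA_COLOR + rng.uniform(-4, 4, size=(h, w, 3))
    image[tissue] = stroma[tissue]
    # keep background and stroma in the "white" regime (all channels >= 200)
    np.clip(image, 200, 255, out=image)

    tissue_area = float(tissue.sum())
    mean_cells = config.nuclei_density * tissue_area / config.tile_size**2
    n_cells = int(rng.poisson(mean_cells))
    rows, cols = _sample_positions_in_mask(
        rng, tissue, n_cells, margin=int(TUMOR_RADIUS[1])
    )
    objects = sample_object_table(rng, rows, cols, lymph_fraction)

    lymph_mask, nuclei_mask = render_objects(
        image, objects, rng, config.color_jitter
    )
    return image.astype(np.uint8), lymph_mask, nuclei_mask, objects


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[SlideRecord], list[np.ndarray], GroundTruth]:
    """Generate a reproducible multi-site cohort of synthetic slides.

    Classes are interleaved across patients and sites so that every site
    contains a balanced mix of classes; a site-segregated split therefore
    preserves class balance.  One slide per patient.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_classes = config.n_classes
    conc = config.lymph_rate_concentration

    records: list[SlideRecord] = []
    images: list[np.ndarray] = []
    lymph_masks: dict[str, np.ndarray] = {}
    nuclei_masks: dict[str, np.ndarray] = {}
    fractions: dict[str, float] = {}
    class_label: dict[str, int] = {}
    object_frames: list[pd.DataFrame] = []

    for i in range(config.n_patients):
        cls = i % n_classes
        site = (i // n_classes) % config.n_sites
        patient_id = f"P{i:04d}"
        slide_id = f"{patient_id}-S1"
        rate = config.lymph_rate_by_class[cls]
        if 0.0 < rate < 1.0:
            a, b = rate * conc, (1.0 - rate) * conc
            frac = float(rng.beta(a, b))
        else:
            frac = float(rate)

        image, lmask, nmask, objects = render_slide(config, frac, rng)
        records.append(
            SlideRecord(
                patient_id=patient_id,
                slide_id=slide_id,
                site_id=f"SITE{site:02d}",
                image_path=None,
                labels={"class": cls},
            )
        )
        images.append(image)
        lymph_masks[slide_id] = lmask
        nuclei_masks[slide_id] = nmask
        n_obj = len(objects)
        realized = (
            float((objects["cell_type"] == "lymphocyte").mean()) if n_obj else frac
        )
        fractions[patient_id] = realized
        class_label[patient_id] = cls
        objects = objects.assign(slide_id=slide_id, patient_id=patient_id)
        object_frames.append(objects)

    truth = GroundTruth(
        lymph_masks=lymph_masks,
        nuclei_masks=nuclei_masks,
        lymph_fraction=fractions,
        class_label=class_label,
        objects=pd.concat(object_frames, ignore_index=True),
    )
    return records, images, truth


def generate_expression(
    config: SyntheticExpressionConfig,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Generate an expression matrix (genes x samples), labels and truth.

    Returns the matrix on a z-like scale (mean 0, sd ``noise_sd`` within
    class), balanced 0/1 labels, and the list of truly informative genes
    (receptor gene first, then the immune program).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    labels = np.zeros(n, dtype=int)
    labels[n // 2 :] = 1
    perm = rng.permutation(n)
    labels = labels[perm]

    gene_names = [f"G{i:05d}" for i in range(g)]
    gene_names[0] = config.receptor_gene_name
    immune_genes = [f"IMM{i:03d}" for i in range(config.n_immune_genes)]
    for j, name in enumerate(immune_genes, start=1):
        gene_names[j] = name

    x = rng.normal(0.0, config.noise_sd, size=(g, n))
    delta = config.effect_size * config.noise_sd
    # receptor gene: clean class shift
    x[0] += delta * labels
    # immune program: shared latent factor + class shift, marginal sd preserved
    rho = config.immune_correlation
    latent = rng.normal(0.0, 1.0, size=n)
    k = config.n_immune_genes
    if k:
        eps = rng.normal(0.0, 1.0, size=(k, n))
        x[1 : k + 1] = config.noise_sd * (
            rho * latent + np.sqrt(1.0 - rho**2) * eps
        ) + delta * labels

    matrix = pd.DataFrame(x, index=gene_names, columns=[f"S{i:04d}" for i in range(n)])
    label_series = pd.Series(labels, index=matrix.columns, name="label")
    informative = (
        [config.receptor_gene_name] + immune_genes if config.effect_size > 0 else []
    )
    return matrix, label_series, informative


def write_cohort(
    out_dir: str | Path,
    records: list[SlideRecord],
    images: list[np.ndarray],
    truth: GroundTruth,
) -> Path:
    """Write slides (PNG), masks (PNG), manifest (CSV) and truth (JSON)."""
    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    rows = []
    for rec, image in zip(records, images):
        slide_path = out / "slides" / f"{rec.slide_id}.png"
        iio.imwrite(slide_path, image)
        iio.imwrite(
            out / "masks" / f"{rec.slide_id}_lymph.png",
            truth.lymph_masks[rec.slide_id].astype(np.uint8) * 255,
        )
        iio.imwrite(
            out / "masks" / f"{rec.slide_id}_nuclei.png",
            truth.nuclei_masks[rec.slide_id].astype(np.uint8) * 255,
        )
        rec.image_path = str(slide_path)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "slide_id": rec.slide_id,
                "site_id": rec.site_id,
                "slide_path": str(slide_path),
                **{f"label_{k}": v for k, v in rec.labels.items()},
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "lymph_fraction": truth.lymph_fraction,
                "class_label": truth.class_label,
            },
            fh,
            indent=2,
        )
    truth.objects.to_csv(out / "objects.csv", index=False)
    return out


def write_expression(
    out_dir: str | Path,
    matrix: pd.DataFrame,
    labels: pd.Series,
    informative: list[str],
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "expression.tsv", sep="\t")
    labels.to_csv(out / "labels.tsv", sep="\t")
    (out / "informative_genes.txt").write_text("\n".join(informative) + "\n")
    return out
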