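"""End-to-end orchestration of the image and lymphocyte analyses.

Wires the synthetic generator, tiling, site-segregated splitting, CNN
training, patient-level aggregation and lymphocyte scoring into single
calls used by the worked examples and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aggregation, lymphocyte, synthetic, tiling
from .classifier import TaskSpec, TrainConfig, train_tile_classifier
from .synthetic import SyntheticCohortConfig
from .tiling import SlideRecord

__all__ = [
    "TiledCohort",
    "build_tiled_cohort",
    "run_image_classification",
    "run_lymphocyte_scoring",
    "tile_truth_objects",
]


@dataclass
class TiledCohort:
    """Tiles of a generated cohort with weak labels and split assignment."""

    records: list[SlideRecord]
    truth: synthetic.GroundTruth
    tiles: np.ndarray                # (n_tiles, T, T, 3) uint8
    tile_table: pd.DataFrame         # patient_id, slide_id, site_id, label,
                                     # partition, origin_row, origin_col, density
    split: tiling.SplitAssignment

    def subset(self, partition: str) -> tuple[np.ndarray, pd.DataFrame]:
        mask = (self.tile_table["partition"] == partition).to_numpy()
        return self.tiles[mask], self.tile_table[mask].reset_index(drop=True)


def build_tiled_cohort(
    config: SyntheticCohortConfig,
    tiles_per_patient: int = 50,
    fractions: dict[str, float] | None = None,
    split_seed: int = 0,
    keep_images: bool = False,
) -> TiledCohort:
    """Generate a cohort, extract top-density tiles and split it by site.

    Tiles inherit their slide's class label (weak supervision).  Slide
    images are dropped after tiling unless ``keep_images``; masks stay in
    the returned ground truth.
    """
    if fractions is None:
        fractions = {"train": 0.5, "test": 0.5}
    records, images, truth = synthetic.generate_cohort(config)
    split = tiling.assign_splits_by_site(records, fractions, seed=split_seed)

    all_tiles, rows = [], []
    for rec, image in zip(records, images):
        selected = tiling.select_top_tiles(
            image, slide_id=rec.slide_id, k=tiles_per_patient,
            tile_size=config.tile_size,
        )
        for cand in selected:
            all_tiles.append(cand.pixels)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "slide_id": rec.slide_id,
                    "site_id": rec.site_id,
                    "label": rec.labels["class"],
                    "partition": split.partition_of(rec.site_id),
                    "origin_row": cand.origin[0],
                    "origin_col": cand.origin[1],
                    "density": cand.density,
                }
            )
    cohort = TiledCohort(
        records=records,
        truth=truth,
        tiles=np.stack(all_tiles),
        tile_table=pd.DataFrame(rows),
        split=split,
    )
    if keep_images:
        cohort.images = images  # type: ignore[attr-defined]
    return cohort


def run_image_classification(
    cohort: TiledCohort,
    train_config: TrainConfig,
    train_partition: str = "train",
    eval_partition: str = "test",
    task: TaskSpec | None = None,
):
    """Train the tile CNN on one partition and evaluate patient-level AUC
    on another.

    Returns a dict with the model, training history, per-patient
    aggregated predictions (range voting) and the patient-level AUC of the
    positive-class probability.
    """
    if task is None:
        classes = sorted(cohort.tile_table["label"].unique())
        task = TaskSpec("class", list(classes), label_source="class")
    x_tr, t_tr = cohort.subset(train_partition)
    x_ev, t_ev = cohort.subset(eval_partition)
    model, history = train_tile_classifier(
        x_tr, t_tr["label"].to_numpy(), task, train_config
    )
    probs = model.predict_proba(x_ev)
    classes = list(task.classes)
    df = pd.DataFrame(probs, columns=classes)
    df["patient_id"] = t_ev["patient_id"].to_numpy()
    patient = aggregation.aggregate_cohort(df, classes, method="range_voting")
    labels = t_ev.groupby("patient_id", sort=True)["label"].first()
    patient = patient.merge(labels.rename("label"), on="patient_id")
    auc = aggregation.compute_auc(
        patient[classes[-1]].to_numpy(), patient["label"].to_numpy()
    )
    return {
        "model": model,
        "history": history,
        "task": task,
        "patient_predictions": patient,
        "patient_auc": auc,
    }


def tile_truth_objects(
    truth: synthetic.GroundTruth,
    slide_id: str,
    origin: tuple[int, int],
    tile_size: int,
) -> pd.DataFrame:
    """Ground-truth cells falling inside one tile, in tile coordinates."""
    obj = truth.objects[truth.objects["slide_id"] == slide_id]
    r0, c0 = origin
    inside = (
        (obj["row"] >= r0) & (obj["row"] < r0 + tile_size)
        & (obj["col"] >= c0) & (obj["col"] < c0 + tile_size)
    )
    out = obj[inside].copy()
    out["row"] -= r0
    out["col"] -= c0
    return out


def run_lymphocyte_scoring(
    cohort: TiledCohort,
    seed: int = 0,
    n_training_tiles: int = 40,
) -> dict:
    """Detect cells, train the lymphocyte forest on generator truth and
    score every patient.

    Object-level training labels come from matching detected objects to
    ground-truth centroids on a subset of tiles.  Returns the forest, its
    held-out balanced accuracy and a per-patient score table joined with
    the ground-truth infiltration fraction.
    """
    table = cohort.tile_table
    inventories = [lymphocyte.detect_cells(t) for t in cohort.tiles]

    rng = np.random.default_rng(seed)
    train_idx = rng.choice(
        len(inventories), size=min(n_training_tiles, len(inventories)),
        replace=False,
    )
    frames = []
    for i in train_idx:
        inv = inventories[i]
        if inv.n_objects == 0:
            continue
        row = table.iloc[i]
        truth_obj = tile_truth_objects(
            cohort.truth, row["slide_id"],
            (row["origin_row"], row["origin_col"]),
            cohort.tiles.shape[1],
        )
        labels = lymphocyte.label_objects_by_truth(inv, truth_obj)
        frames.append(inv.features.assign(cell_type=labels))
    training = pd.concat(frames, ignore_index=True)
    forest, bal_acc = lymphocyte.train_lymphocyte_classifier(training, seed=seed)

    for inv in inventories:
        lymphocyte.call_objects(inv, forest)

    rows = []
    for patient, block in table.groupby("patient_id", sort=True):
        invs = [inventories[i] for i in block.index]
        score = lymphocyte.infiltration_score(patient, invs)
        rows.append(
            {
                "patient_id": patient,
                "score": score.score,
                "n_tiles": score.n_tiles,
                "true_fraction": cohort.truth.lymph_fraction[patient],
                "label": cohort.truth.class_label[patient],
            }
        )
    return {
        "forest": forest,
        "balanced_accuracy": bal_acc,
        "scores": pd.DataFrame(rows),
        "inventories": inventories,
    }
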