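"""First-layer filter interpretability: colocalization and ablation.

The first convolutional layer is the only one whose activations retain
near-pixel resolution, so interpretation focuses there.  Each filter's
post-ReLU activation map is thresholded into a binary mask, upsampled to
tile resolution, and Pearson-correlated against the lymphocyte-only mask
and the non-specific (all-)nuclei mask.  A filter preferentially
colocalizes with lymphocytes on a tile when its correlation magnitude with
the lymphocyte mask exceeds that with the nuclei mask; the fraction of
tiles where that holds ranks the filters.  Filter ablation zeroes one
first-layer kernel (and its bias) and re-measures patient-level accuracy
to attribute predictive signal to that filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .aggregation import aggregate_cohort
from .classifier import TileClassifier

__all__ = [
    "ActivationMap",
    "ColocalizationProfile",
    "first_layer_activations",
    "threshold_activation",
    "colocalization_profile",
    "ablate_filter",
    "ablate_filter_and_eval",
]


@dataclass
class ActivationMap:
    filter_index: int
    grid: np.ndarray
    tile_ref: int | str | None = None


@dataclass
class ColocalizationProfile:
    filter_index: int
    per_tile: pd.DataFrame            # columns: tile, r_lymph, r_nuclei
    preferential_fraction: float
    mean_r_lymph: float
    mean_r_nuclei: float
    pooled_r_lymph: float = float("nan")
    pooled_r_nuclei: float = float("nan")
    n_skipped: int = 0


def first_layer_activations(
    model: TileClassifier, tile: np.ndarray
) -> list[ActivationMap]:
    """Post-ReLU activation maps of every first-layer filter for one tile.

    The tile goes through the model's own preprocessing, so the maps live
    on the first layer's spatial grid (valid convolution of the
    preprocessed input).
    """
    conv = model.first_conv  # raises if the model has no conv layer
    x = model.preprocess(tile)
    act = conv.forward(x, train=False)[0]
    act = np.maximum(act, 0.0)
    return [
        ActivationMap(filter_index=f, grid=np.ascontiguousarray(act[..., f]))
        for f in range(act.shape[-1])
    ]


def threshold_activation(
    amap: ActivationMap | np.ndarray,
    tile_shape: tuple[int, int],
    method: str = "top_decile",
) -> tuple[np.ndarray, bool]:
    """Binarize an activation map and upsample to tile resolution.

    ``top_decile`` keeps the top 10% of |activation| values; ``otsu`` uses
    Otsu's threshold on |activation|.  A constant map has no meaningful
    threshold: the mask comes back empty with the degenerate flag set.
    Upsampling is nearest-neighbor so mask blocks align with the filter's
    receptive-field grid.
    """
    grid = amap.grid if isinstance(amap, ActivationMap) else np.asarray(amap)
    if not np.all(np.isfinite(grid)):
        raise ValueError("activation grid contains non-finite values")
    mag = np.abs(grid)
    if np.ptp(mag) == 0:
        return np.zeros(tile_shape, dtype=bool), True
    if method == "top_decile":
        thr = np.quantile(mag, 0.9)
        mask = mag >= thr
        if mask.all():
            # >=90% of the map ties at the minimum (sparse detector):
            # keep only strictly supra-threshold responses
            mask = mag > thr
    elif method == "otsu":
        mask = mag > threshold_otsu(mag)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    up = resize(
        mask.astype(float), tile_shape, order=0, anti_aliasing=False,
        preserve_range=True,
    )
    return up > 0.5, False


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between two flattened binary masks; NaN if degenerate."""
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def colocalization_profile(
    model: TileClassifier,
    tiles: np.ndarray,
    lymph_masks: list[np.ndarray],
    nuclei_masks: list[np.ndarray],
    threshold_method: str = "top_decile",
    comparison: str = "magnitude",
) -> list[ColocalizationProfile]:
    """Colocalize every first-layer filter with lymphocyte and nuclei masks.

    For each filter and tile, the thresholded activation mask is
    Pearson-correlated with both reference masks over all tile pixels.
    ``preferential_fraction`` is the fraction of usable tiles where the
    filter tracks lymphocytes more strongly than nuclei — by default
    comparing correlation magnitudes (|r_lymph| > |r_nuclei|), optionally
    signed (``comparison='signed'``).  Tiles where either correlation is
    undefined (zero-variance mask) are skipped and counted.  Profiles are
    returned ranked by preferential fraction, and also carry pooled
    correlations computed over all tiles' concatenated pixels.
    """
    if not (len(tiles) == len(lymph_masks) == len(nuclei_masks)):
        raise ValueError("tiles and masks must be aligned")
    if comparison not in ("magnitude", "signed"):
        raise ValueError(f"unknown comparison {comparison!r}")

    n_filters = model.first_conv.W.shape[-1]
    records: dict[int, list] = {f: [] for f in range(n_filters)}
    skipped = dict.fromkeys(range(n_filters), 0)
    pooled_act: dict[int, list] = {f: [] for f in range(n_filters)}
    pooled_lymph: list[np.ndarray] = []
    pooled_nuclei: list[np.ndarray] = []

    for t, tile in enumerate(tiles):
        tile_shape = np.asarray(tile).shape[:2]
        lymph = np.asarray(lymph_masks[t], dtype=bool)
        nuc = np.asarray(nuclei_masks[t], dtype=bool)
        pooled_lymph.append(lymph.ravel())
        pooled_nuclei.append(nuc.ravel())
        for amap in first_layer_activations(model, tile):
            mask, degenerate = threshold_activation(
                amap, tile_shape, threshold_method
            )
            pooled_act[amap.filter_index].append(mask.ravel())
            if degenerate:
                skipped[amap.filter_index] += 1
                continue
            r_l = _pearson(mask, lymph)
            r_n = _pearson(mask, nuc)
            if np.isnan(r_l) or np.isnan(r_n):
                skipped[amap.filter_index] += 1
                continue
            records[amap.filter_index].append((t, r_l, r_n))

    lymph_all = np.concatenate(pooled_lymph)
    nuc_all = np.concatenate(pooled_nuclei)
    profiles = []
    for f in range(n_filters):
        per_tile = pd.DataFrame(
            records[f], columns=["tile", "r_lymph", "r_nuclei"]
        )
        if len(per_tile):
            if comparison == "magnitude":
                wins = per_tile["r_lymph"].abs() > per_tile["r_nuclei"].abs()
            else:
                wins = per_tile["r_lymph"] > per_tile["r_nuclei"]
            frac = float(wins.mean())
            mean_l = float(per_tile["r_lymph"].mean())
            mean_n = float(per_tile["r_nuclei"].mean())
        else:
            frac, mean_l, mean_n = 0.0, float("nan"), float("nan")
        act_all = np.concatenate(pooled_act[f])
        profiles.append(
            ColocalizationProfile(
                filter_index=f,
                per_tile=per_tile,
                preferential_fraction=frac,
                mean_r_lymph=mean_l,
                mean_r_nuclei=mean_n,
                pooled_r_lymph=_pearson(act_all, lymph_all),
                pooled_r_nuclei=_pearson(act_all, nuc_all),
                n_skipped=skipped[f],
            )
        )
    profiles.sort(key=lambda p: -p.preferential_fraction)
    return profiles


def ablate_filter(model: TileClassifier, filter_index: int) -> TileClassifier:
    """Return a copy of the model with one first-layer filter zeroed out."""
    conv = model.first_conv
    if not 0 <= filter_index < conv.W.shape[-1]:
        raise IndexError(f"filter index {filter_index} out of range")
    ablated = model.copy()
    conv_a = ablated.first_conv
    conv_a.W[..., filter_index] = 0.0
    conv_a.b[filter_index] = 0.0
    return ablated


def _patient_accuracy(
    model: TileClassifier,
    tiles: np.ndarray,
    labels,
    patient_ids,
) -> float:
    probs = model.predict_proba(tiles)
    classes = list(model.task.classes)
    df = pd.DataFrame(probs, columns=classes)
    df["patient_id"] = np.asarray(patient_ids)
    df["label"] = np.asarray(labels)
    agg = aggregate_cohort(df, classes, method="range_voting")
    patient_label = df.groupby("patient_id", sort=True)["label"].first()
    pred = agg[classes].to_numpy().argmax(axis=1)
    true = np.array([classes.index(l) for l in patient_label.to_numpy()])
    return float((pred == true).mean())


def ablate_filter_and_eval(
    model: TileClassifier,
    filter_index: int,
    tiles: np.ndarray,
    labels,
    patient_ids,
) -> tuple[TileClassifier, float, float]:
    """Zero one first-layer filter and re-measure patient-level accuracy.

    Returns (ablated model, accuracy before, accuracy after); all other
    weights are untouched.
    """
    before = _patient_accuracy(model, tiles, labels, patient_ids)
    ablated = ablate_filter(model, filter_index)
    after = _patient_accuracy(ablated, tiles, labels, patient_ids)
    return ablated, before, after
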