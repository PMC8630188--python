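"""Weakly supervised tile classifiers.

Tiles inherit the label of their parent slide (weak supervision) and a CNN
is trained at the tile level; patient-level calls are produced downstream
by vote aggregation.  Training uses class-weighted softmax cross-entropy,
dropout, decoupled weight decay and random rotation / shift / zoom /
reflection augmentation.

Architectures are pluggable through a registry.  The bundled ``small_cnn``
is a compact three-block numpy CNN whose first layer has 8 filters of 5x5,
large enough that first-layer kernels are interpretable spatial detectors
for the colocalization analysis.  Heavier architectures (e.g. large
transfer-learned backbones) can be registered by the user; every training,
aggregation and interpretability routine only relies on the small model
surface defined here.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp

from . import nn

__all__ = [
    "TaskSpec",
    "TrainConfig",
    "AugmentConfig",
    "TileClassifier",
    "augment_tile",
    "build_model",
    "train_tile_classifier",
    "predict_tiles",
    "fine_tune",
    "register_architecture",
    "TASKS",
]

TASKS = {
    "tumor_normal": ["normal", "tumor"],
    "subtype": ["ductal", "lobular"],
    "ER": ["negative", "positive"],
    "PR": ["negative", "positive"],
    "HER2": ["negative", "positive"],
    "PAM50": ["LuminalA", "LuminalB", "Basal", "HER2E"],
    "TP53": ["wildtype", "mutant"],
}


@dataclass
class TaskSpec:
    """A classification task: ordered class list and manifest label column."""

    name: str
    classes: list
    label_source: str = "class"

    def __post_init__(self) -> None:
        expected = 4 if self.name == "PAM50" else 2
        if self.name in TASKS and len(self.classes) != expected:
            raise ValueError(f"task {self.name} requires {expected} classes")
        if len(self.classes) not in (2, 4):
            raise ValueError("tasks have 2 or 4 classes")

    @classmethod
    def standard(cls, name: str, label_source: str | None = None) -> "TaskSpec":
        return cls(name, list(TASKS[name]), label_source or name)


@dataclass
class AugmentConfig:
    """Random augmentation magnitudes; all zero + no reflection = identity."""

    max_rotation: float = 15.0     # degrees
    max_shift: float = 0.05        # fraction of tile size
    max_zoom: float = 0.05         # fractional zoom about the center
    allow_reflection: bool = True
    fill: float = 255.0            # exposed borders filled slide-white

    def __post_init__(self) -> None:
        if min(self.max_rotation, self.max_shift, self.max_zoom) < 0:
            raise ValueError("augmentation magnitudes must be nonnegative")

    @property
    def is_identity(self) -> bool:
        return (
            self.max_rotation == 0
            and self.max_shift == 0
            and self.max_zoom == 0
            and not self.allow_reflection
        )


@dataclass
class TrainConfig:
    architecture: str = "small_cnn"
    epochs: int = 6
    batch_size: int = 32
    learning_rate: float = 2e-3
    dropout: float = 0.2
    weight_decay: float = 1e-4
    n_filters: int = 8
    kernel_size: int = 5
    input_downscale: int = 4
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.kernel_size < 5 or self.n_filters < 8:
            raise ValueError("first layer needs >=8 filters of >=5x5")


def _draw_params(config: AugmentConfig, rng: np.random.Generator) -> dict:
    return {
        "rotation": rng.uniform(-config.max_rotation, config.max_rotation),
        "shift": rng.uniform(-config.max_shift, config.max_shift, size=2),
        "zoom": 1.0 + rng.uniform(-config.max_zoom, config.max_zoom),
        "reflect": bool(config.allow_reflection and rng.random() < 0.5),
    }


def _apply_params(pixels: np.ndarray, params: dict, fill: float) -> np.ndarray:
    out = pixels.astype(np.float64)
    if params["reflect"]:
        out = out[:, ::-1]
    h, w = out.shape[:2]
    if params["rotation"] == 0 and params["zoom"] == 1.0 and not np.any(params["shift"]):
        return out
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    shift_px = params["shift"] * np.array([w, h])
    tform = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=np.deg2rad(params["rotation"]), scale=params["zoom"])
        + AffineTransform(translation=center + shift_px)
    )
    return warp(out, tform.inverse, order=1, cval=fill, preserve_range=True)


def augment_tile(
    pixels: np.ndarray,
    config: AugmentConfig,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Randomly rotate, shift, zoom and reflect one tile.

    Transform magnitudes are drawn uniformly within ``config``'s ranges
    from ``seed``.  Output has the same shape, dtype and value range as the
    input; borders exposed by the transform are filled with ``config.fill``.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    pixels = np.asarray(pixels)
    params = _draw_params(config, rng)
    if (
        params["rotation"] == 0
        and params["zoom"] == 1.0
        and not np.any(params["shift"])
        and not params["reflect"]
    ):
        return pixels.copy()
    out = _apply_params(pixels, params, config.fill)
    if np.issubdtype(pixels.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255)
    return out.astype(pixels.dtype)


# ---------------------------------------------------------------------------
# architectures

_ARCHITECTURES: dict = {}


def register_architecture(name: str, builder) -> None:
    """Register ``builder(input_shape, n_classes, config, rng) -> Sequential``."""
    _ARCHITECTURES[name] = builder


def _build_small_cnn(input_shape, n_classes, config: TrainConfig, rng):
    h, w, c = input_shape
    layers = [
        nn.Conv2D(c, config.n_filters, config.kernel_size, rng),
        nn.ReLU(),
        nn.MaxPool2(),
        nn.Conv2D(config.n_filters, 2 * config.n_filters, 3, rng),
        nn.ReLU(),
        nn.MaxPool2(),
        nn.Conv2D(2 * config.n_filters, 4 * config.n_filters, 3, rng),
        nn.ReLU(),
        nn.GlobalAvgPool(),
        nn.Dropout(config.dropout, rng),
        nn.Dense(4 * config.n_filters, n_classes, rng),
    ]
    return nn.Sequential(layers)


register_architecture("small_cnn", _build_small_cnn)


class TileClassifier:
    """A trained tile-level classifier emitting per-class probabilities."""

    def __init__(self, net: nn.Sequential, task: TaskSpec, config: TrainConfig):
        self.net = net
        self.task = task
        self.config = config

    # -- input handling ----------------------------------------------------
    def preprocess(self, tiles: np.ndarray) -> np.ndarray:
        """uint8 (N,H,W,3) -> float32 stain darkness, block-mean downscaled.

        Intensities are complemented (darkness = 1 - value/255) so the
        white slide background maps to ~0 and stained nuclei to sparse
        positive responses — the regime convolutional detectors learn
        fastest in.
        """
        x = np.asarray(tiles)
        if x.ndim == 3:
            x = x[None]
        d = self.config.input_downscale
        n, h, w, c = x.shape
        if d > 1:
            if h % d or w % d:
                raise ValueError(f"tile size {h}x{w} not divisible by downscale {d}")
            x = x.reshape(n, h // d, d, w // d, d, c).mean(axis=(2, 4))
        return (1.0 - x / 255.0).astype(np.float32)

    @property
    def first_conv(self) -> nn.Conv2D:
        for layer in self.net.layers:
            if isinstance(layer, nn.Conv2D):
                return layer
        raise ValueError("model has no convolutional layer")

    # -- inference ---------------------------------------------------------
    def predict_proba(self, tiles: np.ndarray, batch_size: int = 128) -> np.ndarray:
        x = self.preprocess(tiles)
        out = [
            nn.softmax(self.net.forward(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def copy(self) -> "TileClassifier":
        return copy.deepcopy(self)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        weights = {f"p{i}": p for i, p in enumerate(self.net.params)}
        np.savez(path / "weights.npz", **weights)
        sidecar = {
            "task": asdict(self.task),
            "config": asdict(self.config),
        }
        (path / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TileClassifier":
        path = Path(path)
        sidecar = json.loads((path / "model.json").read_text())
        task = TaskSpec(**sidecar["task"])
        cfg_dict = sidecar["config"]
        cfg_dict["augment"] = AugmentConfig(**cfg_dict["augment"])
        config = TrainConfig(**cfg_dict)
        model = _init_model(task, config, input_hw=None)
        data = np.load(path / "weights.npz")
        for i, p in enumerate(model.net.params):
            p[...] = data[f"p{i}"]
        return model


def build_model(
    task: TaskSpec,
    config: TrainConfig,
    input_hw: tuple[int, int] = (224, 224),
) -> TileClassifier:
    """Construct an untrained model (seeded init) for the given tile size.

    Useful for planting hand-designed first-layer kernels before
    interpretability experiments.
    """
    return _init_model(task, config, input_hw)


def _init_model(
    task: TaskSpec, config: TrainConfig, input_hw: tuple[int, int] | None
) -> TileClassifier:
    h, w = input_hw if input_hw is not None else (224, 224)
    d = config.input_downscale
    rng = np.random.default_rng(config.seed)
    builder = _ARCHITECTURES[config.architecture]
    net = builder((h // d, w // d, 3), len(task.classes), config, rng)
    return TileClassifier(net, task, config)


def _encode_labels(labels, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([index[l] for l in labels], dtype=int)
    except KeyError as err:
        raise ValueError(f"label {err} not in task classes {classes}") from None


def _fit_epochs(
    model: TileClassifier,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    rng: np.random.Generator,
    monitor: tuple[np.ndarray, np.ndarray] | None,
    lr: float | None = None,
) -> pd.DataFrame:
    config = model.config
    n_classes = len(model.task.classes)
    counts = np.bincount(y, minlength=n_classes).astype(float)
    class_w = np.where(counts > 0, len(y) / (n_classes * np.maximum(counts, 1)), 0.0)
    sample_w = class_w[y]

    opt = nn.Adam(
        model.net.params,
        lr=lr if lr is not None else config.learning_rate,
        weight_decay=config.weight_decay,
    )
    aug = config.augment
    history = []
    for epoch in range(epochs):
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for start in range(0, len(x), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x[idx]
            if not aug.is_identity:
                # preprocessed tiles are on the darkness scale: white -> 0
                xb = np.stack(
                    [
                        _apply_params(t, _draw_params(aug, rng), fill=0.0)
                        for t in xb
                    ]
                ).astype(np.float32)
            logits = model.net.forward(xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx], sample_w[idx])
            grads = model.net.backward(dlogits)
            opt.step(grads)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        row = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": correct / len(x),
        }
        if monitor is not None:
            xm, ym = monitor
            logits = np.concatenate(
                [
                    model.net.forward(xm[i : i + 256], train=False)
                    for i in range(0, len(xm), 256)
                ]
            )
            mloss, _ = nn.softmax_cross_entropy(logits, ym)
            row["monitor_loss"] = mloss
            row["monitor_accuracy"] = float((logits.argmax(axis=1) == ym).mean())
        history.append(row)
    return pd.DataFrame(history)


def train_tile_classifier(
    train_tiles: np.ndarray,
    train_labels,
    task: TaskSpec,
    config: TrainConfig,
    monitor_tiles: np.ndarray | None = None,
    monitor_labels=None,
    initial_model: TileClassifier | None = None,
) -> tuple[TileClassifier, pd.DataFrame]:
    """Train a tile-level CNN for ``task``.

    Labels are slide-level labels inherited by the tiles.  Class imbalance
    is handled with class-weighted loss; the seed in ``config`` fixes
    initialization, shuffling, dropout and augmentation draws, so repeated
    CPU runs are bit-identical.  ``initial_model`` warm-starts training
    from existing weights (e.g. a model with hand-planted first-layer
    kernels) instead of a fresh seeded initialization.
    """
    y = _encode_labels(train_labels, task.classes)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if initial_model is not None:
        model = initial_model.copy()
    else:
        model = _init_model(task, config, input_hw=train_tiles.shape[1:3])
    x = model.preprocess(train_tiles)
    monitor = None
    if monitor_tiles is not None:
        monitor = (
            model.preprocess(monitor_tiles),
            _encode_labels(monitor_labels, task.classes),
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    history = _fit_epochs(model, x, y, config.epochs, rng, monitor)
    return model, history


def predict_tiles(model: TileClassifier, tiles: np.ndarray) -> pd.DataFrame:
    """Per-tile class probabilities, one row per input tile in input order."""
    probs = model.predict_proba(tiles)
    return pd.DataFrame(probs, columns=list(model.task.classes))


def fine_tune(
    model: TileClassifier,
    primary_tiles: np.ndarray,
    primary_labels,
    external_tiles: np.ndarray,
    external_labels,
    external_patient_ids,
    external_fraction: float = 0.10,
    epochs: int = 3,
    seed: int = 0,
) -> tuple[TileClassifier, list]:
    """Adapt a trained model to an external cohort.

    A fraction of external PATIENTS (not tiles) is selected and their tiles
    are mixed with the primary training tiles for continued training at a
    reduced learning rate.  Returns the adapted model and the list of
    external patients excluded from fine-tuning — the only ones on which
    the adapted model may be evaluated.
    """
    if not 0.0 < external_fraction < 1.0:
        raise ValueError("external_fraction must lie in (0, 1)")
    patient_ids = np.asarray(external_patient_ids)
    patients = np.unique(patient_ids)
    n_sel = int(np.ceil(external_fraction * len(patients)))
    if n_sel < 1:
        raise ValueError("no external patients selected for fine-tuning")
    if n_sel >= len(patients):
        raise ValueError("external cohort too small to spare held-out patients")
    rng = np.random.default_rng(seed)
    selected = set(rng.choice(patients, size=n_sel, replace=False))
    mask = np.array([p in selected for p in patient_ids])

    tuned = model.copy()
    x = np.concatenate(
        [tuned.preprocess(primary_tiles), tuned.preprocess(external_tiles[mask])]
    )
    y = _encode_labels(
        list(primary_labels) + list(np.asarray(external_labels)[mask]),
        tuned.task.classes,
    )
    fit_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    _fit_epochs(
        tuned, x, y, epochs, fit_rng, monitor=None,
        lr=0.1 * tuned.config.learning_rate,
    )
    held_out = sorted(set(patients) - selected)
    return tuned, held_out
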