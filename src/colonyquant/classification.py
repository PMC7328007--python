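"""Five-class colony phenotype classification of cropped colony images.

A small convolutional network maps a resized colony crop to posterior
probabilities over {white, red, pink, variegating, bad_segmentation}.
Training follows a staged recipe: a last-layer warmup without
augmentation, warm-restart cosine-annealed cycles on the last layer with
augmentation, then all layers with differential learning rates across
network thirds and cycles of increasing length (1, 2, 4 epochs per set),
with early stopping on validation log loss.  Prediction optionally uses
test-time augmentation: the mean probability over the original crop plus
four randomly augmented copies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from . import nn
from .postprocess import ColonyCrop
from .schedules import LRScheduleSpec, scheduled_lr
from .synthgen import CLASS_NAMES, CLASS_ORDER, ColonyPhenotype

__all__ = [
    "ClassProbabilities",
    "ClfAugmentSpec",
    "ClfTrainConfig",
    "SmallCNN",
    "build_classifier",
    "augment_crop",
    "train_classifier",
    "training_plan",
    "predict_with_tta",
    "classify_crops",
    "save_classifier",
    "load_classifier",
    "desk_clf_config",
    "fullscale_clf_config",
    "SUPPORTED_BACKBONES",
]

SUPPORTED_BACKBONES = ("small-cnn",)


@dataclass
class ClassProbabilities:
    """Posterior over the five colony classes, in fixed class order."""

    probs: np.ndarray  # shape (5,), sums to 1

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probs must be 5 nonnegative values summing to 1 (±1e-6)")
        self.probs = p

    @property
    def argmax_label(self) -> ColonyPhenotype:
        # np.argmax returns the first maximum: ties break by class order
        return CLASS_ORDER[int(np.argmax(self.probs))]


@dataclass(frozen=True)
class ClfAugmentSpec:
    max_rotation_deg: float = 10.0
    dihedral: bool = True  # random element of the dihedral group of the square
    brightness: float = 0.1
    contrast: float = 0.1
    max_zoom: float = 1.1


@dataclass
class ClfTrainConfig:
    input_size: int = 50
    batch_size: int = 128
    momentum: float = 0.9
    weight_decay: float = 0.0
    warmup_epochs: int = 1
    warmup_lr: float = 1e-2
    last_layer_cycles: int = 3  # cosine-annealed 1-epoch warm restarts
    n_sets: int = 17
    cycle_lengths: tuple[int, ...] = (1, 2, 4)
    max_lrs: tuple[float, float, float] = (1.1e-4, 3.3e-4, 1e-3)
    augmentation: ClfAugmentSpec = field(default_factory=ClfAugmentSpec)
    backbone: str = "small-cnn"
    pretrained: bool = False
    early_stop_patience: int = 3  # evaluations without val log-loss improvement
    seed: int = 0

    def __post_init__(self):
        if self.input_size < 16:
            raise ValueError("input_size must be >= 16")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def desk_clf_config(seed: int = 0) -> ClfTrainConfig:
    """Desk profile: small random-init net, one set of (1, 2, 4) cycles.

    11 epochs total (1 warmup + 3 last-layer cycles + 7 all-layer), with
    learning rates sized for a from-scratch network.
    """
    return ClfTrainConfig(
        batch_size=16,
        warmup_lr=0.02,
        n_sets=1,
        max_lrs=(0.01, 0.03, 0.06),
        seed=seed,
    )


def fullscale_clf_config(seed: int = 0) -> ClfTrainConfig:
    """Full-size profile: pretrained Resnet-34 recipe (schedule ledger only).

    17 sets of (1, 2, 4)-epoch cycles — 51 cycles, 119 epochs — with the
    differential maximum rates (1.1e-4, 3.3e-4, 1e-3) across thirds.
    """
    return ClfTrainConfig(backbone="resnet34", pretrained=True, seed=seed)


def training_plan(config: ClfTrainConfig) -> dict:
    """Enumerate the all-layer stage's cycle ledger without training."""
    lengths = list(config.cycle_lengths) * config.n_sets
    return {
        "n_cycles": len(lengths),
        "cycle_lengths": lengths,
        "n_epochs": int(sum(lengths)),
    }


class SmallCNN:
    """3-conv + 2-fc network for 5-class colony crops."""

    N_CLASSES = 5

    def __init__(self, input_size: int, seed: int):
        self.input_size = input_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2d(3, 12, 3, rng)
        self.conv2 = nn.Conv2d(12, 24, 3, rng)
        self.conv3 = nn.Conv2d(24, 48, 3, rng)
        s = input_size
        for _ in range(3):
            s //= 2
        self._feat = 48 * s * s
        self.fc1 = nn.Linear(self._feat, 64, rng)
        self.fc2 = nn.Linear(64, self.N_CLASSES, rng)
        self.r1, self.r2, self.r3, self.r4 = (nn.ReLU() for _ in range(4))
        self.p1, self.p2, self.p3 = (nn.MaxPool2() for _ in range(3))
        self.flat = nn.Flatten()

    def layer_groups(self) -> list[list[nn.Param]]:
        return [
            self.conv1.params() + self.conv2.params(),
            self.conv3.params() + self.fc1.params(),
            self.fc2.params(),
        ]

    def last_layer_params(self) -> list[nn.Param]:
        return self.fc2.params()

    def named_params(self) -> dict[str, nn.Param]:
        out = {}
        for name in ("conv1", "conv2", "conv3", "fc1", "fc2"):
            layer = getattr(self, name)
            out[f"{name}.weight"] = layer.weight
            out[f"{name}.bias"] = layer.bias
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.p1.forward(self.r1.forward(self.conv1.forward(x)))
        h = self.p2.forward(self.r2.forward(self.conv2.forward(h)))
        h = self.p3.forward(self.r3.forward(self.conv3.forward(h)))
        h = self.r4.forward(self.fc1.forward(self.flat.forward(h)))
        return self.fc2.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc1.backward(self.r4.backward(self.fc2.backward(dlogits)))
        d = self.conv3.backward(self.r3.backward(self.p3.backward(self.flat.backward(d))))
        d = self.conv2.backward(self.r2.backward(self.p2.backward(d)))
        self.conv1.backward(self.r1.backward(self.p1.backward(d)))

    @staticmethod
    def normalize(images: np.ndarray) -> np.ndarray:
        return (images.astype(np.float32) / 255.0 - 0.5).transpose(0, 3, 1, 2)

    def predict_proba_batch(self, images: np.ndarray) -> np.ndarray:
        """Softmax probabilities for a batch of uint8 crops (N, s, s, 3)."""
        return nn.softmax(self.forward(self.normalize(images)))


def build_classifier(config: ClfTrainConfig) -> SmallCNN:
    """Instantiate the classifier network; unknown backbones raise."""
    if config.backbone not in SUPPORTED_BACKBONES:
        raise ValueError(
            f"unsupported backbone {config.backbone!r}; supported: {SUPPORTED_BACKBONES}"
        )
    return SmallCNN(config.input_size, config.seed)


def _apply_dihedral(img: np.ndarray, k: int) -> np.ndarray:
    """Element k of the dihedral group of the square (0 = identity)."""
    if img.shape[0] != img.shape[1]:
        # non-square: restrict to the shape-preserving subgroup
        return [img, img[:, ::-1], img[::-1], img[::-1, ::-1]][k % 4]
    out = np.rot90(img, k % 4)
    if k >= 4:
        out = out[:, ::-1]
    return out


def augment_crop(crop: np.ndarray, aug: ClfAugmentSpec, rng: np.random.Generator) -> np.ndarray:
    """One random augmentation of a colony crop; output dims match input.

    Draws, in fixed order: rotation angle within ±max_rotation_deg, a
    dihedral-8 element, a zoom factor in [1, max_zoom] (zoom in, center
    crop back), and brightness/contrast jitter.
    """
    angle = rng.uniform(-aug.max_rotation_deg, aug.max_rotation_deg)
    k = int(rng.integers(0, 8)) if aug.dihedral else 0
    zoom = rng.uniform(1.0, aug.max_zoom)
    bshift = rng.uniform(-aug.brightness, aug.brightness)
    cfac = 1.0 + rng.uniform(-aug.contrast, aug.contrast)

    img = crop.astype(np.float32) / 255.0
    h, w = img.shape[:2]
    if angle != 0.0:
        img = _sk_rotate(img, angle, order=1, mode="edge", preserve_range=True)
    img = _apply_dihedral(img, k)
    if zoom > 1.0:
        zh, zw = int(round(h * zoom)), int(round(w * zoom))
        if zh > h and zw > w:
            big = _sk_resize(img, (zh, zw), order=1, preserve_range=True)
            r0, c0 = (zh - h) // 2, (zw - w) // 2
            img = big[r0 : r0 + h, c0 : c0 + w]
    img = np.clip((img - 0.5) * cfac + 0.5 + bshift, 0.0, 1.0)
    return np.ascontiguousarray((img * 255.0 + 0.5).astype(np.uint8))


def _resize_crop(pixels: np.ndarray, size: int) -> np.ndarray:
    if pixels.shape[:2] == (size, size):
        return pixels
    return (_sk_resize(pixels, (size, size), order=1, preserve_range=True) + 0.5).astype(np.uint8)


def _load_crop_split(manifest: pd.DataFrame, data_dir: Path, split: str, size: int):
    rows = manifest[manifest["split"] == split]
    if rows.empty:
        raise ValueError(f"crop manifest has no rows in split {split!r}")
    images = np.stack(
        [
            _resize_crop(np.asarray(Image.open(data_dir / p).convert("RGB")), size)
            for p in rows["crop_path"]
        ]
    )
    name_to_idx = {name: i for i, name in enumerate(CLASS_NAMES)}
    try:
        labels = np.array([name_to_idx[l] for l in rows["label"]])
    except KeyError as e:
        raise ValueError(f"unknown class label {e.args[0]!r} in manifest") from None
    return images, labels


def train_classifier(
    manifest: pd.DataFrame | str | Path,
    config: ClfTrainConfig,
    data_dir: str | Path | None = None,
) -> tuple[SmallCNN, pd.DataFrame]:
    """Train the colony classifier through its staged recipe.

    Returns the model at the best validation log loss and a per-epoch
    history (epoch, stage, train_loss, val_log_loss, val_accuracy, lr).
    Raises if any of the five classes is missing from the training split.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = Path(manifest)
        data_dir = manifest.parent if data_dir is None else Path(data_dir)
        manifest = pd.read_csv(manifest)
    elif data_dir is None:
        raise ValueError("data_dir is required when manifest is a DataFrame")
    data_dir = Path(data_dir)

    x_train, y_train = _load_crop_split(manifest, data_dir, "train", config.input_size)
    x_val, y_val = _load_crop_split(manifest, data_dir, "valid", config.input_size)
    present = set(y_train.tolist())
    missing = [CLASS_NAMES[i] for i in range(5) if i not in present]
    if missing:
        raise ValueError(f"training split is missing class(es): {missing}")

    model = build_classifier(config)
    rng = np.random.default_rng(config.seed + 1)
    n_train = len(x_train)
    steps_per_epoch = max(1, -(-n_train // config.batch_size))
    history: list[dict] = []
    best_loss, best_state = np.inf, None
    epochs_since_best = 0
    epoch_counter = 0
    stop = False

    def run_stage(stage_idx, schedule, groups, n_epochs, augment):
        nonlocal epoch_counter, best_loss, best_state, epochs_since_best, stop
        opt = nn.SGD(groups, momentum=config.momentum, weight_decay=config.weight_decay)
        step = 0
        for _ in range(n_epochs):
            if stop:
                return
            order = rng.permutation(n_train)
            losses = []
            lr_last = None
            for start in range(0, n_train, config.batch_size):
                idx = order[start : start + config.batch_size]
                if augment:
                    xb = np.stack(
                        [augment_crop(x_train[i], config.augmentation, rng) for i in idx]
                    )
                else:
                    xb = x_train[idx]
                logits = model.forward(SmallCNN.normalize(xb))
                loss, dlogits = nn.softmax_cross_entropy(logits, y_train[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite training loss in stage {stage_idx}")
                opt.zero_grad()
                model.backward(dlogits)
                lrs = np.broadcast_to(scheduled_lr(step, schedule, steps_per_epoch), (len(groups),))
                opt.step(lrs)
                lr_last = float(lrs[-1])
                losses.append(loss)
                step += 1
            val_loss, val_acc = _evaluate(model, x_val, y_val, config.batch_size)
            epoch_counter += 1
            history.append(
                {
                    "epoch": epoch_counter,
                    "stage": stage_idx,
                    "train_loss": float(np.mean(losses)),
                    "val_log_loss": val_loss,
                    "val_accuracy": val_acc,
                    "lr": lr_last,
                }
            )
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_state = {k: p.value.copy() for k, p in model.named_params().items()}
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if epochs_since_best >= config.early_stop_patience and stage_idx == 2:
                    stop = True  # over-fitting observed: stop the long stage

    # stage 0: last layer, no augmentation, constant warmup rate
    warmup = LRScheduleSpec(
        "cosine_anneal", config.warmup_lr, config.warmup_lr, 0, config.warmup_epochs
    )
    run_stage(0, warmup, [model.last_layer_params()], config.warmup_epochs, augment=False)

    # stage 1: last layer, augmented warm restarts (1-epoch cosine cycles)
    sgdr_last = LRScheduleSpec(
        "cosine_anneal", config.warmup_lr, 0.0, 0, 1, cycles=config.last_layer_cycles
    )
    run_stage(1, sgdr_last, [model.last_layer_params()], config.last_layer_cycles, augment=True)

    # stage 2: all layers, sets of increasing-length cosine cycles with
    # differential learning rates across thirds
    for length in training_plan(config)["cycle_lengths"]:
        if stop:
            break
        sched = LRScheduleSpec(
            "cosine_anneal",
            max_lr=config.max_lrs,
            min_lr=tuple(0.0 for _ in config.max_lrs),
            epochs_up=0,
            epochs_down=length,
        )
        run_stage(2, sched, model.layer_groups(), length, augment=True)

    if best_state is not None:
        for k, p in model.named_params().items():
            p.value[...] = best_state[k]
    return model, pd.DataFrame(history)


def _evaluate(model: SmallCNN, x: np.ndarray, y: np.ndarray, batch_size: int):
    losses, correct = [], 0
    for start in range(0, len(x), batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        logits = model.forward(SmallCNN.normalize(xb))
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def predict_with_tta(
    model: SmallCNN,
    crop: np.ndarray,
    n_augments: int = 4,
    rng: np.random.Generator | None = None,
    aug: ClfAugmentSpec | None = None,
) -> ClassProbabilities:
    """Average the class posterior over the original crop plus augmented copies.

    With the default ``n_augments=4`` this is five forward passes; with 0
    it reduces exactly to the plain prediction.
    """
    if n_augments < 0:
        raise ValueError("n_augments must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    aug = aug or ClfAugmentSpec()
    crop = _resize_crop(np.asarray(crop), model.input_size)
    variants = [crop] + [augment_crop(crop, aug, rng) for _ in range(n_augments)]
    probs = model.predict_proba_batch(np.stack(variants))
    mean = probs.mean(axis=0)
    return ClassProbabilities(mean / mean.sum())


def classify_crops(
    model: SmallCNN,
    crops: list[ColonyCrop | str | Path],
    tta: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Predict a class for every crop; one row per crop, unreadable files flagged.

    Returns columns: plate_id, region_id, label, p_<class> x5, status.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, crop in enumerate(crops):
        plate_id, region_id = "", i
        try:
            if isinstance(crop, ColonyCrop):
                pixels = crop.pixels
                plate_id, region_id = crop.plate_id, crop.region_id
            else:
                path = Path(crop)
                plate_id = path.stem.split("__")[0]
                if "__" in path.stem:
                    region_id = int(path.stem.split("__")[1])
                pixels = np.asarray(Image.open(path).convert("RGB"))
            if tta:
                cp = predict_with_tta(model, pixels, n_augments=4, rng=rng)
            else:
                resized = _resize_crop(pixels, model.input_size)
                p = model.predict_proba_batch(resized[None])[0]
                cp = ClassProbabilities(p / p.sum())
            rows.append(
                {
                    "plate_id": plate_id,
                    "region_id": region_id,
                    "label": cp.argmax_label.value,
                    **{f"p_{_short(n)}": float(v) for n, v in zip(CLASS_NAMES, cp.probs)},
                    "status": "ok",
                }
            )
        except (OSError, ValueError) as e:
            rows.append(
                {
                    "plate_id": plate_id,
                    "region_id": region_id,
                    "label": "",
                    **{f"p_{_short(n)}": np.nan for n in CLASS_NAMES},
                    "status": f"error: {e}",
                }
            )
    return pd.DataFrame(rows)


def _short(name: str) -> str:
    return "bad" if name == "bad_segmentation" else name


def save_classifier(model: SmallCNN, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **{k: p.value for k, p in model.named_params().items()})
    sidecar = {
        "backbone": "small-cnn",
        "input_size": model.input_size,
        "seed": model.seed,
        "classes": list(CLASS_NAMES),
        "normalization": "x/255 - 0.5",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_classifier(path: str | Path) -> SmallCNN:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = SmallCNN(sidecar["input_size"], sidecar.get("seed", 0))
    with np.load(path) as data:
        for k, p in model.named_params().items():
            p.value[...] = data[k]
    return model
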