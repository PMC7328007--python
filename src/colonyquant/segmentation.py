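"""Plate-image semantic segmentation: a small encoder-decoder network.

The segmenter maps an RGB plate photograph to per-pixel foreground
(colony) probability.  It is a U-net-style encoder-decoder with skip
connections, trained with binary cross-entropy with logits and evaluated
with the dice coefficient, using cyclical learning-rate schedules and
differential learning rates across network thirds.

Two training profiles exist: a desk profile (128 px synthetic plates,
small random-init encoder) that trains in minutes on one CPU, and a
full-size profile (1024 px, pretrained Resnet-34 encoder) whose stage and
schedule ledger is represented for schedule arithmetic but which requires
a GPU-class deep-learning stack to execute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from . import nn
from .schedules import LRScheduleSpec, scheduled_lr

__all__ = [
    "PlateImage",
    "AugmentSpec",
    "SegStage",
    "SegTrainConfig",
    "Segmenter",
    "build_segmenter",
    "dice_coefficient",
    "augment_seg_pair",
    "train_segmenter",
    "predict_mask",
    "binarize",
    "save_segmenter",
    "load_segmenter",
    "desk_seg_config",
    "fullscale_seg_config",
    "SUPPORTED_ENCODERS",
]

SUPPORTED_ENCODERS = ("small-unet",)
#: Encoders named in the full-size profile; they need a GPU deep-learning
#: stack and are not executable here, but their configs remain expressible.
DECLARED_ENCODERS = ("small-unet", "resnet34-unet")


@dataclass
class PlateImage:
    """An RGB plate photograph with its identity."""

    pixels: np.ndarray  # H x W x 3 uint8
    plate_id: str
    source_path: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or min(px.shape[:2]) < 64:
            raise ValueError(f"plate image must be HxWx3 with H,W >= 64, got {px.shape}")
        self.pixels = px


@dataclass(frozen=True)
class AugmentSpec:
    max_rotation_deg: float = 4.0
    horizontal_flip: bool = True
    brightness: float = 0.1  # max |additive| shift as fraction of full scale
    contrast: float = 0.1  # max |multiplicative| deviation from 1


@dataclass(frozen=True)
class SegStage:
    image_size: int
    last_layer_only: bool
    schedule: LRScheduleSpec


@dataclass
class SegTrainConfig:
    image_size: int = 128
    batch_size: int = 4
    weight_decay: float = 1e-7
    stages: tuple[SegStage, ...] = ()
    augmentation: AugmentSpec = field(default_factory=AugmentSpec)
    encoder: str = "small-unet"
    pretrained: bool = False
    base_channels: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


def desk_seg_config(seed: int = 0) -> SegTrainConfig:
    """Desk-scale training profile: 128 px plates, small random-init net.

    One all-layer triangular cycle (1 epoch up, 8 down, 9 epochs total)
    with differential maximum rates across thirds.  A last-layer warmup
    stage only helps when the encoder is pretrained, so the from-scratch
    desk profile goes straight to all-layer training.
    """
    main = SegStage(
        image_size=128,
        last_layer_only=False,
        schedule=LRScheduleSpec(
            "circular",
            max_lr=(0.05, 0.1, 0.2),
            min_lr=(0.05 / 20, 0.1 / 20, 0.2 / 20),
            epochs_up=1,
            epochs_down=8,
        ),
    )
    return SegTrainConfig(image_size=128, batch_size=2, stages=(main,), base_channels=12, seed=seed)


def fullscale_seg_config(seed: int = 0) -> SegTrainConfig:
    """Full-size profile: the four-stage 512->1024 px schedule ledger.

    Executable only with a pretrained Resnet-34 encoder on GPU-class
    hardware; kept so the stage parameters remain first-class objects.
    """
    stages = (
        SegStage(512, True, LRScheduleSpec("circular", 4e-2, 8e-3, 1, 7)),
        SegStage(
            512,
            False,
            LRScheduleSpec(
                "circular",
                max_lr=(1e-4, 1e-3, 1e-2),
                min_lr=(1e-4 / 20, 1e-3 / 20, 1e-2 / 20),
                epochs_up=2,
                epochs_down=18,
            ),
        ),
        SegStage(1024, True, LRScheduleSpec("circular", 4e-2, 8e-3, 0.5, 1.5)),
        SegStage(
            1024,
            False,
            LRScheduleSpec(
                "circular",
                max_lr=(4e-5, 2e-4, 4e-3),
                min_lr=(4e-5 / 20, 2e-4 / 20, 4e-3 / 20),
                epochs_up=2.5,
                epochs_down=17.5,
                cycles=20,
            ),
        ),
    )
    return SegTrainConfig(
        image_size=512,
        batch_size=4,
        stages=stages,
        encoder="resnet34-unet",
        pretrained=True,
        seed=seed,
    )


class Segmenter:
    """Small U-net-style network: 3-channel image -> 1-channel logits."""

    def __init__(self, input_size: int, seed: int, base_channels: int = 8):
        if input_size % 4 != 0 or input_size < 16:
            raise ValueError("input_size must be a multiple of 4 and >= 16")
        self.input_size = input_size
        self.seed = seed
        self.base_channels = c = base_channels
        rng = np.random.default_rng(seed)
        self.enc1 = nn.Conv2d(3, c, 3, rng)
        self.enc2 = nn.Conv2d(c, 2 * c, 3, rng)
        self.bott = nn.Conv2d(2 * c, 4 * c, 3, rng)
        self.dec2 = nn.Conv2d(6 * c, 2 * c, 3, rng)
        self.dec1 = nn.Conv2d(3 * c, c, 3, rng)
        self.head = nn.Conv2d(c, 1, 1, rng)
        self.r1, self.r2, self.r3, self.r4, self.r5 = (nn.ReLU() for _ in range(5))
        self.p1, self.p2 = nn.MaxPool2(), nn.MaxPool2()
        self.u1, self.u2 = nn.Upsample2(), nn.Upsample2()
        self.threshold = 0.5

    # --- layer-group bookkeeping -----------------------------------------
    def layer_groups(self) -> list[list[nn.Param]]:
        """Three groups in network order, for differential learning rates."""
        return [
            self.enc1.params() + self.enc2.params(),
            self.bott.params() + self.dec2.params(),
            self.dec1.params() + self.head.params(),
        ]

    def last_layer_params(self) -> list[nn.Param]:
        return self.head.params()

    def named_params(self) -> dict[str, nn.Param]:
        out = {}
        for name in ("enc1", "enc2", "bott", "dec2", "dec1", "head"):
            layer = getattr(self, name)
            out[f"{name}.weight"] = layer.weight
            out[f"{name}.bias"] = layer.bias
        return out

    # --- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        a1 = self.r1.forward(self.enc1.forward(x))
        a2 = self.r2.forward(self.enc2.forward(self.p1.forward(a1)))
        b = self.r3.forward(self.bott.forward(self.p2.forward(a2)))
        u2 = self.u2.forward(b)
        d2 = self.r4.forward(self.dec2.forward(np.concatenate([u2, a2], axis=1)))
        u1 = self.u1.forward(d2)
        d1 = self.r5.forward(self.dec1.forward(np.concatenate([u1, a1], axis=1)))
        return self.head.forward(d1)

    def backward(self, dlogits: np.ndarray) -> None:
        c = self.base_channels
        d = self.dec1.backward(self.r5.backward(self.head.backward(dlogits)))
        du1, da1_skip = d[:, : 2 * c], d[:, 2 * c :]
        d = self.dec2.backward(self.r4.backward(self.u1.backward(du1)))
        du2, da2_skip = d[:, : 4 * c], d[:, 4 * c :]
        db = self.u2.backward(du2)
        da2 = self.p2.backward(self.bott.backward(self.r3.backward(db)))
        da2 += da2_skip
        da1 = self.p1.backward(self.enc2.backward(self.r2.backward(da2)))
        da1 += da1_skip
        self.enc1.backward(self.r1.backward(da1))

    # --- inference ---------------------------------------------------------
    @staticmethod
    def normalize(images: np.ndarray) -> np.ndarray:
        return (images.astype(np.float32) / 255.0 - 0.5).transpose(0, 3, 1, 2)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        x = self.normalize(image[None])
        logits = self.forward(x)[0, 0]
        return nn.sigmoid(logits)


def build_segmenter(config: SegTrainConfig) -> Segmenter:
    """Instantiate the segmentation network for a training config.

    Only the small random-init encoder is runnable in this build; asking
    for any other encoder raises and lists the supported names.
    """
    if config.encoder not in SUPPORTED_ENCODERS:
        raise ValueError(
            f"unsupported encoder {config.encoder!r}; supported: {SUPPORTED_ENCODERS}"
        )
    return Segmenter(config.image_size, config.seed, config.base_channels)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    a, b = int(pred.sum()), int(truth.sum())
    if a + b == 0:
        return 1.0
    return 2.0 * int((pred & truth).sum()) / (a + b)


def _rotate_image(img: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    from skimage.transform import rotate

    if angle_deg == 0.0:
        return img
    return rotate(img, angle_deg, order=order, mode="edge", preserve_range=True)


def augment_seg_pair(
    image: np.ndarray,
    mask: np.ndarray,
    aug: AugmentSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly augment an image/mask training pair.

    The same geometric transform (small rotation, horizontal flip) is
    applied to both; brightness/contrast jitter touches the image only.
    The mask is resampled nearest-neighbour and stays boolean.
    """
    angle = rng.uniform(-aug.max_rotation_deg, aug.max_rotation_deg)
    do_flip = bool(aug.horizontal_flip and rng.uniform() < 0.5)
    bshift = rng.uniform(-aug.brightness, aug.brightness)
    cfac = 1.0 + rng.uniform(-aug.contrast, aug.contrast)

    img = image.astype(np.float32) / 255.0
    m = np.asarray(mask, dtype=bool)
    if angle != 0.0:
        img = _rotate_image(img, angle, order=1)
        m = _rotate_image(m.astype(np.float32), angle, order=0) > 0.5
    if do_flip:
        img = img[:, ::-1]
        m = m[:, ::-1]
    img = (img - 0.5) * cfac + 0.5 + bshift
    img = np.clip(img, 0.0, 1.0)
    return (img * 255.0 + 0.5).astype(np.uint8), np.ascontiguousarray(m)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability mask (inclusive: p == threshold is foreground)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability mask values must lie in [0, 1]")
    return prob >= threshold


def predict_mask(model: Segmenter, image: np.ndarray | PlateImage) -> np.ndarray:
    """Foreground probability for one plate image at the trained geometry."""
    px = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    if px.shape[:2] != (model.input_size, model.input_size):
        raise ValueError(
            f"image size {px.shape[:2]} does not match trained input "
            f"({model.input_size}, {model.input_size})"
        )
    return model.predict_proba(px)


def _load_split(manifest: pd.DataFrame, data_dir: Path, split: str, size: int):
    rows = manifest[manifest["split"] == split]
    if rows.empty:
        raise ValueError(f"manifest has no rows in split {split!r}")
    images, masks = [], []
    for _, r in rows.iterrows():
        img = np.asarray(Image.open(data_dir / r["image_path"]).convert("RGB"))
        m = np.asarray(Image.open(data_dir / r["mask_path"]).convert("L")) > 127
        if img.shape[0] != size or img.shape[1] != size:
            img = (_sk_resize(img, (size, size), order=1, preserve_range=True) + 0.5).astype(np.uint8)
            m = _sk_resize(m.astype(float), (size, size), order=0, preserve_range=True) > 0.5
        images.append(img)
        masks.append(m)
    return images, masks


def train_segmenter(
    manifest: pd.DataFrame | str | Path,
    config: SegTrainConfig,
    data_dir: str | Path | None = None,
) -> tuple[Segmenter, pd.DataFrame]:
    """Train the segmenter through the configured stages.

    Returns the model holding the weights of the epoch with the best
    validation dice, together with a per-epoch history table
    (epoch, stage, train_loss, val_loss, val_dice, lr).
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = Path(manifest)
        data_dir = manifest.parent if data_dir is None else Path(data_dir)
        manifest = pd.read_csv(manifest)
    elif data_dir is None:
        raise ValueError("data_dir is required when manifest is a DataFrame")
    data_dir = Path(data_dir)

    model = build_segmenter(config)
    rng = np.random.default_rng(config.seed + 1)
    history: list[dict] = []
    best_dice, best_state = -1.0, None
    epoch_counter = 0

    for stage_idx, stage in enumerate(config.stages):
        if stage.image_size != model.input_size:
            raise ValueError(
                "multi-resolution stages require rebuilding the network; "
                f"stage size {stage.image_size} != model size {model.input_size}"
            )
        train_imgs, train_masks = _load_split(manifest, data_dir, "train", stage.image_size)
        val_imgs, val_masks = _load_split(manifest, data_dir, "valid", stage.image_size)
        n_train = len(train_imgs)
        # foreground prior: weight the positive class and initialize the
        # head bias at the prior log-odds, so early training cannot
        # collapse into the all-background attractor
        fg = float(np.mean([m.mean() for m in train_masks]))
        fg = min(max(fg, 1e-3), 0.5)
        pos_weight = float(np.clip((1.0 - fg) / fg, 1.0, 2.0))
        if stage_idx == 0:
            model.head.bias.value[...] = np.log(fg / (1.0 - fg))
        steps_per_epoch = max(1, -(-n_train // config.batch_size))
        groups = [model.last_layer_params()] if stage.last_layer_only else model.layer_groups()
        opt = nn.SGD(groups, momentum=0.9, weight_decay=config.weight_decay)
        n_epochs = int(round(stage.schedule.total_epochs))
        step = 0
        for _ in range(n_epochs):
            order = rng.permutation(n_train)
            losses = []
            lr_last = None
            for start in range(0, n_train, config.batch_size):
                idx = order[start : start + config.batch_size]
                xb, yb = [], []
                for i in idx:
                    img, m = augment_seg_pair(train_imgs[i], train_masks[i], config.augmentation, rng)
                    xb.append(img)
                    yb.append(m)
                x = Segmenter.normalize(np.stack(xb))
                y = np.stack(yb).astype(np.float32)[:, None]
                logits = model.forward(x)
                loss, dlogits = nn.bce_with_logits(logits, y, pos_weight=pos_weight)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at stage {stage_idx}, step {step}"
                    )
                opt.zero_grad()
                model.backward(dlogits)
                lrs = scheduled_lr(step, stage.schedule, steps_per_epoch)
                lrs = np.broadcast_to(lrs, (len(groups),))
                opt.step(lrs)
                lr_last = float(lrs[-1])
                losses.append(loss)
                step += 1
            val_loss, val_dice = _evaluate(model, val_imgs, val_masks, pos_weight)
            epoch_counter += 1
            history.append(
                {
                    "epoch": epoch_counter,
                    "stage": stage_idx,
                    "train_loss": float(np.mean(losses)),
                    "val_loss": val_loss,
                    "val_dice": val_dice,
                    "lr": lr_last,
                }
            )
            if val_dice > best_dice:
                best_dice = val_dice
                best_state = {k: p.value.copy() for k, p in model.named_params().items()}

    if best_state is not None:
        for k, p in model.named_params().items():
            p.value[...] = best_state[k]
    return model, pd.DataFrame(history)


def _evaluate(model: Segmenter, images, masks, pos_weight: float = 1.0) -> tuple[float, float]:
    losses, dices = [], []
    for img, m in zip(images, masks):
        x = Segmenter.normalize(img[None])
        logits = model.forward(x)
        loss, _ = nn.bce_with_logits(logits, m.astype(np.float32)[None, None], pos_weight=pos_weight)
        prob = nn.sigmoid(logits[0, 0])
        dices.append(dice_coefficient(prob >= model.threshold, m))
        losses.append(loss)
    return float(np.mean(losses)), float(np.mean(dices))


def save_segmenter(model: Segmenter, path: str | Path) -> None:
    """Save weights (.npz) plus a JSON sidecar with the model geometry."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **{k: p.value for k, p in model.named_params().items()})
    sidecar = {
        "encoder": "small-unet",
        "input_size": model.input_size,
        "threshold": model.threshold,
        "seed": model.seed,
        "base_channels": model.base_channels,
        "normalization": "x/255 - 0.5",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_segmenter(path: str | Path) -> Segmenter:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = Segmenter(
        sidecar["input_size"], sidecar.get("seed", 0), sidecar.get("base_channels", 8)
    )
    model.threshold = sidecar.get("threshold", 0.5)
    with np.load(path) as data:
        for k, p in model.named_params().items():
            p.value[...] = data[k]
    return model
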