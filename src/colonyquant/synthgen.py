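"""Synthetic red/white colony-assay plates with pixel-exact ground truth.

Emulates photographs of limiting-adenine indicator plates: a bright agar
disk on a dark background carrying round yeast colonies of five phenotypes —
``white`` (functional adenine pathway), ``red`` and ``pink`` (accumulating
vacuolar pigment from silenced *ade6+*), ``variegating`` (sectored red/white
colonies from unstable silencing), and ``bad_segmentation`` (clusters of
small overlapping colonies that a segmenter cannot separate and which are
excluded from per-plate statistics).

Every plate comes with a per-pixel foreground mask and a per-colony label
list, so both trainable pipeline stages and the end-to-end pipeline can be
trained and evaluated with no external photographs.  All randomness flows
from explicit seeds; one generator stream per plate/crop keeps datasets
order-independent and byte-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ColonyPhenotype",
    "CLASS_ORDER",
    "ColorModel",
    "ColonyAppearance",
    "SynthPlateSpec",
    "GroundTruth",
    "sample_colony",
    "render_plate",
    "generate_plate_dataset",
    "generate_crop_dataset",
    "allocate_counts",
]


class ColonyPhenotype(str, Enum):
    """The five colony classes scored in the red/white color assay."""

    WHITE = "white"
    RED = "red"
    PINK = "pink"
    VARIEGATING = "variegating"
    BAD_SEGMENTATION = "bad_segmentation"


#: Fixed class order used for tie-breaking and table columns everywhere.
CLASS_ORDER: tuple[ColonyPhenotype, ...] = (
    ColonyPhenotype.WHITE,
    ColonyPhenotype.RED,
    ColonyPhenotype.PINK,
    ColonyPhenotype.VARIEGATING,
    ColonyPhenotype.BAD_SEGMENTATION,
)

CLASS_NAMES: tuple[str, ...] = tuple(p.value for p in CLASS_ORDER)


@dataclass(frozen=True)
class ColorModel:
    mean_rgb: tuple[float, float, float]
    jitter: float = 0.05  # multiplicative per-channel s.d.


# Colony colors must merely be separable yet confusable under pixel noise;
# whites are warm off-white, reds dark crimson, pinks desaturated red.
DEFAULT_COLOR_MODELS: dict[ColonyPhenotype, ColorModel] = {
    ColonyPhenotype.WHITE: ColorModel((230.0, 225.0, 210.0)),
    ColonyPhenotype.RED: ColorModel((170.0, 40.0, 40.0)),
    ColonyPhenotype.PINK: ColorModel((220.0, 140.0, 150.0)),
}

AGAR_RGB = np.array([196.0, 168.0, 122.0])
BACKGROUND_RGB = np.array([26.0, 26.0, 30.0])
RIM_RGB = np.array([235.0, 232.0, 220.0])  # bright, deliberately colony-like
RING_RGB = (225.0, 168.0, 168.0)  # pinkish ring of aged white colonies

# Default class mixture mirrors the label frequencies of a hand-labeled
# colony pool from a silencing experiment (white-dominated, few clusters).
DEFAULT_MIXTURE: tuple[float, ...] = (537.0, 273.0, 310.0, 318.0, 38.0)


@dataclass
class ColonyAppearance:
    """Geometry and coloring of a single rendered colony (or cluster)."""

    center: tuple[float, float]  # (row, col), px
    radius: float  # px
    base_color: tuple[float, float, float]
    phenotype: ColonyPhenotype
    sector_pattern: list[tuple[float, float, tuple[float, float, float]]] = field(
        default_factory=list
    )
    ring_morphology: bool = False
    ring_color: tuple[float, float, float] = RING_RGB
    # bad-segmentation clusters: extra disks as (d_row, d_col, radius, color)
    cluster: list[tuple[float, float, float, tuple[float, float, float]]] = field(
        default_factory=list
    )

    @property
    def extent(self) -> float:
        """Radius of the smallest centered disk containing the whole colony."""
        e = self.radius
        for dr, dc, r, _ in self.cluster:
            e = max(e, math.hypot(dr, dc) + r)
        return e


@dataclass
class SynthPlateSpec:
    """Parameters of the synthetic plate renderer.

    Lengths are pixels; colony radii and rim thickness scale with
    ``image_size`` so a 128 px desk plate and a 512 px plate look alike.
    """

    image_size: int = 512
    plate_radius: float | None = None  # default 0.49 * image_size
    n_colonies: int | tuple[int, int] = 30
    class_mixture: tuple[float, ...] = DEFAULT_MIXTURE
    color_models: dict[ColonyPhenotype, ColorModel] = field(
        default_factory=lambda: dict(DEFAULT_COLOR_MODELS)
    )
    radius_range: tuple[float, float] = (0.030, 0.050)  # fraction of image_size
    overlap_probability: float = 0.0
    noise_sigma: float = 3.0  # additive, 0-255 scale
    illumination_amplitude: float = 0.08
    ring_probability: float = 0.0  # aged-white ring artifact, off by default
    edge_artifact: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.plate_radius is None:
            self.plate_radius = 0.49 * self.image_size
        if not self.plate_radius < self.image_size / 2:
            raise ValueError("plate_radius must be < image_size / 2")
        mix = np.asarray(self.class_mixture, dtype=float)
        if mix.shape != (5,) or (mix < 0).any() or mix.sum() <= 0:
            raise ValueError("class_mixture must be 5 nonnegative weights with positive sum")
        self.class_mixture = tuple(mix)

    @property
    def mixture_probs(self) -> np.ndarray:
        mix = np.asarray(self.class_mixture, dtype=float)
        return mix / mix.sum()

    @property
    def rim_thickness(self) -> float:
        return max(2.0, 0.02 * self.image_size)


@dataclass
class GroundTruth:
    """Per-pixel mask plus per-colony labels for one rendered plate."""

    mask: np.ndarray  # bool, H x W
    colonies: list[ColonyAppearance]
    true_nonwhite_pct: float | None

    def class_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in CLASS_NAMES}
        for col in self.colonies:
            counts[col.phenotype.value] += 1
        return counts


def nonwhite_percentage(counts: dict[str, int]) -> float | None:
    """100 x (red + pink + variegating) / (total - bad_segmentation), or None."""
    denom = sum(counts.values()) - counts["bad_segmentation"]
    if denom <= 0:
        return None
    num = counts["red"] + counts["pink"] + counts["variegating"]
    return 100.0 * num / denom


def _jittered(color: tuple[float, float, float], jitter: float, rng: np.random.Generator):
    factors = rng.normal(1.0, jitter, size=3)
    return tuple(np.clip(np.asarray(color) * factors, 0, 255))


def sample_colony(
    phenotype: ColonyPhenotype, spec: SynthPlateSpec, rng: np.random.Generator
) -> ColonyAppearance:
    """Draw the appearance of one colony of the requested phenotype.

    The center is drawn uniformly over the region of the plate where the
    colony fits entirely inside the agar; :func:`render_plate` may redraw it
    during placement.
    """
    try:
        phenotype = ColonyPhenotype(phenotype)
    except ValueError:
        raise ValueError(f"unknown colony phenotype: {phenotype!r}") from None

    lo, hi = spec.radius_range
    radius = rng.uniform(lo, hi) * spec.image_size
    center = _draw_center(spec, radius, rng)
    models = spec.color_models

    if phenotype in (ColonyPhenotype.WHITE, ColonyPhenotype.RED, ColonyPhenotype.PINK):
        m = models[phenotype]
        ring = phenotype is ColonyPhenotype.WHITE and rng.uniform() < spec.ring_probability
        return ColonyAppearance(
            center=center,
            radius=radius,
            base_color=_jittered(m.mean_rgb, m.jitter, rng),
            phenotype=phenotype,
            ring_morphology=ring,
        )
    if phenotype is ColonyPhenotype.VARIEGATING:
        n_sectors = int(rng.integers(2, 7))
        bounds = np.sort(rng.uniform(0.0, 2 * np.pi, size=n_sectors))
        first_white = bool(rng.integers(0, 2))
        white = _jittered(models[ColonyPhenotype.WHITE].mean_rgb, 0.04, rng)
        red = _jittered(models[ColonyPhenotype.RED].mean_rgb, 0.06, rng)
        sectors = []
        for i in range(n_sectors):
            start = float(bounds[i])
            end = float(bounds[(i + 1) % n_sectors])  # wraps when end < start
            color = white if (i % 2 == 0) == first_white else red
            sectors.append((start, end, color))
        return ColonyAppearance(
            center=center,
            radius=radius,
            base_color=white,
            phenotype=phenotype,
            sector_pattern=sectors,
        )
    # bad_segmentation: 2-4 mutually overlapping small disks, one component
    n_sub = int(rng.integers(2, 5))
    base_model = models[
        (ColonyPhenotype.WHITE, ColonyPhenotype.RED, ColonyPhenotype.PINK)[
            rng.integers(0, 3)
        ]
    ]
    main_r = radius * 0.75
    cluster: list[tuple[float, float, float, tuple[float, float, float]]] = []
    placed = [(0.0, 0.0, main_r)]
    for _ in range(n_sub - 1):
        anchor = placed[rng.integers(0, len(placed))]
        sub_r = radius * rng.uniform(0.5, 0.75)
        angle = rng.uniform(0.0, 2 * np.pi)
        dist = (anchor[2] + sub_r) * rng.uniform(0.55, 0.85)  # guarantees overlap
        dr = anchor[0] + dist * math.sin(angle)
        dc = anchor[1] + dist * math.cos(angle)
        m = spec.color_models[
            (ColonyPhenotype.WHITE, ColonyPhenotype.RED, ColonyPhenotype.PINK)[
                rng.integers(0, 3)
            ]
        ]
        cluster.append((dr, dc, sub_r, _jittered(m.mean_rgb, m.jitter, rng)))
        placed.append((dr, dc, sub_r))
    return ColonyAppearance(
        center=center,
        radius=main_r,
        base_color=_jittered(base_model.mean_rgb, base_model.jitter, rng),
        phenotype=ColonyPhenotype.BAD_SEGMENTATION,
        cluster=cluster,
    )


def _draw_center(spec: SynthPlateSpec, extent: float, rng: np.random.Generator):
    c = (spec.image_size - 1) / 2.0
    margin = spec.plate_radius - extent - spec.rim_thickness - 2.0
    margin = max(margin, 1.0)
    while True:
        dr, dc = rng.uniform(-margin, margin, size=2)
        if dr * dr + dc * dc <= margin * margin:
            return (c + dr, c + dc)


def _paint_disk(img, mask, center, radius, color, shade=True):
    h, w = mask.shape
    r0 = max(int(center[0] - radius) - 1, 0)
    r1 = min(int(center[0] + radius) + 2, h)
    c0 = max(int(center[1] - radius) - 1, 0)
    c1 = min(int(center[1] + radius) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - center[0], cc - center[1])
    cover = np.clip(radius + 0.5 - d, 0.0, 1.0)  # antialiased edge
    inside = cover > 0.5
    col = np.asarray(color, dtype=float)
    if shade:
        dome = 1.0 - 0.18 * np.clip(d / max(radius, 1e-6), 0, 1) ** 2
    else:
        dome = 1.0
    patch = img[r0:r1, c0:c1]
    blend = cover[..., None]
    patch[...] = patch * (1 - blend) + (col * np.atleast_3d(dome)) * blend
    mask[r0:r1, c0:c1] |= inside
    return (rr, cc, d, inside, (r0, r1, c0, c1))


def _paint_colony(img, mask, app: ColonyAppearance):
    res = _paint_disk(img, mask, app.center, app.radius, app.base_color)
    if app.sector_pattern and res is not None:
        rr, cc, d, inside, (r0, r1, c0, c1) = res
        theta = np.mod(np.arctan2(rr - app.center[0], cc - app.center[1]), 2 * np.pi)
        bounds = np.array([s[0] for s in app.sector_pattern])
        order = np.argsort(bounds)
        sorted_bounds = bounds[order]
        colors = np.array([app.sector_pattern[i][2] for i in order])
        idx = np.searchsorted(sorted_bounds, theta, side="right") - 1
        idx[idx < 0] = len(sorted_bounds) - 1
        dome = 1.0 - 0.18 * np.clip(d / max(app.radius, 1e-6), 0, 1) ** 2
        sel = inside
        patch = img[r0:r1, c0:c1]
        patch[sel] = colors[idx[sel]] * dome[sel, None]
    if app.ring_morphology and res is not None:
        rr, cc, d, inside, (r0, r1, c0, c1) = res
        ring = inside & (d >= 0.72 * app.radius)
        img[r0:r1, c0:c1][ring] = np.asarray(app.ring_color)
    for dr, dc, r, color in app.cluster:
        _paint_disk(img, mask, (app.center[0] + dr, app.center[1] + dc), r, color)


def render_plate(
    spec: SynthPlateSpec, rng: np.random.Generator
) -> tuple[np.ndarray, GroundTruth]:
    """Render one plate image (uint8 RGB) and its ground truth.

    Colonies are placed by rejection sampling; unless the spec allows
    overlap, centers keep a clearance of the summed radii plus a small gap.
    Raises if the requested count cannot be placed after bounded retries.
    """
    size = spec.image_size
    img = np.tile(BACKGROUND_RGB, (size, size, 1)).astype(float)
    mask = np.zeros((size, size), dtype=bool)

    c = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    d = np.hypot(rr - c, cc - c)
    plate = d <= spec.plate_radius
    img[plate] = AGAR_RGB

    if spec.edge_artifact:
        # bright rim whose outer edge runs past the frame so edge artefacts
        # touch the image border (removable by border clearing downstream)
        outer = spec.plate_radius + spec.rim_thickness + max(2.0, 0.02 * size)
        rim = (d >= spec.plate_radius - 0.5) & (d <= outer)
        img[rim] = RIM_RGB

    if isinstance(spec.n_colonies, tuple):
        n = int(rng.integers(spec.n_colonies[0], spec.n_colonies[1] + 1))
    else:
        n = int(spec.n_colonies)

    probs = spec.mixture_probs
    colonies: list[ColonyAppearance] = []
    gap = max(2.0, 0.015 * size)
    attempts = 0
    max_attempts = 400 * max(n, 1)
    while len(colonies) < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n} colonies within {max_attempts} attempts; "
                "reduce n_colonies or colony radii"
            )
        attempts += 1
        phenotype = CLASS_ORDER[rng.choice(5, p=probs)]
        app = sample_colony(phenotype, spec, rng)
        if spec.overlap_probability > 0 and rng.uniform() < spec.overlap_probability:
            colonies.append(app)
            continue
        ok = all(
            math.hypot(app.center[0] - o.center[0], app.center[1] - o.center[1])
            >= app.extent + o.extent + gap
            for o in colonies
        )
        if ok:
            colonies.append(app)

    for app in colonies:
        _paint_colony(img, mask, app)

    # smooth illumination gradient across the plate
    if spec.illumination_amplitude > 0:
        angle = rng.uniform(0.0, 2 * np.pi)
        ramp = ((rr - c) * math.sin(angle) + (cc - c) * math.cos(angle)) / size
        img *= 1.0 + spec.illumination_amplitude * ramp[..., None]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    image = np.clip(img, 0, 255).astype(np.uint8)
    counts = {name: 0 for name in CLASS_NAMES}
    for app in colonies:
        counts[app.phenotype.value] += 1
    truth = GroundTruth(mask=mask, colonies=colonies, true_nonwhite_pct=nonwhite_percentage(counts))
    return image, truth


def allocate_counts(total: int, weights) -> np.ndarray:
    """Apportion ``total`` items to classes by largest remainder.

    Ties in the fractional remainders break toward the earlier class in
    ``CLASS_ORDER`` (lower index).
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    raw = total * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    if rem > 0:
        frac = raw - base
        order = np.lexsort((np.arange(len(w)), -frac))
        base[order[:rem]] += 1
    return base


def _spread_indices(n_items: int, n_pick: int) -> np.ndarray:
    """``n_pick`` distinct indices spread evenly over ``range(n_items)``."""
    if n_pick <= 0:
        return np.array([], dtype=int)
    if n_pick >= n_items:
        return np.arange(n_items)
    if n_pick == 1:
        return np.array([0])
    return np.round(np.linspace(0, n_items - 1, n_pick)).astype(int)


def _validation_indices(n_items: int, fraction: float = 0.2) -> np.ndarray:
    return _spread_indices(n_items, int(round(fraction * n_items)))


def generate_plate_dataset(
    spec: SynthPlateSpec,
    n_plates: int,
    out_dir,
    seed: int,
    class_mixtures=None,
) -> pd.DataFrame:
    """Write ``n_plates`` plate image / mask pairs plus a CSV manifest.

    Images are 8-bit JPEG, masks single-channel PNG (0 background / 255
    foreground).  About 20% of plates are flagged as the validation split.
    ``class_mixtures`` optionally overrides the class mixture per plate
    (sequence of 5-weight tuples), e.g. to span non-white fractions.
    Re-running with identical arguments reproduces the files byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    val_idx = set(_validation_indices(n_plates).tolist())
    rows = []
    for i in range(n_plates):
        plate_spec = spec
        if class_mixtures is not None:
            plate_spec = SynthPlateSpec(**{**spec.__dict__, "class_mixture": tuple(class_mixtures[i])})
        rng = np.random.default_rng([seed, 0, i])
        image, truth = render_plate(plate_spec, rng)
        plate_id = f"plate_{i:04d}"
        img_path = out_dir / f"{plate_id}.jpg"
        mask_path = out_dir / f"{plate_id}_mask.png"
        Image.fromarray(image).save(img_path, quality=95)
        Image.fromarray((truth.mask * 255).astype(np.uint8)).save(mask_path)
        counts = truth.class_counts()
        rows.append(
            {
                "plate_id": plate_id,
                "image_path": img_path.name,
                "mask_path": mask_path.name,
                "split": "valid" if i in val_idx else "train",
                **{f"n_{k}" if k != "bad_segmentation" else "n_bad": v for k, v in counts.items()},
                "true_nonwhite_pct": truth.true_nonwhite_pct,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _render_crop(app: ColonyAppearance, spec: SynthPlateSpec, rng: np.random.Generator) -> np.ndarray:
    """Render a single colony centered on an agar patch (pipeline-style crop)."""
    extent = app.extent
    side = max(int(math.ceil(2.4 * extent)) + 2, 8)
    img = np.tile(AGAR_RGB, (side, side, 1)).astype(float)
    mask = np.zeros((side, side), dtype=bool)
    centered = ColonyAppearance(
        center=((side - 1) / 2.0, (side - 1) / 2.0),
        radius=app.radius,
        base_color=app.base_color,
        phenotype=app.phenotype,
        sector_pattern=app.sector_pattern,
        ring_morphology=app.ring_morphology,
        ring_color=app.ring_color,
        cluster=app.cluster,
    )
    _paint_colony(img, mask, centered)
    if spec.illumination_amplitude > 0:
        img *= 1.0 + rng.uniform(-spec.illumination_amplitude, spec.illumination_amplitude)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_crop_dataset(
    spec: SynthPlateSpec,
    n_crops: int,
    class_proportions,
    out_dir,
    seed: int,
) -> pd.DataFrame:
    """Write ``n_crops`` labeled single-colony JPEGs plus a CSV manifest.

    Class counts follow ``class_proportions`` by largest-remainder
    apportionment; the ~20% validation split is stratified so each class
    appears in the validation set at the same proportion as in the pool.
    """
    props = np.asarray(class_proportions, dtype=float)
    if props.shape != (5,) or (props < 0).any() or props.sum() <= 0:
        raise ValueError("class_proportions must be 5 nonnegative weights, not all zero")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = allocate_counts(n_crops, props)
    for name, p, c in zip(CLASS_NAMES, props, counts):
        if p > 0 and c == 0:
            warnings.warn(
                f"class {name!r} has positive weight but 0 crops at n={n_crops}; "
                "dropped from split stratification",
                stacklevel=2,
            )
    val_total = int(round(0.2 * n_crops))
    val_quota = allocate_counts(val_total, counts) if val_total > 0 else np.zeros(5, int)

    rows = []
    crop_index = 0
    for cls_i, (phenotype, n_cls) in enumerate(zip(CLASS_ORDER, counts)):
        val_within = set(_spread_indices(n_cls, int(val_quota[cls_i])).tolist())
        for j in range(n_cls):
            rng = np.random.default_rng([seed, 1, crop_index])
            app = sample_colony(phenotype, spec, rng)
            crop = _render_crop(app, spec, rng)
            name = f"crop_{crop_index:05d}_{phenotype.value}.jpg"
            Image.fromarray(crop).save(out_dir / name, quality=95)
            rows.append(
                {
                    "crop_path": name,
                    "label": phenotype.value,
                    "split": "valid" if j in val_within else "train",
                }
            )
            crop_index += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "labels.csv", index=False)
    return manifest
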