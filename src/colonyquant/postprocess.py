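"""Mask post-processing: from a predicted foreground mask to colony crops.

The predicted mask is cleaned (border clearing removes plate-rim
artefacts, morphological opening removes speckle), connected components
are labelled and measured, and regions are kept only if they are round
enough (eccentricity <= 0.6) and large enough (area >= 400 px at full
resolution) — single, well-segmented colonies.  Kept regions are cropped
out of the color image for classification, retaining plate provenance.

Coordinates are 0-based; bounding boxes are half-open [min, max).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.measure import label as _sk_label
from skimage.measure import regionprops
from skimage.morphology import disk as _sk_disk
from skimage.morphology import opening as _sk_opening
from skimage.segmentation import clear_border as _sk_clear_border
from skimage.transform import resize as _sk_resize

from .segmentation import PlateImage

__all__ = [
    "Region",
    "ColonyCrop",
    "center_crop_resize",
    "resize_mask_to_original",
    "clear_border",
    "morphological_open",
    "label_regions",
    "filter_regions",
    "crop_colonies",
    "ECC_MAX_DEFAULT",
    "AREA_MIN_DEFAULT",
]

#: Inclusive roundness/size selection thresholds for single colonies,
#: stated at full (1024 px) working resolution.
ECC_MAX_DEFAULT = 0.6
AREA_MIN_DEFAULT = 400


@dataclass(frozen=True)
class Region:
    """One labelled connected component of a binary mask."""

    region_id: int
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open
    area: int
    eccentricity: float
    centroid: tuple[float, float]
    plate_id: str = ""


@dataclass
class ColonyCrop:
    """A cropped single-colony RGB image with its provenance."""

    pixels: np.ndarray  # h x w x 3 uint8
    plate_id: str
    region_id: int
    bbox: tuple[int, int, int, int]

    def __post_init__(self):
        if self.pixels.ndim != 3 or min(self.pixels.shape[:2]) < 1:
            raise ValueError("crop must be a non-empty h x w x 3 array")
        if not self.plate_id:
            raise ValueError("crop must record its plate_id")

    @property
    def name(self) -> str:
        return f"{self.plate_id}__{self.region_id}.jpg"


def center_crop_resize(image: PlateImage | np.ndarray, target_size: int) -> PlateImage:
    """Center-crop to the largest square, then resample to ``target_size``."""
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    px = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    plate_id = image.plate_id if isinstance(image, PlateImage) else ""
    h, w = px.shape[:2]
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    sq = px[r0 : r0 + side, c0 : c0 + side]
    if side != target_size:
        sq = (_sk_resize(sq, (target_size, target_size), order=1, preserve_range=True) + 0.5).astype(
            np.uint8
        )
    return PlateImage(pixels=np.ascontiguousarray(sq), plate_id=plate_id)


def resize_mask_to_original(mask: np.ndarray, original_dims: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a boolean mask to the original dimensions."""
    h, w = original_dims
    if h <= 0 or w <= 0:
        raise ValueError("original_dims must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape == (h, w):
        return mask.copy()
    return _sk_resize(mask.astype(np.float32), (h, w), order=0, preserve_range=True) > 0.5


def clear_border(mask: np.ndarray) -> np.ndarray:
    """Remove every connected component touching any image edge."""
    return _sk_clear_border(np.asarray(mask, dtype=bool))


def morphological_open(mask: np.ndarray, radius: int) -> np.ndarray:
    """Opening (erosion then dilation) with a disk structuring element."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return _sk_opening(np.asarray(mask, dtype=bool), _sk_disk(radius))


def label_regions(mask: np.ndarray, plate_id: str = "") -> list[Region]:
    """Label 8-connected components and measure area, bbox, eccentricity.

    Eccentricity is that of the ellipse with the same normalized second
    central moments as the component: sqrt(1 - (minor/major)^2), 0 for a
    perfect disk.
    """
    lab = _sk_label(np.asarray(mask, dtype=bool), connectivity=2)
    regions = []
    for rp in regionprops(lab):
        regions.append(
            Region(
                region_id=int(rp.label),
                bbox=tuple(int(v) for v in rp.bbox),
                area=int(rp.area),
                eccentricity=float(rp.eccentricity),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                plate_id=plate_id,
            )
        )
    return regions


def filter_regions(
    regions: list[Region],
    ecc_max: float = ECC_MAX_DEFAULT,
    area_min: int = AREA_MIN_DEFAULT,
) -> tuple[list[Region], list[Region]]:
    """Partition regions into (kept, rejected) single-colony candidates.

    Both thresholds are inclusive: a region is kept iff
    eccentricity <= ecc_max and area >= area_min.
    """
    if not (np.isfinite(ecc_max) and np.isfinite(area_min)):
        raise ValueError("thresholds must be finite")
    kept = [r for r in regions if r.eccentricity <= ecc_max and r.area >= area_min]
    rejected = [r for r in regions if not (r.eccentricity <= ecc_max and r.area >= area_min)]
    return kept, rejected


def crop_colonies(
    image: PlateImage | np.ndarray,
    kept: list[Region],
    padding: int | None = None,
    plate_id: str = "",
) -> list[ColonyCrop]:
    """Crop each kept region from the color image, bbox expanded by padding.

    ``padding=None`` uses 10% of the larger bbox side (per region),
    clipped to the image bounds.  An empty region list yields an empty
    crop list, not an error.
    """
    px = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    pid = image.plate_id if isinstance(image, PlateImage) else plate_id
    h, w = px.shape[:2]
    crops = []
    for region in kept:
        r0, c0, r1, c1 = region.bbox
        pad = padding
        if pad is None:
            pad = int(round(0.1 * max(r1 - r0, c1 - c0)))
        rr0 = max(r0 - pad, 0)
        cc0 = max(c0 - pad, 0)
        rr1 = min(r1 + pad, h)
        cc1 = min(c1 + pad, w)
        crops.append(
            ColonyCrop(
                pixels=np.ascontiguousarray(px[rr0:rr1, cc0:cc1]),
                plate_id=pid or region.plate_id or "plate",
                region_id=region.region_id,
                bbox=(rr0, cc0, rr1, cc1),
            )
        )
    return crops
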