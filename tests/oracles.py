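"""Independent brute-force oracles for region measures and morphology.

These deliberately avoid scikit-image: components come from flood fill
over python sets, moments from explicit pixel-coordinate sums, and
morphology from direct set arithmetic over a structuring-element offset
list (outside-the-frame counts as foreground for erosion, background for
dilation — the standard binary-morphology convention).
"""

from __future__ import annotations

import numpy as np


def brute_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by flood fill."""
    remaining = {(int(r), int(c)) for r, c in zip(*np.nonzero(mask))}
    comps = []
    while remaining:
        seed = next(iter(remaining))
        stack, comp = [seed], set()
        remaining.discard(seed)
        while stack:
            r, c = stack.pop()
            comp.add((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (r + dr, c + dc)
                    if q in remaining:
                        remaining.discard(q)
                        stack.append(q)
        comps.append(comp)
    return comps


def brute_moments(comp: set[tuple[int, int]]):
    """Area, half-open bbox, centroid, moments-ellipse eccentricity."""
    pts = np.array(sorted(comp), dtype=float)
    area = len(pts)
    r0, c0 = pts.min(axis=0)
    r1, c1 = pts.max(axis=0)
    cy, cx = pts.mean(axis=0)
    dy, dx = pts[:, 0] - cy, pts[:, 1] - cx
    # normalized second central moments of the pixel-center point set
    mu20 = (dy**2).mean()
    mu02 = (dx**2).mean()
    mu11 = (dy * dx).mean()
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    l1 = (mu20 + mu02 + common) / 2
    l2 = (mu20 + mu02 - common) / 2
    ecc = float(np.sqrt(1 - l2 / l1)) if l1 > 0 else 0.0
    return area, (int(r0), int(c0), int(r1) + 1, int(c1) + 1), (cy, cx), ecc


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def brute_erode(mask: np.ndarray, offsets) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc]:
                    ok = False
                    break
                # outside the frame counts as foreground
            out[r, c] = ok
    return out


def brute_dilate(mask: np.ndarray, offsets) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r, c in zip(*np.nonzero(mask)):
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                out[rr, cc] = True
    return out


def brute_open(mask: np.ndarray, radius: int) -> np.ndarray:
    offsets = disk_offsets(radius)
    return brute_dilate(brute_erode(mask, offsets), offsets)


def brute_clear_border(mask: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    out = mask.copy()
    for comp in brute_components(mask):
        if any(r in (0, h - 1) or c in (0, w - 1) for r, c in comp):
            for r, c in comp:
                out[r, c] = False
    return out


def random_blob_mask(rng: np.random.Generator, size: int = 64, n_blobs: int = 3) -> np.ndarray:
    """Union of a few random rotated ellipses, for oracle comparisons."""
    mask = np.zeros((size, size), bool)
    rr, cc = np.mgrid[0:size, 0:size]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(8, size - 8, 2)
        ry, rx = rng.uniform(2, 7, 2)
        theta = rng.uniform(0, np.pi)
        y, x = rr - cy, cc - cx
        yr = y * np.cos(theta) + x * np.sin(theta)
        xr = -y * np.sin(theta) + x * np.cos(theta)
        mask |= (yr / ry) ** 2 + (xr / rx) ** 2 <= 1
    return mask
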