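"""Low-level binary image primitives.

These are the building blocks of both detection pipelines: luminance
conversion, Otsu thresholding, inverted binarization, binary morphology
(dilation, erosion, closing, opening), hole filling, connected-component
labeling, border clearing, area filtering and foreground counting.

Conventions
-----------
* Images are ``numpy`` arrays, row-major, 0-based; an RGB image is
  ``(H, W, 3)`` uint8, a grayscale image ``(H, W)`` uint8, a binary mask
  ``(H, W)`` with values in ``{0, 1}``.
* Morphology uses pad-with-zero border semantics: pixels outside the
  image are background, so border pixels erode unless fully supported.
* Foreground components use 8-connectivity by default; hole filling
  flood-fills the background with 4-connectivity (the standard dual).
* Pixel "area" is the raw count of foreground pixels; no sub-pixel
  correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DegenerateHistogramError, InvalidInputError

__all__ = [
    "ComponentStats",
    "LabeledMask",
    "square_se",
    "to_grayscale",
    "otsu_threshold",
    "binarize_inverted",
    "dilate",
    "erode",
    "close",
    "open_",
    "fill_holes",
    "label_components",
    "component_stats",
    "clear_border_objects",
    "area_filter",
    "count_foreground",
]

# ITU-R BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])

_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


class LabeledMask(NamedTuple):
    """Connected-component labeling of a binary mask.

    ``labels`` holds 0 for background and 1..n_components for foreground
    components, numbered by the row-major order of each component's
    first pixel.
    """

    labels: np.ndarray
    n_components: int
    connectivity: int = 8


@dataclass(frozen=True)
class ComponentStats:
    """Per-component geometry used by candidate filters and ranking."""

    label: int
    pixel_area: int
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open
    centroid: tuple[float, float]
    touches_border: bool

    @property
    def extent(self) -> float:
        r0, c0, r1, c1 = self.bbox
        return self.pixel_area / ((r1 - r0) * (c1 - c0))

    @property
    def aspect_ratio(self) -> float:
        """Bounding-box height / width."""
        r0, c0, r1, c1 = self.bbox
        return (r1 - r0) / (c1 - c0)


def square_se(size: int = 3) -> np.ndarray:
    """All-ones square structuring element with a centered origin."""
    if size < 1:
        raise InvalidInputError("structuring element size must be >= 1")
    return np.ones((size, size), dtype=bool)


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise InvalidInputError("mask must be a non-empty 2-D array")
    if not np.isin(mask, (0, 1)).all():
        raise InvalidInputError("mask values must be exactly 0 or 1")
    return mask.astype(bool)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luminance, rounded half-up and clamped to [0, 255]."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise InvalidInputError("expected a non-empty H x W x 3 image")
    y = img.astype(np.float64) @ _LUMA
    return np.clip(np.floor(y + 0.5), 0, 255).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram.

    Returns the smallest ``t`` in [0, 255] maximizing the between-class
    variance of the split into {<= t} and {> t}.  A constant image has
    no valid split and raises :class:`DegenerateHistogramError`.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise InvalidInputError("empty image")
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "image has a single intensity value; no threshold separates it"
        )
    n = hist.sum()
    omega = np.cumsum(hist) / n                      # class-0 mass for t = 0..255
    mu = np.cumsum(hist * np.arange(256)) / n        # partial means
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def binarize_inverted(img: np.ndarray, t: int) -> np.ndarray:
    """Inverted thresholding: dark pixels (<= t) become foreground 1."""
    if not 0 <= t <= 255:
        raise InvalidInputError("threshold must lie in [0, 255]")
    img = np.asarray(img)
    return (img <= t).astype(np.uint8)


def _se_offsets(se: np.ndarray) -> np.ndarray:
    se = np.asarray(se).astype(bool)
    if se.ndim != 2 or not se.any():
        raise InvalidInputError("structuring element must be non-empty and 2-D")
    origin = (se.shape[0] // 2, se.shape[1] // 2)
    rows, cols = np.nonzero(se)
    return np.stack([rows - origin[0], cols - origin[1]], axis=1)


def _shift(a: np.ndarray, dr: int, dc: int, fill: bool) -> np.ndarray:
    """Shift a 2-D boolean array by (dr, dc), padding with ``fill``."""
    h, w = a.shape
    out = np.full((h, w), fill, dtype=bool)
    rs_src = slice(max(0, -dr), min(h, h - dr))
    cs_src = slice(max(0, -dc), min(w, w - dc))
    rs_dst = slice(max(0, dr), min(h, h + dr))
    cs_dst = slice(max(0, dc), min(w, w + dc))
    out[rs_dst, cs_dst] = a[rs_src, cs_src]
    return out


def dilate(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Minkowski dilation with zero padding outside the image."""
    m = _as_mask(mask)
    out = np.zeros_like(m)
    for dr, dc in _se_offsets(se):
        out |= _shift(m, dr, dc, fill=False)
    return out.astype(np.uint8)


def erode(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Minkowski erosion; border pixels erode unless fully supported."""
    m = _as_mask(mask)
    out = np.ones_like(m)
    for dr, dc in _se_offsets(se):
        out &= _shift(m, -dr, -dc, fill=False)
    return out.astype(np.uint8)


def close(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Closing: dilation then erosion.  Idempotent and extensive.

    Computed on the zero-extended plane (the mask is padded before the
    dilation and cropped after the erosion), so foreground grown past
    the image edge still supports the erosion and ``close(X) >= X``
    holds pixelwise even at the border.
    """
    m = _as_mask(mask).astype(np.uint8)
    ph, pw = np.asarray(se).shape
    padded = np.pad(m, ((ph, ph), (pw, pw)))
    out = erode(dilate(padded, se), se)
    return out[ph:-ph, pw:-pw].astype(np.uint8)


def open_(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Opening: erosion then dilation.  Idempotent and anti-extensive."""
    return dilate(erode(mask, se), se)


def _flood(region: np.ndarray, seeds: np.ndarray, connectivity: int) -> np.ndarray:
    """Breadth-first reachable set inside ``region`` from boolean ``seeds``."""
    offsets = _OFFSETS_4 if connectivity == 4 else _OFFSETS_8
    h, w = region.shape
    visited = seeds & region
    frontier = np.nonzero(visited)
    fr, fc = frontier[0], frontier[1]
    while fr.size:
        cand_r = []
        cand_c = []
        for dr, dc in offsets:
            nr, nc = fr + dr, fc + dc
            ok = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
            cand_r.append(nr[ok])
            cand_c.append(nc[ok])
        nr = np.concatenate(cand_r)
        nc = np.concatenate(cand_c)
        keep = region[nr, nc] & ~visited[nr, nc]
        nr, nc = nr[keep], nc[keep]
        new = np.zeros_like(visited)
        new[nr, nc] = True        # scatter dedupes repeated frontier pixels
        visited |= new
        fr, fc = np.nonzero(new)
    return visited


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    m = _as_mask(mask)
    bg = ~m
    seeds = np.zeros_like(bg)
    seeds[0, :] = seeds[-1, :] = True
    seeds[:, 0] = seeds[:, -1] = True
    reachable = _flood(bg, seeds, connectivity=4)
    return (m | (bg & ~reachable)).astype(np.uint8)


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabeledMask:
    """Label maximal connected foreground sets.

    Components are numbered 1..n in the row-major order of their first
    (topmost-then-leftmost) pixel, which makes the labeling
    deterministic.
    """
    if connectivity not in (4, 8):
        raise InvalidInputError("connectivity must be 4 or 8")
    m = _as_mask(mask)
    labels = np.zeros(m.shape, dtype=np.int32)
    remaining = m.copy()
    n = 0
    flat = remaining.ravel()
    while True:
        idx = flat.argmax()
        if not flat[idx]:
            break
        n += 1
        seeds = np.zeros_like(m)
        seeds.ravel()[idx] = True
        comp = _flood(remaining, seeds, connectivity)
        labels[comp] = n
        remaining &= ~comp
        flat = remaining.ravel()
    return LabeledMask(labels=labels, n_components=n, connectivity=connectivity)


def component_stats(labeled: LabeledMask) -> list[ComponentStats]:
    """Geometry of every labeled component, ordered by label."""
    labels = labeled.labels
    h, w = labels.shape
    out = []
    for lab in range(1, labeled.n_components + 1):
        rows, cols = np.nonzero(labels == lab)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        out.append(
            ComponentStats(
                label=lab,
                pixel_area=int(rows.size),
                bbox=bbox,
                centroid=(float(rows.mean()), float(cols.mean())),
                touches_border=bool(
                    (rows == 0).any() or (rows == h - 1).any()
                    or (cols == 0).any() or (cols == w - 1).any()
                ),
            )
        )
    return out


def clear_border_objects(labeled: LabeledMask) -> np.ndarray:
    """Delete every component with at least one pixel on the image border."""
    labels = labeled.labels
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border_labels = border_labels[border_labels > 0]
    keep = (labels > 0) & ~np.isin(labels, border_labels)
    return keep.astype(np.uint8)


def area_filter(labeled: LabeledMask, min_area: int, max_area: float) -> np.ndarray:
    """Keep components with min_area <= pixel_area <= max_area (inclusive)."""
    if min_area < 0 or min_area > max_area:
        raise InvalidInputError("need 0 <= min_area <= max_area")
    labels = labeled.labels
    counts = np.bincount(labels.ravel(), minlength=labeled.n_components + 1)
    keep_lab = np.zeros(labeled.n_components + 1, dtype=bool)
    for lab in range(1, labeled.n_components + 1):
        keep_lab[lab] = min_area <= counts[lab] <= max_area
    return keep_lab[labels].astype(np.uint8)


def count_foreground(mask: np.ndarray) -> int:
    """Exact number of 1-valued pixels."""
    return int(_as_mask(mask).sum())
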