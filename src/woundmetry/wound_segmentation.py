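"""Wound boundary detection: CIELAB K-means segmentation.

The photograph is converted to the L*a*b* color space — which separates
lightness (L*) from opponent chroma (a*: green-red, b*: blue-yellow) —
and its pixels are clustered with K-means.  Clustering on chroma alone
(the default) keys the segmentation on color rather than illumination.
The cluster corresponding to the wound is selected (by default the one
with the highest mean a*, i.e. the reddest), the resulting mask is
cleaned by morphological opening and hole filling, and the wound
outline is traced with Moore-neighbor contour following.  The wound's
pixel area is the foreground count of the cleaned mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import color as _skcolor
from sklearn.cluster import KMeans

from . import binary_ops as bo
from .errors import (
    AmbiguousClusterError,
    DegenerateClusteringError,
    InvalidInputError,
)

__all__ = [
    "SegmentationConfig",
    "ClusterModel",
    "WoundDetection",
    "rgb_to_lab",
    "kmeans_cluster",
    "select_wound_cluster",
    "refine_mask",
    "trace_boundaries",
    "wound_pixel_area",
    "segment_wound",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the segmentation stage.

    ``k`` defaults to 3 (wound / skin / background).  ``feature_channels``
    defaults to chroma only; add ``"L"`` to cluster on lightness too.
    ``strategy`` is the wound-cluster identification rule: ``"max_a"``
    (reddest cluster), ``"manual"`` (``manual_id``), or ``"seed_point"``
    (cluster containing ``seed_point`` = (row, col)).
    """

    k: int = 3
    feature_channels: tuple[str, ...] = ("a", "b")
    seed: int = 0
    n_init: int = 10
    max_iter: int = 300
    strategy: str = "max_a"
    manual_id: int | None = None
    seed_point: tuple[int, int] | None = None
    se_size: int = 3
    keep_largest: bool = True
    tie_tolerance: float = 0.5  # a* units


@dataclass
class ClusterModel:
    """A converged K-means partition of the image's pixels.

    ``assignments`` is H x W with values in {0..k-1}; pixels excluded
    from clustering (e.g. under the fiducial sticker) hold -1.
    """

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    seed: int
    feature_channels: tuple[str, ...]


@dataclass
class WoundDetection:
    """Cleaned wound mask, traced outline, and exact pixel area."""

    mask: np.ndarray
    boundaries: list[np.ndarray]
    pixel_area: int
    cluster_id: int
    model: ClusterModel | None = None


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """sRGB (8-bit) -> CIELAB under the D65 white point."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError("expected an H x W x 3 sRGB image")
    return _skcolor.rgb2lab(img.astype(np.float64) / 255.0)


_CHANNEL_INDEX = {"L": 0, "a": 1, "b": 2}


def _features(lab: np.ndarray, channels: Sequence[str]) -> np.ndarray:
    try:
        idx = [_CHANNEL_INDEX[c] for c in channels]
    except KeyError as e:
        raise InvalidInputError(f"unknown feature channel {e.args[0]!r}") from e
    return lab[..., idx]


def kmeans_cluster(
    lab: np.ndarray,
    k: int = 3,
    seed: int = 0,
    cfg: SegmentationConfig | None = None,
    include: np.ndarray | None = None,
) -> ClusterModel:
    """Lloyd's K-means with k-means++ starts over the pixel features.

    ``include`` (optional boolean H x W) restricts clustering to a
    subset of pixels; excluded pixels are assigned -1.  The best of
    ``n_init`` restarts (lowest inertia) is kept, and the result is
    fully reproducible given ``seed``.
    """
    cfg = cfg or SegmentationConfig(k=k, seed=seed)
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    feats = _features(lab, cfg.feature_channels)
    h, w = feats.shape[:2]
    if include is None:
        include = np.ones((h, w), dtype=bool)
    X = feats[include].reshape(-1, len(cfg.feature_channels))
    if np.unique(X, axis=0).shape[0] < k:
        raise DegenerateClusteringError(
            f"k={k} exceeds the number of distinct feature vectors"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=cfg.n_init,
        max_iter=cfg.max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    assignments = np.full((h, w), -1, dtype=np.int32)
    assignments[include] = km.labels_
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=assignments,
        inertia=float(km.inertia_),
        seed=seed,
        feature_channels=tuple(cfg.feature_channels),
    )


def select_wound_cluster(
    model: ClusterModel,
    lab: np.ndarray,
    strategy: str = "max_a",
    manual_id: int | None = None,
    seed_point: tuple[int, int] | None = None,
    tie_tolerance: float = 0.5,
) -> int:
    """Identify the cluster holding the wound.

    ``"max_a"`` picks the cluster with the highest mean a* (wounds are
    red); an inter-cluster gap below ``tie_tolerance`` raises
    :class:`AmbiguousClusterError` so the caller can fall back to the
    manual strategy.
    """
    if strategy == "manual":
        if manual_id is None or not 0 <= manual_id < model.k:
            raise InvalidInputError("manual strategy needs a valid cluster id")
        return manual_id
    if strategy == "seed_point":
        if seed_point is None:
            raise InvalidInputError("seed_point strategy needs a (row, col) pixel")
        cid = int(model.assignments[seed_point])
        if cid < 0:
            raise InvalidInputError("seed point lies in an excluded region")
        return cid
    if strategy != "max_a":
        raise InvalidInputError(f"unknown strategy {strategy!r}")
    a_star = lab[..., 1]
    means = np.full(model.k, -np.inf)
    for cid in range(model.k):
        sel = model.assignments == cid
        if sel.any():
            means[cid] = a_star[sel].mean()
    order = np.argsort(means)[::-1]
    if model.k > 1 and means[order[0]] - means[order[1]] < tie_tolerance:
        raise AmbiguousClusterError(
            f"top clusters' mean a* within {tie_tolerance}; "
            "use the manual or seed_point strategy"
        )
    return int(order[0])


def refine_mask(
    raw: np.ndarray, se_size: int = 3, keep_largest: bool = True
) -> np.ndarray:
    """Opening (speck removal) + hole filling; optionally keep the
    largest connected component."""
    se = bo.square_se(se_size)
    cleaned = bo.fill_holes(bo.open_(raw, se))
    if keep_largest and cleaned.any():
        labeled = bo.label_components(cleaned, connectivity=8)
        if labeled.n_components > 1:
            counts = np.bincount(labeled.labels.ravel())
            counts[0] = 0
            cleaned = (labeled.labels == counts.argmax()).astype(np.uint8)
    return cleaned.astype(np.uint8)


# Clockwise Moore neighborhood in image coordinates (row grows downward).
_CLOCKWISE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def _moore_trace(comp: np.ndarray, start: tuple[int, int], back: tuple[int, int]):
    """Moore-neighbor contour following from ``start`` with initial
    backtrack ``back``; stops when the (pixel, backtrack) state repeats."""
    h, w = comp.shape
    contour = [start]
    seen = {(start, back)}
    cur = start
    cap = 4 * int(comp.sum()) + 8
    for _ in range(cap):
        d = (back[0] - cur[0], back[1] - cur[1])
        i = _CLOCKWISE.index(d)
        nxt = None
        for j in range(1, 9):
            dr, dc = _CLOCKWISE[(i + j) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if 0 <= cand[0] < h and 0 <= cand[1] < w and comp[cand]:
                pr, pc = _CLOCKWISE[(i + j - 1) % 8]
                nxt, back = cand, (cur[0] + pr, cur[1] + pc)
                break
        if nxt is None:  # isolated pixel
            break
        cur = nxt
        if (cur, back) in seen:
            break
        seen.add((cur, back))
        contour.append(cur)
    while len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return contour


def trace_boundaries(mask: np.ndarray) -> list[np.ndarray]:
    """Ordered outline(s) of every connected component, clockwise.

    Each component contributes its outer contour (and one contour per
    enclosed hole), starting from the row-major-first boundary pixel.
    The union of traced pixels equals the set of mask pixels with a
    non-mask 4-neighbor or on the image border.  Returns a list of
    (n, 2) integer arrays of (row, col) coordinates; empty mask -> [].
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return []
    labeled = bo.label_components(m.astype(np.uint8), connectivity=8)
    out = []
    for lab in range(1, labeled.n_components + 1):
        comp = labeled.labels == lab
        rows, cols = np.nonzero(comp)
        start = (int(rows[0]), int(cols[0]))  # row-major first pixel
        out.append(np.array(_moore_trace(comp, start, (start[0], start[1] - 1))))
        # inner contours around enclosed holes
        holes = bo.fill_holes(comp.astype(np.uint8)).astype(bool) & ~comp
        if holes.any():
            hole_lab = bo.label_components(holes.astype(np.uint8), connectivity=4)
            for hl in range(1, hole_lab.n_components + 1):
                hr, hc = np.nonzero(hole_lab.labels == hl)
                # pixel above a hole's topmost-leftmost pixel is foreground
                start = (int(hr[0]) - 1, int(hc[0]))
                out.append(
                    np.array(_moore_trace(comp, start, (start[0] + 1, start[1])))
                )
    return out


def wound_pixel_area(mask: np.ndarray) -> int:
    """Pixel count of the wound region (foreground count of the mask)."""
    return bo.count_foreground(mask)


def segment_wound(
    img: np.ndarray,
    cfg: SegmentationConfig = SegmentationConfig(),
    exclude_bbox: tuple[int, int, int, int] | None = None,
    exclude_margin: int = 0,
) -> WoundDetection:
    """Full segmentation chain: Lab -> K-means -> cluster pick -> refine
    -> trace.

    ``exclude_bbox`` (half-open, typically the detected fiducial's box)
    is masked out before clustering, expanded by ``exclude_margin``
    pixels, so the sticker cannot capture a cluster.
    """
    lab = rgb_to_lab(img)
    h, w = lab.shape[:2]
    include = np.ones((h, w), dtype=bool)
    if exclude_bbox is not None:
        r0, c0, r1, c1 = exclude_bbox
        g = exclude_margin
        include[max(0, r0 - g):r1 + g, max(0, c0 - g):c1 + g] = False
    model = kmeans_cluster(lab, k=cfg.k, seed=cfg.seed, cfg=cfg, include=include)
    cid = select_wound_cluster(
        model,
        lab,
        strategy=cfg.strategy,
        manual_id=cfg.manual_id,
        seed_point=cfg.seed_point,
        tie_tolerance=cfg.tie_tolerance,
    )
    raw = (model.assignments == cid).astype(np.uint8)
    mask = refine_mask(raw, se_size=cfg.se_size, keep_largest=cfg.keep_largest)
    return WoundDetection(
        mask=mask,
        boundaries=trace_boundaries(mask),
        pixel_area=wound_pixel_area(mask),
        cluster_id=cid,
        model=model,
    )
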