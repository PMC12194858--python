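"""Fiducial (QR-sticker) detection: the scale-reference half of the pipeline.

A printed patient-ID QR code of known physical size (default
1.2 cm x 1.2 cm) serves as a ruler inside each photograph.  The
detection chain is classical binary image processing:

    grayscale -> Otsu threshold -> inverted binarization -> closing
    -> connected components -> border clearing -> hole filling
    -> area filter -> candidate ranking

The QR code is never decoded; only its pixel footprint matters.  After
closing, the code's dark modules merge into (or enclose) one region
whose holes are filled, so the retained component is the full solid
square footprint of the sticker code.  Its pixel count divided by the
known physical area gives the image's scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import binary_ops as bo
from .errors import AmbiguousFiducialError, FiducialNotFoundError, InvalidInputError

__all__ = [
    "FiducialSpec",
    "FiducialConfig",
    "FiducialDetection",
    "rank_candidates",
    "detect_fiducial",
]


@dataclass(frozen=True)
class FiducialSpec:
    """Physical size of the printed fiducial square."""

    physical_side: float = 1.2  # cm

    def __post_init__(self):
        if self.physical_side <= 0:
            raise InvalidInputError("fiducial side must be positive")

    @property
    def physical_area(self) -> float:
        """Known physical area in cm^2 (side^2; 1.44 for the default)."""
        return self.physical_side**2


@dataclass(frozen=True)
class FiducialConfig:
    """Tunable knobs of the detection chain.

    ``area_range_mode``:
      * ``"relative"`` (default) — keep components whose area is within
        ``relative_range`` of the total image pixel count; appropriate
        when nothing is known about the shot distance.
      * ``"absolute"`` — keep areas within ``absolute_range`` pixels.
      * ``"prior"`` — keep areas within [0.5x, 2x] of ``prior_area_px``
        (a previous shot of the same sticker).
    """

    se_size: int = 3
    area_range_mode: str = "relative"
    relative_range: tuple[float, float] = (0.002, 0.25)
    absolute_range: tuple[float, float] = (0.0, math.inf)
    prior_area_px: float | None = None
    aspect_limits: tuple[float, float] = (0.75, 1.33)
    min_extent: float = 0.85

    def area_bounds(self, n_pixels: int) -> tuple[float, float]:
        if self.area_range_mode == "relative":
            lo, hi = self.relative_range
            return lo * n_pixels, hi * n_pixels
        if self.area_range_mode == "absolute":
            return self.absolute_range
        if self.area_range_mode == "prior":
            if not self.prior_area_px or self.prior_area_px <= 0:
                raise InvalidInputError("prior mode requires a positive prior_area_px")
            return 0.5 * self.prior_area_px, 2.0 * self.prior_area_px
        raise InvalidInputError(f"unknown area_range_mode {self.area_range_mode!r}")


@dataclass
class FiducialDetection:
    """The retained fiducial region and its exact pixel count."""

    mask: np.ndarray
    pixel_area: int
    spec: FiducialSpec
    bbox: tuple[int, int, int, int]
    candidate_stats: list[bo.ComponentStats] = field(default_factory=list)
    threshold: int = 0

    @property
    def px_per_cm(self) -> float:
        """Implied resolution, from the square-root of the area ratio."""
        return math.sqrt(self.pixel_area / self.spec.physical_area)


def _score(st: bo.ComponentStats) -> tuple[float, float, int]:
    # squareness first (|log aspect| so 2:1 and 1:2 rank alike), then
    # larger area; first-pixel order breaks residual ties upstream.
    return (abs(math.log(st.aspect_ratio)), -st.pixel_area, st.label)


def rank_candidates(
    stats: list[bo.ComponentStats],
    cfg: FiducialConfig = FiducialConfig(),
) -> int:
    """Pick the most square, most solid, largest candidate.

    Candidates failing the squareness window or the extent floor are
    set aside; if none pass, all candidates compete (the caller may
    still reject on area grounds).  An exact tie on (squareness, area)
    is resolved in row-major first-pixel order with a warning.
    """
    if not stats:
        raise InvalidInputError("rank_candidates requires at least one candidate")
    lo, hi = cfg.aspect_limits
    passing = [
        s for s in stats if lo <= s.aspect_ratio <= hi and s.extent >= cfg.min_extent
    ]
    pool = passing if passing else stats
    ranked = sorted(pool, key=_score)
    if len(ranked) > 1 and _score(ranked[0])[:2] == _score(ranked[1])[:2]:
        warnings.warn(
            "two fiducial candidates tie exactly; keeping the first in "
            "row-major order",
            stacklevel=2,
        )
    return ranked[0].label


def detect_fiducial(
    img: np.ndarray,
    spec: FiducialSpec = FiducialSpec(),
    cfg: FiducialConfig = FiducialConfig(),
    *,
    return_steps: bool = False,
):
    """Run the full fiducial-isolation chain on an RGB photograph.

    Returns a :class:`FiducialDetection` whose ``pixel_area`` is the
    exact foreground count of the retained solid square.  Raises
    :class:`FiducialNotFoundError` when no component survives the
    filters and :class:`AmbiguousFiducialError` when the ranking ties
    exactly.

    With ``return_steps=True`` also returns an ordered dict of the
    intermediate images (for step-by-step visualization).
    """
    gray = bo.to_grayscale(img)
    t = bo.otsu_threshold(gray)
    inverted = bo.binarize_inverted(gray, t)
    se = bo.square_se(cfg.se_size)
    closed = bo.close(inverted, se)
    labeled = bo.label_components(closed, connectivity=8)
    cleared = bo.clear_border_objects(labeled)
    solid = bo.fill_holes(cleared)
    relabeled = bo.label_components(solid, connectivity=8)
    stats = bo.component_stats(relabeled)

    lo, hi = cfg.area_bounds(gray.size)
    filtered = [s for s in stats if lo <= s.pixel_area <= hi]
    if not filtered:
        raise FiducialNotFoundError(
            f"no interior component with area in [{lo:.0f}, {hi:.0f}] px "
            f"(had {len(stats)} candidates)",
            candidate_stats=stats,
        )

    scores = sorted(_score(s) for s in filtered)
    if len(scores) > 1 and scores[0][:2] == scores[1][:2]:
        raise AmbiguousFiducialError(
            "two candidates tie exactly under the ranking score",
            candidate_stats=filtered,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chosen = rank_candidates(filtered, cfg)
    chosen_stats = next(s for s in filtered if s.label == chosen)
    mask = (relabeled.labels == chosen).astype(np.uint8)
    det = FiducialDetection(
        mask=mask,
        pixel_area=bo.count_foreground(mask),
        spec=spec,
        bbox=chosen_stats.bbox,
        candidate_stats=stats,
        threshold=t,
    )
    if return_steps:
        steps = {
            "grayscale": gray,
            "inverted_binary": inverted,
            "closed": closed,
            "border_cleared": cleared,
            "hole_filled": solid,
            "fiducial_mask": mask,
        }
        return det, steps
    return det
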