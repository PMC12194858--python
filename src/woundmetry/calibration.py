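"""Pixel-ratio scale calibration.

The core identity of the method:

    actual area [cm^2] = object pixel area x fiducial physical area
                                           / fiducial pixel area

Because both pixel areas scale identically with camera distance, the
quotient — and hence the physical estimate — is distance-invariant.

Reported values follow the truncation convention: quotients are
truncated (toward zero) at 4 decimals, percent differences rounded to
1 decimal.  Full precision is retained internally; truncation applies
only to reported figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import InvalidInputError

__all__ = [
    "Measurement",
    "truncate",
    "compute_ratio",
    "actual_area",
    "validate_against_reference",
    "coin_validation",
    "ONE_CENT_COIN_AREA_CM2",
]

# Published reference area of a US one-cent coin.
ONE_CENT_COIN_AREA_CM2 = 2.8488


def truncate(x: float, decimals: int = 4) -> float:
    """Truncate toward zero at the given number of decimals."""
    scale = 10**decimals
    return math.trunc(x * scale) / scale


def compute_ratio(object_px: float, fiducial_px: float, *, reported: bool = False) -> float:
    """Object-to-fiducial pixel-area ratio.

    With ``reported=True`` the quotient is truncated at 4 decimals,
    the convention used for printed figures.
    """
    if fiducial_px <= 0:
        raise InvalidInputError("fiducial pixel area must be positive")
    r = object_px / fiducial_px
    return truncate(r) if reported else r


def actual_area(
    object_px: float, fiducial_px: float, fiducial_area: float, *, reported: bool = False
) -> float:
    """Physical area in cm^2 via the pixel-ratio identity."""
    if fiducial_px <= 0 or fiducial_area <= 0:
        raise InvalidInputError("fiducial pixel area and physical area must be positive")
    a = object_px * fiducial_area / fiducial_px
    return truncate(a) if reported else a


def validate_against_reference(estimate: float, reference: float) -> float:
    """Percent difference |reference - estimate| / reference x 100,
    rounded to 1 decimal for reporting."""
    if reference <= 0:
        raise InvalidInputError("reference area must be positive")
    return round(abs(reference - estimate) / reference * 100.0, 1)


@dataclass(frozen=True)
class Measurement:
    """A calibrated area measurement of one photographed object."""

    wound_pixel_area: int
    fiducial_pixel_area: int
    fiducial_physical_area: float
    source: str = ""

    def __post_init__(self):
        if self.fiducial_pixel_area <= 0:
            raise InvalidInputError("fiducial pixel area must be positive")

    @property
    def ratio(self) -> float:
        return compute_ratio(self.wound_pixel_area, self.fiducial_pixel_area)

    @property
    def actual_area_cm2(self) -> float:
        return actual_area(
            self.wound_pixel_area, self.fiducial_pixel_area, self.fiducial_physical_area
        )

    def as_row(self) -> dict:
        """One serializable record (CSV/JSON row)."""
        return {
            "source": self.source,
            "wound_px": self.wound_pixel_area,
            "fiducial_px": self.fiducial_pixel_area,
            "fiducial_cm2": self.fiducial_physical_area,
            "ratio": truncate(self.ratio),
            "actual_cm2": truncate(self.actual_area_cm2),
        }


def coin_validation(
    pixel_pairs: Sequence[tuple[float, float]],
    fiducial_area: float = 1.44,
    reference: float = ONE_CENT_COIN_AREA_CM2,
) -> dict:
    """Reference-coin validation arithmetic over repeated shots.

    For each (coin pixel area, fiducial pixel area) pair the truncated
    ratio is computed; the mean of those ratios (truncated) times the
    fiducial's physical area gives the coin's estimated area, compared
    against the known reference area as a percent difference.
    """
    if not pixel_pairs:
        raise InvalidInputError("at least one pixel pair is required")
    ratios = [compute_ratio(o, f, reported=True) for o, f in pixel_pairs]
    mean_ratio = truncate(sum(ratios) / len(ratios))
    estimate = truncate(mean_ratio * fiducial_area)
    return {
        "ratios": ratios,
        "mean_ratio": mean_ratio,
        "estimated_area_cm2": estimate,
        "reference_area_cm2": reference,
        "percent_difference": validate_against_reference(estimate, reference),
    }
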