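"""Calibrated activation bands and virtual-object placement.

A block's raw BOLD response is expressed as a percentage of the subject's
individual maximum (the calibration reference), then classified into three
bands: below 30% of maximum counts as insufficient (so simply stopping the
task never scores), 30-60% is weak activation ("L"), and above 60% is strong
activation ("U").  The relative percentage also drives the vertical position
of the subject's sphere in the visual field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .analysis import CalibrationProfile

__all__ = [
    "Band",
    "ActivationEstimate",
    "ObjectPosition",
    "relative_activation",
    "classify",
    "position_object",
    "estimate_block",
    "WEAK_THRESHOLD",
    "STRONG_THRESHOLD",
]

WEAK_THRESHOLD = 30.0
STRONG_THRESHOLD = 60.0


class Band(str, Enum):
    INSUFFICIENT = "insufficient"
    WEAK_L = "weak_L"
    STRONG_U = "strong_U"

    @property
    def region(self) -> str:
        return {"weak_L": "L", "strong_U": "U"}.get(self.value, "none")


@dataclass(frozen=True)
class ActivationEstimate:
    """One block's calibrated outcome."""

    block_index: int
    raw_response_percent: float
    relative_percent: float
    band: Band


@dataclass(frozen=True)
class ObjectPosition:
    object_id: str
    vertical_position: float  # 0 = bottom of field, 1 = top
    region: str  # "U", "L" or "none"


def relative_activation(raw_response_percent: float, profile: CalibrationProfile) -> float:
    """Raw block response as a percentage of the individual maximum.

    Not clipped: values above 100 (stronger than the localizer maximum) or
    below 0 are legitimate and classified as-is.
    """
    if profile.max_bold_percent <= 0:
        raise ValueError("calibration maximum must be positive")
    return 100.0 * raw_response_percent / profile.max_bold_percent


def classify(relative_percent: float) -> Band:
    """Band the relative activation: <30 insufficient, [30, 60] weak ("L"),
    >60 strong ("U")."""
    if math.isnan(relative_percent):
        raise ValueError("cannot classify NaN activation")
    if relative_percent < WEAK_THRESHOLD:
        return Band.INSUFFICIENT
    if relative_percent <= STRONG_THRESHOLD:
        return Band.WEAK_L
    return Band.STRONG_U


def position_object(
    band: Band, relative_percent: float, object_id: str = "sphere"
) -> ObjectPosition:
    """Continuous sphere placement: relative percent / 100 clipped to [0, 1];
    the region label follows the band."""
    pos = min(1.0, max(0.0, relative_percent / 100.0))
    return ObjectPosition(object_id=object_id, vertical_position=pos, region=band.region)


def estimate_block(
    block_index: int, raw_response_percent: float, profile: CalibrationProfile
) -> ActivationEstimate:
    """Raw response -> relative percent -> band, as one record."""
    rel = relative_activation(raw_response_percent, profile)
    return ActivationEstimate(
        block_index=block_index,
        raw_response_percent=raw_response_percent,
        relative_percent=rel,
        band=classify(rel),
    )
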