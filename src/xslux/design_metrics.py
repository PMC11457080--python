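"""Irradiance-design metrics for characterizing a growth-light environment.

Two summaries are provided: the U2 uniformity ratio (minimum/maximum
irradiance over measured growing positions) and the daily light integral
(DLI), the total photon dose per day in mol m^-2 d^-1 delivered by a given
mean irradiance (umol m^-2 s^-1) over a photoperiod (hours).

The DLI is reported to two decimals. Published DLI values are sometimes
truncated rather than rounded (e.g. a raw 9.828 printed as 9.82), so the
caller selects the mode explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["IrradianceGrid", "uniformity_u2", "daily_light_integral"]


@dataclass
class IrradianceGrid:
    """Irradiance measurements (umol m^-2 s^-1) at growing positions."""

    position_ids: Sequence[str]
    irradiance: Sequence[float]
    photoperiod_h: float = 12.0

    def __post_init__(self) -> None:
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if len(self.position_ids) != len(self.irradiance):
            raise ValueError("position_ids and irradiance lengths differ")
        if (self.irradiance <= 0).any():
            raise ValueError("irradiances must be positive")
        if not 0 < self.photoperiod_h <= 24:
            raise ValueError("photoperiod must be in (0, 24] hours")


def uniformity_u2(grid: IrradianceGrid) -> float:
    """U2 uniformity = minimum/maximum irradiance over positions (in (0, 1])."""
    if len(grid.irradiance) < 2:
        raise ValueError("U2 requires at least 2 measured positions")
    return float(grid.irradiance.min() / grid.irradiance.max())


def daily_light_integral(
    mean_irradiance: float, photoperiod_h: float, rounding: str = "round2"
) -> float:
    """Daily light integral in mol m^-2 d^-1, reported to two decimals.

    DLI = mean_irradiance [umol m^-2 s^-1] x photoperiod [h] x 3600 / 1e6,
    then rounded (``round2``) or truncated (``trunc2``) to 2 decimals.
    """
    if mean_irradiance <= 0 or photoperiod_h <= 0:
        raise ValueError("mean irradiance and photoperiod must be positive")
    if photoperiod_h > 24:
        raise ValueError("photoperiod exceeds 24 h")
    raw = mean_irradiance * photoperiod_h * 3600.0 / 1e6
    if rounding == "round2":
        return float(np.round(raw, 2))
    if rounding == "trunc2":
        # guard against float representation just below the true value
        return math.floor(raw * 100 + 1e-9) / 100.0
    raise ValueError(f"unknown rounding mode {rounding!r}")
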