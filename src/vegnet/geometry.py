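"""Almucantar scan geometry: range-to-height conversion and plot footprint."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .lad import HINGE_ZENITH_DEG

__all__ = ["InstrumentGeometry", "FootprintArea", "height_from_range", "footprint_area"]

M2_PER_HECTARE = 10_000.0


@dataclass(frozen=True)
class InstrumentGeometry:
    """Fixed-position scanning geometry.

    Attributes
    ----------
    zenith : float
        Constant scan zenith angle in degrees (default the 57.5 deg hinge).
    instrument_height_above_ground : float
        Height of the scan head above ground, m.  Profile heights are
        reported above the instrument datum (z = 0 at the scan head);
        add this offset for above-ground reporting.
    max_detect_range : float
        Maximum slant range at which live foliage returns a valid range
        (night-time operation), m.  Beyond it, interceptions appear as gaps.
    """

    zenith: float = HINGE_ZENITH_DEG
    instrument_height_above_ground: float = 1.5
    max_detect_range: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 < self.zenith < 90.0):
            raise ValueError(f"zenith must be in (0, 90) deg, got {self.zenith}")
        if self.instrument_height_above_ground < 0:
            raise ValueError("instrument height above ground must be >= 0")
        if self.max_detect_range <= 0:
            raise ValueError("max detect range must be > 0")

    @property
    def cos_zenith(self) -> float:
        return float(np.cos(np.radians(self.zenith)))

    @property
    def max_profile_height(self) -> float:
        """Height ceiling of useful profiling: cos(zenith) * max range."""
        return self.cos_zenith * self.max_detect_range


class FootprintArea(NamedTuple):
    area_m2: float
    area_ha: float


def height_from_range(
    d, geom: InstrumentGeometry = InstrumentGeometry(), *, above_ground: bool = False
):
    """Height of a target at slant range ``d`` (m), assuming flat ground.

    h = cos(zenith) * d, above the instrument datum by default; with
    ``above_ground=True`` the instrument mounting height is added.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("range must be >= 0")
    h = geom.cos_zenith * d
    if above_ground:
        h = h + geom.instrument_height_above_ground
    return h if h.ndim else float(h)


def footprint_area(
    canopy_height: float,
    rule: str = "2h",
    *,
    zenith: float = HINGE_ZENITH_DEG,
) -> FootprintArea:
    """Circular plot area sampled by a full-azimuth scan in a canopy of
    uniform height H.

    Two radius rules are supported:

    ``2h``
        radius = 2 H — the rule of thumb that the beam exits the canopy at
        a horizontal distance of twice the canopy height (yields 1 ha for
        H = 28 m).
    ``tangent``
        radius = H tan(zenith) — the exact horizontal distance at which a
        beam launched at ``zenith`` reaches height H (tan 57.5 deg = 1.57,
        so this is smaller than the 2H rule).

    Returns the area in both m^2 and hectares.
    """
    if canopy_height <= 0:
        raise ValueError("canopy height must be > 0")
    if rule == "2h":
        radius = 2.0 * canopy_height
    elif rule == "tangent":
        radius = canopy_height * float(np.tan(np.radians(zenith)))
    else:
        raise ValueError(f"unknown footprint rule {rule!r}; use '2h' or 'tangent'")
    area = float(np.pi * radius**2)
    return FootprintArea(area_m2=area, area_ha=area / M2_PER_HECTARE)
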