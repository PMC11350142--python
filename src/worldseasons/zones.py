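"""Climate zonation: desert, arctic/high-montane, tropical, temperate.

Each land cell is assigned exactly one of four climate zones by a fixed
decision sequence:

1. DESERT if the annual Aridity Index (total precipitation over total
   potential evapotranspiration) falls below ``desert_ai_thresh``.  Aridity is
   tested first so that cold arid regions (dry tundra, Tibetan plateau, Gobi)
   classify as deserts rather than arctic.
2. else ARCTIC_MONTANE if the mean monthly minimum temperature never exceeds
   ``arctic_tmin_ceiling`` (a frost is possible in any month).
3. else TROPICAL if the intra-annual precipitation range is high, the
   intra-annual temperature range is low, and the coldest month stays warm
   (ocean-moderated cold coasts are excluded by the last test).
4. else TEMPERATE.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .climate import ClimateStack, PixelClimate, extract_pixel

__all__ = ["Zone", "ZoneThresholds", "annual_aridity", "classify_zone", "zone_map"]


class Zone(IntEnum):
    """Climate zone with stable raster codes (0 is reserved for nodata)."""

    DESERT = 1
    ARCTIC_MONTANE = 2
    TROPICAL = 3
    TEMPERATE = 4


@dataclass(frozen=True)
class ZoneThresholds:
    """Threshold constants of the zonation rules.

    ``precip_diff_thresh`` (mm) and ``temp_diff_thresh`` (°C) are the two
    tunable tropical gates (intra-annual ranges of precipitation and
    temperature); the tuned default is 81.972 mm / 7.52 °C.  The other
    three are fixed: coldest-month midpoint temperature of at least 18 °C for
    the tropics, a 10 °C ceiling on monthly-mean minimum temperature for the
    arctic, and the 0.2 arid/semi-arid Aridity Index boundary for deserts.
    """

    precip_diff_thresh: float = 81.972
    temp_diff_thresh: float = 7.52
    tropical_min_temp: float = 18.0
    arctic_tmin_ceiling: float = 10.0
    desert_ai_thresh: float = 0.2

    def __post_init__(self) -> None:
        if not (self.precip_diff_thresh > 0 and self.temp_diff_thresh > 0):
            raise ValueError("thresholds must be positive")


def annual_aridity(pixel: PixelClimate) -> float:
    """Annual Aridity Index: total precipitation / total PET (unitless)."""
    pet_sum = float(pixel.pet.sum())
    if pet_sum <= 0:
        raise ValueError("annual PET is zero: aridity undefined for this pixel")
    return float(pixel.precip.sum()) / pet_sum


def classify_zone(pixel: PixelClimate, th: ZoneThresholds | None = None) -> Zone:
    """Assign one climate zone to a pixel by the fixed decision sequence."""
    th = th or ZoneThresholds()
    if annual_aridity(pixel) < th.desert_ai_thresh:
        return Zone.DESERT
    if np.max(pixel.tmin) <= th.arctic_tmin_ceiling:
        return Zone.ARCTIC_MONTANE
    if (
        np.ptp(pixel.precip) > th.precip_diff_thresh
        and np.ptp(pixel.tmid) < th.temp_diff_thresh
        and np.min(pixel.tmid) >= th.tropical_min_temp
    ):
        return Zone.TROPICAL
    return Zone.TEMPERATE


def zone_map(stack: ClimateStack, th: ZoneThresholds | None = None) -> np.ndarray:
    """Per-cell zonation of a stack: uint8 grid of zone codes, 0 where masked."""
    th = th or ZoneThresholds()
    h, w = stack.shape
    out = np.zeros((h, w), dtype=np.uint8)
    # vectorized translation of classify_zone over the whole grid
    precip = stack.layers["precip"]
    pet = stack.layers["pet"]
    tmin = stack.layers["tmin"]
    tmid = (stack.layers["tmin"] + stack.layers["tmax"]) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = precip.sum(axis=0) / pet.sum(axis=0)
    desert = ai < th.desert_ai_thresh
    arctic = tmin.max(axis=0) <= th.arctic_tmin_ceiling
    tropical = (
        (np.ptp(precip, axis=0) > th.precip_diff_thresh)
        & (np.ptp(tmid, axis=0) < th.temp_diff_thresh)
        & (tmid.min(axis=0) >= th.tropical_min_temp)
    )
    out[:] = Zone.TEMPERATE
    out[tropical] = Zone.TROPICAL
    out[arctic] = Zone.ARCTIC_MONTANE
    out[desert] = Zone.DESERT
    out[~stack.mask] = 0
    bad = stack.mask & ~np.isfinite(ai)
    if bad.any():
        # zero-PET cells cannot be zoned; fall back to the scalar path's error
        r, c = np.argwhere(bad)[0]
        extract_pixel(stack, int(c), int(r))  # raises if masked
        raise ValueError(f"annual PET is zero at (col={c}, row={r})")
    return out
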