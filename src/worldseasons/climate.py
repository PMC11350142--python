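"""Monthly climate feature engineering.

Everything downstream of the raw rasters works on twelve-month vectors for a
single location (:class:`PixelClimate`) or on aligned twelve-band grids
(:class:`ClimateStack`).  The derived features are the ones the classifier
consumes: the temperature midpoint ``(tmin + tmax) / 2``, monthly aridity
``precip / pet``, and circular month-over-month lags (January minus December
for the first month), which carry the size and direction of monthly change in
temperature, precipitation and vegetation greenness (NDVI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

MONTHS = 12
#: floor applied to PET when forming the monthly aridity ratio, in mm
PET_EPS = 0.1

__all__ = [
    "PixelClimate",
    "ClimateStack",
    "midpoint_temperature",
    "monthly_from_weekly",
    "circular_lag",
    "znormalize",
    "read_monthly_stack",
    "extract_pixel",
]


def _as12(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (MONTHS,):
        raise ValueError(f"{name} must have exactly {MONTHS} monthly values, got shape {v.shape}")
    return v


def midpoint_temperature(tmin, tmax) -> np.ndarray:
    """Midpoint between the monthly minimum and maximum temperature, °C."""
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if tmin.shape != tmax.shape:
        raise ValueError("tmin and tmax must have equal length")
    bad = ~(np.isfinite(tmin) & np.isfinite(tmax))
    if bad.any():
        raise ValueError(f"non-finite temperature at month index {int(np.argmax(bad))}")
    return (tmin + tmax) / 2.0


def monthly_from_weekly(values, dates) -> np.ndarray:
    """Aggregate a dated (e.g. weekly) series to twelve climatological monthly means.

    Each observation counts wholly toward the calendar month containing its
    timestamp; observations from multiple years pool into a single mean per
    month.  Months with no observations yield NaN rather than raising.
    """
    values = np.asarray(values, dtype=float)
    months = pd.DatetimeIndex(pd.to_datetime(dates)).month
    if len(values) != len(months):
        raise ValueError("values and dates must have equal length")
    out = np.full(MONTHS, np.nan)
    s = pd.Series(values).groupby(np.asarray(months)).mean()
    out[s.index.to_numpy() - 1] = s.to_numpy()
    return out


def circular_lag(v) -> np.ndarray:
    """Circular first difference: ``lag[m] = v[m] - v[m-1]``, January wrapping to December.

    The twelve lags of any series telescope to zero around the annual cycle.
    """
    v = _as12(v, "series")
    if not np.isfinite(v).all():
        raise ValueError("circular_lag requires 12 finite values")
    return v - np.roll(v, 1)


def znormalize(v) -> np.ndarray:
    """Z-score a twelve-month vector with the sample (n-1) standard deviation.

    Zero-variance or all-missing input normalizes to zeros instead of NaN, so
    degenerate series (e.g. NDVI over barren ground) drop out of the distance
    computation rather than poisoning it.
    """
    v = np.asarray(v, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        return np.zeros_like(v)
    mu = v[ok].mean()
    sd = v[ok].std(ddof=1) if ok.sum() > 1 else 0.0
    # relative tolerance: a constant vector's sd is float noise, not variance
    if not np.isfinite(sd) or sd <= 1e-13 * float(np.abs(v[ok]).max()):
        return np.zeros_like(v)
    z = np.where(ok, (v - mu) / sd, 0.0)
    return z


@dataclass
class PixelClimate:
    """Twelve-month climate of one grid cell plus the derived classifier features.

    All vectors are indexed January..December.  ``tmid`` is the temperature
    midpoint, ``aridity`` the monthly precipitation/PET ratio (PET floored at
    :data:`PET_EPS` mm), and the ``lag_*`` fields circular first differences.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    srad: np.ndarray
    ndvi: np.ndarray
    pet: np.ndarray
    tmid: np.ndarray = field(init=False)
    aridity: np.ndarray = field(init=False)
    lag_tmid: np.ndarray = field(init=False)
    lag_ndvi: np.ndarray = field(init=False)
    lag_precip: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("tmin", "tmax", "precip", "srad", "ndvi", "pet"):
            setattr(self, name, _as12(getattr(self, name), name))
        both = np.isfinite(self.tmin) & np.isfinite(self.tmax)
        if (self.tmin[both] > self.tmax[both]).any():
            raise ValueError("tmin exceeds tmax")
        self.tmid = midpoint_temperature(self.tmin, self.tmax)
        self.aridity = self.precip / np.maximum(self.pet, PET_EPS)
        self.lag_tmid = circular_lag(self.tmid)
        self.lag_precip = circular_lag(self.precip)
        ndvi = np.where(np.isfinite(self.ndvi), self.ndvi, 0.0)
        self.lag_ndvi = circular_lag(ndvi)


#: raw per-variable layers a complete stack must carry
STACK_VARIABLES = ("tmin", "tmax", "precip", "srad", "ndvi", "pet")


@dataclass
class ClimateStack:
    """Aligned twelve-band grids for every raw climate variable.

    ``layers[var]`` has shape ``(12, height, width)`` in calendar band order;
    ``mask`` is True on valid (land) cells; ``transform`` is the affine
    ``(a, b, c, d, e, f)`` mapping (col, row) -> (x, y) as in GDAL, and ``crs``
    a CRS label (``"EPSG:4326"`` by default).
    """

    layers: Mapping[str, np.ndarray]
    mask: np.ndarray
    transform: tuple = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        missing = [v for v in STACK_VARIABLES if v not in self.layers]
        if missing:
            raise ValueError(f"climate stack is missing variables: {missing}")
        h, w = self.mask.shape
        for name, arr in self.layers.items():
            if arr.shape != (MONTHS, h, w):
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, expected {(MONTHS, h, w)}"
                )

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def xy(self, col, row):
        """Map pixel-center (col, row) to world coordinates."""
        a, b, c, d, e, f = self.transform
        col = np.asarray(col, dtype=float) + 0.5
        row = np.asarray(row, dtype=float) + 0.5
        return a * col + b * row + c, d * col + e * row + f


def extract_pixel(stack: ClimateStack, col: int, row: int) -> PixelClimate:
    """Pull one cell out of a stack as a :class:`PixelClimate` with derived fields."""
    h, w = stack.shape
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"(col={col}, row={row}) outside grid {w}x{h}")
    if not stack.mask[row, col]:
        raise ValueError(f"no data at (col={col}, row={row}): masked cell")
    return PixelClimate(**{v: stack.layers[v][:, row, col].copy() for v in STACK_VARIABLES})


def _bilinear_to_grid(src: np.ndarray, src_transform, dst_transform, dst_shape) -> np.ndarray:
    """Resample one band onto a destination grid by bilinear interpolation."""
    from scipy.ndimage import map_coordinates

    h, w = dst_shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    a, b, c, d, e, f = dst_transform
    x = a * (cols + 0.5) + b * (rows + 0.5) + c
    y = d * (cols + 0.5) + e * (rows + 0.5) + f
    sa, sb, sc, sd, se, sf = src_transform
    # invert the (diagonal-dominant) source affine; rotation terms unsupported
    if sb != 0 or sd != 0:
        raise ValueError("rotated source transforms are not supported")
    src_col = (x - sc) / sa - 0.5
    src_row = (y - sf) / se - 0.5
    return map_coordinates(src, [src_row, src_col], order=1, mode="nearest")


def read_monthly_stack(config: Mapping[str, str], target: str = "tmin") -> ClimateStack:
    """Read twelve-band GeoTIFFs into an aligned :class:`ClimateStack`.

    ``config`` maps variable name -> GeoTIFF path (12 bands, band m = month m).
    All variables are resampled bilinearly onto the grid of the ``target``
    variable when grids differ, then masked to the intersection of the
    per-variable nodata masks (the common land mask).
    """
    from .geotiff import read_geotiff

    missing = [v for v in STACK_VARIABLES if v not in config]
    if missing:
        raise ValueError(f"config is missing climate variables: {missing}")
    rasters = {}
    for var in STACK_VARIABLES:
        data, transform, crs, nodata = read_geotiff(config[var])
        if data.ndim == 2:
            data = data[None]
        if data.shape[0] != MONTHS:
            raise ValueError(f"{var}: expected {MONTHS} bands, found {data.shape[0]}")
        rasters[var] = (np.asarray(data, dtype=float), transform, crs, nodata)

    _, t_transform, t_crs, _ = rasters[target]
    shape = rasters[target][0].shape[1:]
    layers, mask = {}, np.ones(shape, dtype=bool)
    for var, (data, transform, crs, nodata) in rasters.items():
        if crs != t_crs:
            raise ValueError(f"{var}: CRS {crs!r} differs from target {t_crs!r}")
        if nodata is not None:
            data = np.where(data == nodata, np.nan, data)
        if transform != t_transform or data.shape[1:] != shape:
            data = np.stack(
                [_bilinear_to_grid(band, transform, t_transform, shape) for band in data]
            )
        layers[var] = data
        mask &= np.isfinite(data).all(axis=0)
    return ClimateStack(layers=layers, mask=mask, transform=t_transform, crs=t_crs)
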