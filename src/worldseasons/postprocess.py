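"""Post-processing of season rasters: focal smoothing, reprojection, output.

Near season boundaries the per-pixel classifier can flip between adjacent
labels across small regions.  A modal (majority) focal filter smooths each
month layer spatially; because the vote is spatial only, it can break a
pixel's temporal contiguity, so a per-pixel repair pass projects every
non-tropical pixel back onto its nearest contiguous calendar.  Finally the
categorical rasters can be reprojected to the equal-area Equal Earth
projection so that every cell covers the same ground area.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import linear_sum_assignment

from .clustering import (
    MONTHS,
    SeasonLabel,
    SeasonRaster,
    _contiguous_partitions,
    n_circular_runs,
)
from .equal_earth import equal_earth_forward, equal_earth_inverse
from .zones import Zone

__all__ = [
    "focal_smooth",
    "repair_contiguity",
    "reproject_equal_earth",
    "write_outputs",
]


def _modal_filter_layer(layer: np.ndarray, zones: np.ndarray, window: int) -> np.ndarray:
    """Majority vote over the window, restricted to same-zone neighbours.

    Nodata (code 0) and cells of a different climate zone do not vote; ties
    retain the centre value.
    """
    pad = window // 2
    lp = np.pad(layer, pad, constant_values=0)
    zp = np.pad(zones, pad, constant_values=0)
    lw = sliding_window_view(lp, (window, window))
    zw = sliding_window_view(zp, (window, window))
    same_zone = (zw == zones[:, :, None, None]) & (zones[:, :, None, None] != 0)
    votable = same_zone & (lw != 0)
    labels = np.unique(layer[layer != 0])
    if labels.size == 0:
        return layer.copy()
    counts = np.stack([((lw == lab) & votable).sum(axis=(-1, -2)) for lab in labels])
    best = counts.max(axis=0)
    center_idx = np.searchsorted(labels, layer)
    center_idx = np.clip(center_idx, 0, len(labels) - 1)
    center_count = np.take_along_axis(counts, center_idx[None], axis=0)[0]
    winner = labels[np.argmax(counts, axis=0)]
    out = np.where((layer != 0) & (center_count < best), winner, layer)
    return out.astype(layer.dtype)


def repair_contiguity(labels12: np.ndarray) -> np.ndarray:
    """Project one pixel's 12 month labels onto the nearest contiguous calendar.

    Keeps the same label set (one circular run each) while changing as few
    months as possible; ties resolve to the lexicographically first cut-set.
    Already-contiguous input returns unchanged.
    """
    labels12 = np.asarray(labels12)
    uniq = np.unique(labels12)
    k = len(uniq)
    if n_circular_runs(labels12) <= k:
        return labels12.copy()
    parts, _ = _contiguous_partitions(k)
    best = None
    for p in range(parts.shape[0]):
        arcs = parts[p]
        agree = np.zeros((k, k))
        for j in range(k):
            for i, lab in enumerate(uniq):
                agree[j, i] = np.sum((arcs == j) & (labels12 == lab))
        rows, cols = linear_sum_assignment(-agree)
        score = int(agree[rows, cols].sum())
        if best is None or score > best[0]:
            best = (score, p, cols)
    _, p, perm = best
    out = np.empty(MONTHS, dtype=labels12.dtype)
    for j in range(k):
        out[parts[p] == j] = uniq[perm[j]]
    return out


def focal_smooth(sr: SeasonRaster, window: int = 3, *, repair: bool = True) -> SeasonRaster:
    """Spatially smooth each month layer with a modal filter.

    ``window`` must be odd and at least 3.  With ``repair=True`` (default) a
    per-pixel pass restores circular contiguity for every non-tropical pixel
    afterwards, since the spatial vote knows nothing about the months.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    codes = np.stack([
        _modal_filter_layer(sr.codes[m], sr.zones, window) for m in range(MONTHS)
    ])
    if repair:
        fix = sr.mask & (sr.zones != int(Zone.TROPICAL)) & (sr.zones != 0)
        for r, c in zip(*np.nonzero(fix)):
            codes[:, r, c] = repair_contiguity(codes[:, r, c])
    return dataclasses.replace(sr, codes=codes, zones=sr.zones.copy(), mask=sr.mask.copy())


def reproject_equal_earth(
    data: np.ndarray,
    transform,
    src_crs: str = "EPSG:4326",
    *,
    nodata: float = 0,
    cellsize: float | None = None,
):
    """Nearest-neighbour reprojection of a lon/lat raster to Equal Earth.

    ``data`` is (h, w) or (bands, h, w) on a north-up geographic grid.
    Returns ``(out, out_transform, "EPSG:8857")``.  The target cell size in
    metres defaults to the metric width of a source cell at the equator, so
    the output resolution is comparable; every output cell covers the same
    ground area by construction of the projection.
    """
    if src_crs != "EPSG:4326":
        raise ValueError(f"unknown source CRS {src_crs!r}: expected EPSG:4326 lon/lat")
    data = np.asarray(data)
    squeeze = data.ndim == 2
    if squeeze:
        data = data[None]
    _, h, w = data.shape
    a, b, c, d, e, f = transform
    # project the grid corners to bound the target
    cols = np.array([0.0, w, 0.0, w, w / 2, 0.0, w, w / 2])
    rows = np.array([0.0, 0.0, h, h, 0.0, h / 2, h / 2, h])
    lon = a * cols + c
    lat = e * rows + f
    x, y = equal_earth_forward(lon, lat)
    if cellsize is None:
        cellsize = equal_earth_forward(np.array([abs(a)]), np.array([0.0]))[0][0]
    out_w = max(int(np.ceil((x.max() - x.min()) / cellsize)), 1)
    out_h = max(int(np.ceil((y.max() - y.min()) / cellsize)), 1)
    out_transform = (cellsize, 0.0, float(x.min()), 0.0, -cellsize, float(y.max()))
    oc, orr = np.meshgrid(np.arange(out_w), np.arange(out_h))
    ox = cellsize * (oc + 0.5) + x.min()
    oy = y.max() - cellsize * (orr + 0.5)
    lon_t, lat_t = equal_earth_inverse(ox, oy)
    valid = np.isfinite(lon_t) & np.isfinite(lat_t)
    src_col = np.round(np.nan_to_num((lon_t - c) / a - 0.5, nan=-1)).astype(int)
    src_row = np.round(np.nan_to_num((lat_t - f) / e - 0.5, nan=-1)).astype(int)
    inside = valid & (src_col >= 0) & (src_col < w) & (src_row >= 0) & (src_row < h)
    out = np.full((data.shape[0], out_h, out_w), nodata, dtype=data.dtype)
    sc = np.clip(src_col, 0, w - 1)
    sr_ = np.clip(src_row, 0, h - 1)
    for band in range(data.shape[0]):
        vals = data[band][sr_, sc]
        out[band] = np.where(inside, vals, nodata)
    if squeeze:
        out = out[0]
    return out, out_transform, "EPSG:8857"


def write_outputs(sr: SeasonRaster, outdir, *, equal_earth: bool = False) -> dict:
    """Write the standard output formats into ``outdir``.

    Produces ``seasons.tif`` (12 uint8 bands, one per month), ``zones.tif``
    (single uint8 band) and ``seasons.txt`` — a long-format table with
    columns x, y, month, season (canonical lowercase names) covering every
    valid cell.  Returns the written paths.
    """
    import pandas as pd
    from pathlib import Path

    from .geotiff import write_geotiff

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    codes, zones, transform, crs = sr.codes, sr.zones, sr.transform, sr.crs
    mask = sr.mask
    if equal_earth:
        stackin = np.concatenate([codes, zones[None]], axis=0)
        out, transform, crs = reproject_equal_earth(stackin, sr.transform, sr.crs)
        codes, zones = out[:MONTHS], out[MONTHS]
        mask = zones != 0

    season_path = outdir / "seasons.tif"
    zone_path = outdir / "zones.tif"
    text_path = outdir / "seasons.txt"
    write_geotiff(season_path, codes.astype(np.uint8), transform, crs, nodata=0)
    write_geotiff(zone_path, zones.astype(np.uint8), transform, crs, nodata=0)

    rows_idx, cols_idx = np.nonzero(mask)
    a, b, c, d, e, f = transform
    xs = a * (cols_idx + 0.5) + c
    ys = e * (rows_idx + 0.5) + f
    frames = []
    for m in range(MONTHS):
        lab = codes[m, rows_idx, cols_idx]
        frames.append(pd.DataFrame({
            "x": xs, "y": ys, "month": m + 1,
            "season": [SeasonLabel(v).name.lower() if v else "" for v in lab],
        }))
    pd.concat(frames, ignore_index=True).to_csv(text_path, index=False)
    return {"seasons": season_path, "zones": zone_path, "table": text_path}
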