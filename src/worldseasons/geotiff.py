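"""Minimal GeoTIFF reading and writing on top of tifffile.

Stores the north-up affine transform via the ModelPixelScale and
ModelTiepoint tags, the CRS as an EPSG code in the GeoKeyDirectory, and
nodata in the GDAL_NODATA ascii tag — the subset of GeoTIFF this package
needs for its own rasters.  Rotated transforms are out of scope.
"""

from __future__ import annotations

import numpy as np
import tifffile

__all__ = ["write_geotiff", "read_geotiff"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024        # 1 = projected, 2 = geographic
_KEY_RASTER_TYPE = 1025       # 1 = PixelIsArea
_KEY_GEOGRAPHIC_CRS = 2048
_KEY_PROJECTED_CRS = 3072

#: EPSG codes treated as geographic (lon/lat) rather than projected
_GEOGRAPHIC_EPSG = {4326, 4269, 4267}


def _epsg_from_crs(crs: str) -> int:
    crs = str(crs).upper().replace(" ", "")
    if crs in ("EQUAL-EARTH", "EQUALEARTH"):
        return 8857
    if not crs.startswith("EPSG:"):
        raise ValueError(f"unsupported CRS {crs!r}: expected 'EPSG:<code>'")
    return int(crs.split(":", 1)[1])


def write_geotiff(path, data, transform, crs: str = "EPSG:4326", nodata=None) -> None:
    """Write a single- or multi-band north-up GeoTIFF.

    ``data`` is (h, w) or (bands, h, w); ``transform`` the GDAL-style affine
    ``(a, b, c, d, e, f)`` with no rotation (b = d = 0) and e < 0.
    """
    data = np.asarray(data)
    a, b, c, d, e, f = (float(t) for t in transform)
    if b != 0 or d != 0:
        raise ValueError("rotated transforms are not supported")
    epsg = _epsg_from_crs(crs)
    if epsg in _GEOGRAPHIC_EPSG:
        keys = [(_KEY_MODEL_TYPE, 0, 1, 2), (_KEY_RASTER_TYPE, 0, 1, 1),
                (_KEY_GEOGRAPHIC_CRS, 0, 1, epsg)]
    else:
        keys = [(_KEY_MODEL_TYPE, 0, 1, 1), (_KEY_RASTER_TYPE, 0, 1, 1),
                (_KEY_PROJECTED_CRS, 0, 1, epsg)]
    directory = [1, 1, 0, len(keys)]
    for key in keys:
        directory.extend(key)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (a, -e, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0)),
        (_TAG_GEO_KEYS, "H", len(directory), tuple(directory)),
    ]
    if nodata is not None:
        nd = str(int(nodata)) if float(nodata).is_integer() else repr(float(nodata))
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd))
    tifffile.imwrite(
        str(path), data, photometric="minisblack", extratags=extratags, metadata=None
    )


def read_geotiff(path):
    """Read a GeoTIFF written by :func:`write_geotiff` (or compatible).

    Returns ``(data, transform, crs, nodata)`` with ``data`` of shape
    (bands, h, w) for multi-band files and (h, w) for single-band ones.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        tags = tif.pages[0].tags
        try:
            sx, sy, _ = tags[_TAG_PIXEL_SCALE].value[:3]
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as err:
            raise ValueError(f"{path}: not a GeoTIFF (missing tag {err})") from None
        ox, oy = float(tie[3]), float(tie[4])
        transform = (float(sx), 0.0, ox, 0.0, -float(sy), oy)
        crs = None
        if _TAG_GEO_KEYS in tags:
            d = list(tags[_TAG_GEO_KEYS].value)
            for i in range(4, len(d), 4):
                key, _, _, value = d[i:i + 4]
                if key in (_KEY_GEOGRAPHIC_CRS, _KEY_PROJECTED_CRS):
                    crs = f"EPSG:{value}"
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value.rstrip("\x00"))
    return data, transform, crs, nodata
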