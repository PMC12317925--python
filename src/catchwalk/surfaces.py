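"""Cost-surface input: raster reading/writing, slope, synthetic terrain.

The walker takes a single-band cost (friction) raster — in the demonstration
use-case, terrain slope in degrees.  This module reads and writes such
rasters as GeoTIFF (georeferencing carried in the standard GeoTIFF tags)
or ESRI ASCII grid (plain text), derives slope from a DEM with Horn's
3x3 finite-difference estimator, and generates synthetic cost surfaces with
the structure the walker is designed to exploit: smooth low-cost corridors
(valleys) embedded in high-cost walls (ridges), optionally ringed by NoData
margins.

Synthetic kinds
---------------
``tilted_plane``
    Cost increases linearly along a stated gradient; the walker's greedy
    descent direction is then unique everywhere, which makes walks exactly
    predictable (used for oracle tests).
``parabolic_valley``
    A low-cost trough along a vertical or horizontal axis with quadratic
    walls — the synthetic analogue of a river corridor flanked by slopes.
``random_field``
    Seeded, smoothly correlated Gaussian noise emulating a slope map of
    rolling terrain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
import tifffile

from .lattice import CostSurface

__all__ = [
    "SyntheticSpec",
    "read_cost_surface",
    "write_cost_surface",
    "slope_from_dem",
    "generate_surface",
]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

_NODATA_FILL = -9999.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic cost surface.

    ``params`` are kind-specific:

    * ``tilted_plane``: ``base`` (cost at the origin corner, default 0),
      ``gradient`` (gx, gy) in cost per map unit eastward / southward,
      default (1, 0).
    * ``parabolic_valley``: ``axis`` ("vertical" or "horizontal", default
      vertical), ``position`` (world coordinate of the trough axis; default
      the surface midline), ``base`` (trough cost, default 1.0),
      ``curvature`` (cost per squared map unit, default 0.01).
    * ``random_field``: ``mean`` (default 10.0 — a typical rolling-terrain
      slope in degrees), ``std`` (default 3.0), ``correlation_length``
      (map units, default 10 pixels).

    All kinds accept ``margin`` (integer >= 0): width in pixels of a NoData
    ring around the surface, emulating the clipped edges of real rasters.
    """

    kind: str
    shape: tuple[int, int]
    resolution: float
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("tilted_plane", "parabolic_valley", "random_field"):
            raise ValueError(f"unknown synthetic surface kind {self.kind!r}")
        rows, cols = self.shape
        if rows < 3 or cols < 3:
            raise ValueError("synthetic surface must be at least 3x3")
        if not (self.resolution > 0):
            raise ValueError("resolution must be > 0")


def generate_surface(
    spec: SyntheticSpec, origin: tuple[float, float] = (0.0, 0.0)
) -> CostSurface:
    """Deterministically generate the surface described by ``spec``."""
    rows, cols = spec.shape
    res = spec.resolution
    x0, y0 = origin
    xs = x0 + (np.arange(cols) + 0.5) * res
    ys = y0 - (np.arange(rows) + 0.5) * res
    xx, yy = np.meshgrid(xs, ys)
    p = dict(spec.params)
    margin = int(p.pop("margin", 0))

    if spec.kind == "tilted_plane":
        base = float(p.pop("base", 0.0))
        gx, gy = p.pop("gradient", (1.0, 0.0))
        values = base + gx * (xx - x0) + gy * (y0 - yy)
    elif spec.kind == "parabolic_valley":
        axis = p.pop("axis", "vertical")
        base = float(p.pop("base", 1.0))
        curv = float(p.pop("curvature", 0.01))
        if axis == "vertical":
            pos = float(p.pop("position", x0 + cols * res / 2.0))
            d = xx - pos
        elif axis == "horizontal":
            pos = float(p.pop("position", y0 - rows * res / 2.0))
            d = yy - pos
        else:
            raise ValueError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")
        values = base + curv * d**2
    else:  # random_field
        mean = float(p.pop("mean", 10.0))
        std = float(p.pop("std", 3.0))
        corr = float(p.pop("correlation_length", 10.0 * res))
        rng = np.random.default_rng(spec.seed)
        white = rng.standard_normal((rows, cols))
        sigma = corr / res
        smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
        s = smooth.std()
        if s > 0:
            smooth = (smooth - smooth.mean()) / s
        values = np.clip(mean + std * smooth, 0.0, None)
    if p:
        raise ValueError(f"unknown params for kind {spec.kind!r}: {sorted(p)}")

    mask = np.zeros((rows, cols), dtype=bool)
    if margin > 0:
        mask[:] = True
        mask[margin:-margin, margin:-margin] = False
    return CostSurface(
        values=values, resolution=res, origin=origin, nodata_mask=mask
    )


def slope_from_dem(dem: CostSurface) -> CostSurface:
    """Terrain slope in degrees from a DEM, by Horn's 3x3 estimator.

    ``slope = arctan(sqrt(p^2 + q^2))`` with ``p = dz/dx`` and ``q = dz/dy``
    from Horn's weighted central differences.  Elevations must share the
    linear unit of the cell resolution.  Border pixels and any pixel with
    NoData in its 3x3 window come out NoData; outputs lie in [0, 90).
    """
    nrow, ncol = dem.shape
    if nrow < 3 or ncol < 3:
        raise ValueError("slope_from_dem requires a grid of at least 3x3")
    z = dem.values
    res = dem.resolution
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8.0 * res)
    ky = kx.T
    p = ndimage.convolve(z, kx, mode="nearest")
    q = ndimage.convolve(z, ky, mode="nearest")
    slope = np.degrees(np.arctan(np.hypot(p, q)))

    bad = dem.nodata_mask.astype(float)
    window_bad = ndimage.maximum_filter(bad, size=3, mode="constant", cval=1.0) > 0
    mask = window_bad.copy()
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = True
    slope = np.where(mask, _NODATA_FILL, slope)
    return CostSurface(
        values=slope,
        resolution=res,
        origin=dem.origin,
        nodata_mask=mask,
        crs_id=dem.crs_id,
    )


# ---------------------------------------------------------------------------
# raster file I/O


def read_cost_surface(path: str | Path, band: int | None = None) -> CostSurface:
    """Read a single-band georeferenced raster (GeoTIFF or ESRI ASCII grid).

    Multi-band files are rejected unless ``band`` selects one (0-based);
    non-square pixels are rejected.  NoData is taken from the file header
    (GDAL_NODATA tag / NODATA_value field).
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"raster not found: {path}")
    if path.suffix.lower() in (".asc", ".agr", ".grd"):
        return _read_ascii_grid(path)
    return _read_geotiff(path, band)


def _read_geotiff(path: Path, band: int | None) -> CostSurface:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        if data.ndim == 3:
            if band is None:
                raise ValueError(
                    f"{path} has {data.shape[-1] if data.shape[-1] < data.shape[0] else data.shape[0]}"
                    " bands; select one with band="
                )
            data = data[band] if data.shape[0] < data.shape[-1] else data[..., band]
        elif len(tf.pages) > 1:
            if band is None:
                raise ValueError(f"{path} has {len(tf.pages)} bands; select one with band=")
            data = tf.pages[band].asarray()
        tags = page.tags
        scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise ValueError(f"{path} carries no GeoTIFF georeferencing tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise ValueError(f"{path} has non-square pixels ({sx} x {sy})")
        tp = tiepoint.value
        origin = (float(tp[3]) - float(tp[0]) * sx, float(tp[4]) + float(tp[1]) * sy)
        nodata = None
        nd_tag = tags.get(_TAG_GDAL_NODATA)
        if nd_tag is not None:
            nodata = float(str(nd_tag.value).strip())
        crs_id = _crs_from_geokeys(tags.get(_TAG_GEO_KEY_DIRECTORY))

    values = np.asarray(data, dtype=float)
    mask = np.zeros(values.shape, dtype=bool)
    if nodata is not None:
        mask = np.isclose(values, nodata) | ~np.isfinite(values)
    else:
        mask = ~np.isfinite(values)
    return CostSurface(
        values=np.where(mask, _NODATA_FILL, values),
        resolution=sx,
        origin=origin,
        nodata_mask=mask,
        crs_id=crs_id,
    )


def _crs_from_geokeys(tag) -> str | None:
    if tag is None:
        return None
    keys = np.asarray(tag.value).ravel()
    # directory entries are (key_id, location, count, value) quadruples
    for k in range(4, len(keys) - 3, 4):
        key_id, loc, _count, value = keys[k : k + 4]
        if key_id in (3072, 2048) and loc == 0:  # projected / geographic CS
            return f"EPSG:{int(value)}"
    return None


def _epsg_code(crs_id: str | None) -> int | None:
    if crs_id and crs_id.upper().startswith("EPSG:"):
        try:
            return int(crs_id.split(":", 1)[1])
        except ValueError:
            return None
    return None


def write_cost_surface(surface: CostSurface, path: str | Path) -> None:
    """Write a CostSurface as GeoTIFF (.tif) or ESRI ASCII grid (.asc)."""
    path = Path(path)
    if path.suffix.lower() in (".asc", ".agr", ".grd"):
        _write_ascii_grid(surface, path)
    else:
        write_geotiff(surface.values, surface, path, nodata=_NODATA_FILL,
                      mask=surface.nodata_mask)


def write_geotiff(
    values: np.ndarray,
    like: CostSurface,
    path: str | Path,
    nodata: float | None = None,
    mask: np.ndarray | None = None,
) -> None:
    """Write ``values`` as a single-band GeoTIFF on ``like``'s grid/CRS."""
    data = np.asarray(values)
    if mask is not None and nodata is not None:
        data = np.where(mask, nodata, data)
    res = like.resolution
    x0, y0 = like.origin
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    epsg = _epsg_code(like.crs_id)
    if epsg is not None:
        # minimal GeoKey directory: version 1.1.0, one projected-CS key
        extratags.append(
            (_TAG_GEO_KEY_DIRECTORY, "H", 8, (1, 1, 0, 1, 3072, 0, 1, epsg))
        )
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    tifffile.imwrite(
        Path(path), data, photometric="minisblack", extratags=extratags
    )


def _write_ascii_grid(surface: CostSurface, path: Path) -> None:
    nrow, ncol = surface.shape
    res = surface.resolution
    x0, y0 = surface.origin
    vals = np.where(surface.nodata_mask, _NODATA_FILL, surface.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {(y0 - nrow * res)!r}\n")
        fh.write(f"cellsize {res!r}\n")
        fh.write(f"NODATA_value {_NODATA_FILL!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_ascii_grid(path: Path) -> CostSurface:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ) and len(parts) == 2:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    try:
        ncol, nrow = int(header["ncols"]), int(header["nrows"])
        res = header["cellsize"]
        x0 = header["xllcorner"]
        yll = header["yllcorner"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing ASCII-grid header field {exc}") from exc
    values = np.asarray(rows, dtype=float).reshape(nrow, ncol)
    nodata = header.get("nodata_value")
    mask = (
        np.isclose(values, nodata) if nodata is not None
        else np.zeros(values.shape, bool)
    ) | ~np.isfinite(values)
    return CostSurface(
        values=np.where(mask, _NODATA_FILL, values),
        resolution=res,
        origin=(x0, yll + nrow * res),
        nodata_mask=mask,
    )
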