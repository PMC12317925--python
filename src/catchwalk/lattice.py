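"""Lattice geometry and neighbourhood cost aggregation.

The agent moves on a discrete lattice laid over a cost raster.  Two lattice
shapes are supported:

* ``square`` — a regular square grid with a Moore (8-cell) single-ring
  neighbourhood; cells are indexed ``(i, j)`` (row, column), row 0 at the
  north edge.
* ``hex`` — a pointy-top hexagonal grid in axial coordinates ``(q, r)``
  with a 6-cell single-ring neighbourhood.

The *neighbourhood cell size* ``nsize`` is the centre-to-centre distance
between adjacent cells: for squares the edge length, for hexagons the
spacing between adjacent hex centres (so every hex step has length exactly
``nsize``, while square steps are ``nsize`` orthogonally and ``nsize*sqrt(2)``
diagonally).

Each lattice cell aggregates the raster cost values whose pixel centres fall
inside its footprint; the cell's cost is the arithmetic mean of those values
(NoData excluded).  Membership on shared footprint boundaries follows a fixed
left/top-inclusive half-open rule so the lattice partitions the plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "CostSurface",
    "NeighbourhoodSpec",
    "LatticeCell",
    "neighbour_offsets",
    "cell_centre",
    "cell_footprint",
    "footprint_members",
    "aggregate_cell_cost",
    "neighbourhood_costs",
    "cell_containing",
]

SQRT3 = math.sqrt(3.0)

#: Fixed enumeration order of the 8 Moore offsets (row, col), clockwise from
#: north.  The order is part of the reproducibility contract: tie-breaking
#: draws an index into the candidate list, so seeded runs are bit-identical
#: across platforms only if this order never changes.
SQUARE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)

#: Fixed enumeration order of the 6 axial hex offsets (q, r), starting east
#: and proceeding clockwise on screen (pointy-top axial, +r pointing south).
HEX_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1),
)

Shape = Literal["square", "hex"]


class ConfigError(ValueError):
    """Invalid run or neighbourhood configuration."""


@dataclass(frozen=True)
class NeighbourhoodSpec:
    """Shape and cell size of the agent's decision catchment.

    Parameters
    ----------
    shape:
        ``"square"`` (Moore, 8 neighbours) or ``"hex"`` (6 neighbours).
    nsize:
        Neighbourhood cell size in map units (> 0): the centre-to-centre
        distance between adjacent lattice cells.
    """

    shape: Shape
    nsize: float

    def __post_init__(self) -> None:
        if self.shape not in ("square", "hex"):
            raise ConfigError(f"unknown neighbourhood shape {self.shape!r}")
        if not (self.nsize > 0):
            raise ConfigError(f"nsize must be > 0, got {self.nsize}")


@dataclass
class CostSurface:
    """A single-band cost/friction raster.

    Attributes
    ----------
    values:
        2-D float array of cost values (e.g. terrain slope in degrees).
    resolution:
        Square pixel edge length in map units (> 0).
    origin:
        World ``(x, y)`` of the grid's top-left corner; row 0 is the
        northernmost row, pixel centres at ``origin + (col+0.5, -(row+0.5))
        * resolution``.
    nodata_mask:
        Boolean array, True where the pixel is invalid.
    crs_id:
        Opaque coordinate-reference identifier (e.g. ``"EPSG:25830"``) or
        None.
    """

    values: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    crs_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("cost surface must be a non-empty 2-D grid")
        if not (self.resolution > 0):
            raise ValueError("resolution must be > 0")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape must match values")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-masked cost values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent in world units."""
        nrow, ncol = self.values.shape
        x0, y0 = self.origin
        return (x0, y0 - nrow * self.resolution, x0 + ncol * self.resolution, y0)

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of pixel-centre x (per column) and y (per row)."""
        nrow, ncol = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.resolution
        ys = y0 - (np.arange(nrow) + 0.5) * self.resolution
        return xs, ys

    def value_at(self, x: float, y: float) -> float | None:
        """Raster value at world point, or None when outside/NoData."""
        col = int(math.floor((x - self.origin[0]) / self.resolution))
        row = int(math.floor((self.origin[1] - y) / self.resolution))
        nrow, ncol = self.values.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            return None
        if self.nodata_mask[row, col]:
            return None
        return float(self.values[row, col])


@dataclass(frozen=True)
class LatticeCell:
    """A lattice cell: integer coords plus its derived world centre."""

    coords: tuple[int, int]
    centre: tuple[float, float] = field(compare=False)


def neighbour_offsets(shape: Shape) -> tuple[tuple[int, int], ...]:
    """Ordered single-ring neighbour offsets for a lattice shape.

    Square gives the 8 Moore offsets, hex the 6 axial unit offsets; the
    enumeration order is fixed (see module constants) because tie-breaking
    indexes into it.
    """
    if shape == "square":
        return SQUARE_OFFSETS
    if shape == "hex":
        return HEX_OFFSETS
    raise ConfigError(f"unknown neighbourhood shape {shape!r}")


def cell_centre(
    coords: tuple[int, int],
    spec: NeighbourhoodSpec,
    anchor: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float]:
    """World centre of the lattice cell at ``coords``.

    Square (i, j): ``anchor + ((j + 0.5) * nsize, -(i + 0.5) * nsize)``
    (north-up). Hex axial (q, r), pointy-top:
    ``x = anchor_x + nsize * (q + r / 2)``, ``y = anchor_y - nsize *
    (sqrt(3)/2) * r`` so all six neighbour centres lie exactly ``nsize``
    away.
    """
    s = spec.nsize
    ax, ay = anchor
    if spec.shape == "square":
        i, j = coords
        return (ax + (j + 0.5) * s, ay - (i + 0.5) * s)
    q, r = coords
    return (ax + s * (q + r / 2.0), ay - s * (SQRT3 / 2.0) * r)


def cell_containing(
    point: tuple[float, float],
    spec: NeighbourhoodSpec,
    anchor: tuple[float, float] = (0.0, 0.0),
) -> tuple[int, int]:
    """Integer coords of the lattice cell whose footprint contains ``point``.

    For hexes this rounds fractional axial coordinates to the nearest hex
    (cube rounding), which is exactly the Voronoi assignment.
    """
    s = spec.nsize
    dx = point[0] - anchor[0]
    dy = anchor[1] - point[1]  # positive southward
    if spec.shape == "square":
        return (int(math.floor(dy / s)), int(math.floor(dx / s)))
    # fractional axial coords then cube-round
    rf = dy / (s * SQRT3 / 2.0)
    qf = dx / s - rf / 2.0
    return _axial_round(qf, rf)


def _axial_round(qf: float, rf: float) -> tuple[int, int]:
    sf = -qf - rf
    q, r, sc = round(qf), round(rf), round(sf)
    dq, dr, ds = abs(q - qf), abs(r - rf), abs(sc - sf)
    if dq > dr and dq > ds:
        q = -r - sc
    elif dr > ds:
        r = -q - sc
    return (int(q), int(r))


def cell_footprint(
    coords: tuple[int, int],
    spec: NeighbourhoodSpec,
    anchor: tuple[float, float] = (0.0, 0.0),
) -> Polygon:
    """Footprint polygon of a lattice cell in world coordinates.

    Square cells are axis-aligned squares of side ``nsize``; hex cells are
    regular pointy-top hexagons with circumradius ``nsize / sqrt(3)``
    (the Voronoi cell of the triangular lattice of centres).
    """
    cx, cy = cell_centre(coords, spec, anchor)
    s = spec.nsize
    if spec.shape == "square":
        h = s / 2.0
        return Polygon(
            [(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)]
        )
    radius = s / SQRT3
    pts = []
    for k in range(6):
        ang = math.radians(90 + 60 * k)
        pts.append((cx + radius * math.cos(ang), cy + radius * math.sin(ang)))
    return Polygon(pts)


def footprint_members(
    surface: CostSurface, footprint: Polygon
) -> tuple[np.ndarray, np.ndarray]:
    """Raster (row, col) indices whose pixel centres lie inside ``footprint``.

    Boundary pixels are resolved with the half-open left/top-inclusive rule:
    a pixel centre lying exactly on a footprint edge belongs to the cell on
    whose left (west) or top (north) edge it sits.  Implemented by nudging
    test points infinitesimally east and south before the point-in-polygon
    test, which realises exactly that rule for any convex footprint.
    """
    xs, ys = surface.pixel_centres()
    xmin, ymin, xmax, ymax = footprint.bounds
    eps = 1e-9 * surface.resolution
    ci = np.nonzero((xs >= xmin - eps) & (xs <= xmax + eps))[0]
    ri = np.nonzero((ys >= ymin - eps) & (ys <= ymax + eps))[0]
    if ci.size == 0 or ri.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cc, rr = np.meshgrid(ci, ri)
    inside = shapely.contains_xy(
        footprint, xs[cc].ravel() + eps, ys[rr].ravel() - eps
    )
    return rr.ravel()[inside], cc.ravel()[inside]


def aggregate_cell_cost(surface: CostSurface, footprint: Polygon) -> float | None:
    """Mean cost of the raster values whose centres fall in ``footprint``.

    Returns the arithmetic mean of member values, NoData excluded.  When the
    footprint contains no pixel centre at all (cell smaller than a pixel),
    falls back to sampling the raster at the footprint centroid.  Returns
    ``None`` (the invalid marker) when no valid value is available — all
    members NoData, or footprint wholly outside the raster extent.
    """
    rows, cols = footprint_members(surface, footprint)
    if rows.size == 0:
        c = footprint.centroid
        eps = 1e-9 * surface.resolution  # same left/top-inclusive nudge
        return surface.value_at(c.x + eps, c.y - eps)
    valid = ~surface.nodata_mask[rows, cols]
    if not valid.any():
        return None
    return float(surface.values[rows[valid], cols[valid]].mean())


def _footprint_in_extent(
    coords: tuple[int, int],
    spec: NeighbourhoodSpec,
    anchor: tuple[float, float],
    surface: CostSurface,
) -> bool:
    cx, cy = cell_centre(coords, spec, anchor)
    if spec.shape == "square":
        hx = hy = spec.nsize / 2.0
    else:
        hx = spec.nsize / 2.0           # hex half-width (flat sides E/W)
        hy = spec.nsize / SQRT3         # hex circumradius (points N/S)
    xmin, ymin, xmax, ymax = surface.bounds
    tol = 1e-9 * surface.resolution
    return (
        cx - hx >= xmin - tol
        and cx + hx <= xmax + tol
        and cy - hy >= ymin - tol
        and cy + hy <= ymax + tol
    )


def neighbourhood_costs(
    surface: CostSurface,
    centre: tuple[int, int],
    spec: NeighbourhoodSpec,
    anchor: tuple[float, float] | None = None,
) -> dict[tuple[int, int], float]:
    """Aggregated cost of every valid single-ring neighbour of ``centre``.

    Returns a mapping ``offset -> mean cost`` in the fixed offset order.
    Neighbours whose footprint extends (even partly) beyond the raster
    extent are omitted, as are neighbours with no valid cost (all NoData).
    An empty mapping therefore means the agent is at the map edge with no
    legal move — the walker's termination condition.  ``anchor`` defaults
    to the raster origin, the package-wide lattice anchoring convention.
    """
    if anchor is None:
        anchor = surface.origin
    out: dict[tuple[int, int], float] = {}
    ci, cj = centre
    for di, dj in neighbour_offsets(spec.shape):
        coords = (ci + di, cj + dj)
        if not _footprint_in_extent(coords, spec, anchor, surface):
            continue
        cost = aggregate_cell_cost(surface, cell_footprint(coords, spec, anchor))
        if cost is not None:
            out[(di, dj)] = cost
    return out
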