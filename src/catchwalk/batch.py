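"""Batch execution of seeded walks and the aggregate walk-density raster.

A batch runs ``n_runs`` walks under one configuration.  Each walk draws its
randomness from an independent substream derived from ``(master_seed,
walk_index)``, so a batch is bit-reproducible regardless of execution
order.  The density raster counts, per raster pixel, how many *distinct*
walks crossed it: each walk's polyline of consecutive cell centres is
rasterised with a supercover line algorithm (every pixel the segment
passes through is marked) and contributes at most 1 per pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import CostSurface, NeighbourhoodSpec
from .walker import Walk, run_walk
from . import walkstats

__all__ = ["BatchConfig", "BatchResult", "run_batch", "density_raster"]


@dataclass(frozen=True)
class BatchConfig:
    """Run design for a batch of walks.

    ``start_mode`` is either a fixed world coordinate or the string
    ``"random"`` (each walk then starts in its own uniformly drawn valid
    cell).
    """

    spec: NeighbourhoodSpec
    n_runs: int
    n_steps: int
    start_mode: tuple[float, float] | str = "random"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 0 or self.n_steps < 0:
            raise ValueError("n_runs and n_steps must be >= 0")


@dataclass
class BatchResult:
    walks: list[Walk]
    density: np.ndarray
    stats_table: pd.DataFrame


def run_batch(surface: CostSurface, config: BatchConfig) -> BatchResult:
    """Execute ``n_runs`` seeded walks and aggregate density and statistics.

    Walk ``k`` uses the RNG substream seeded by ``(master_seed, k)``;
    rerunning with the same configuration reproduces every walk, the
    density grid and the statistics table bit-identically.
    """
    walks: list[Walk] = []
    for k in range(config.n_runs):
        rng = np.random.default_rng([config.master_seed, k])
        walks.append(
            run_walk(
                surface,
                config.spec,
                config.start_mode,
                config.n_steps,
                rng,
                seed_record=(config.master_seed, k),
            )
        )
    density = density_raster(walks, surface)
    stats = walkstats.stats_table(walks)
    return BatchResult(walks=walks, density=density, stats_table=stats)


def _supercover_pixels(
    p0: tuple[float, float], p1: tuple[float, float]
) -> list[tuple[int, int]]:
    """All integer grid cells a segment passes through (supercover).

    Coordinates are continuous pixel coordinates (pixel (r, c) spans
    [c, c+1) x [r, r+1)).  Uses parametric grid traversal; when the segment
    crosses a lattice corner exactly, both adjacent side cells are included
    (conservative, gap-free coverage).
    """
    x0, y0 = p0
    x1, y1 = p1
    cx, cy = math.floor(x0), math.floor(y0)
    ex, ey = math.floor(x1), math.floor(y1)
    cells = [(cy, cx)]
    dx, dy = x1 - x0, y1 - y0
    sx = 1 if dx > 0 else -1
    sy = 1 if dy > 0 else -1
    # parametric distance to the next vertical / horizontal pixel boundary
    tmax_x = math.inf if dx == 0 else ((cx + (sx > 0)) - x0) / dx
    tmax_y = math.inf if dy == 0 else ((cy + (sy > 0)) - y0) / dy
    tdx = math.inf if dx == 0 else abs(1.0 / dx)
    tdy = math.inf if dy == 0 else abs(1.0 / dy)
    guard = 0
    while (cx, cy) != (ex, ey):
        guard += 1
        if guard > 4 * (abs(ex - cx) + abs(ey - cy) + 2) + 8:
            break  # numerical stalemate; coverage so far is still gap-free
        if math.isclose(tmax_x, tmax_y, rel_tol=0.0, abs_tol=1e-12):
            # exact corner crossing: include both side cells
            cells.append((cy, cx + sx))
            cells.append((cy + sy, cx))
            cx += sx
            cy += sy
            tmax_x += tdx
            tmax_y += tdy
        elif tmax_x < tmax_y:
            cx += sx
            tmax_x += tdx
        else:
            cy += sy
            tmax_y += tdy
        cells.append((cy, cx))
    return cells


def density_raster(walks: list[Walk], surface: CostSurface) -> np.ndarray:
    """Per-pixel count of distinct walks crossing each raster pixel.

    Every segment between consecutive cell centres is rasterised onto the
    surface grid with supercover coverage; a walk increments a pixel at
    most once however many of its segments touch it.  Output is an integer
    grid aligned to ``surface.values``.
    """
    nrow, ncol = surface.shape
    density = np.zeros((nrow, ncol), dtype=np.int64)
    x0, y0 = surface.origin
    res = surface.resolution
    for walk in walks:
        touched: set[tuple[int, int]] = set()
        pts = [((x - x0) / res, (y0 - y) / res) for x, y in walk.centres]
        if len(pts) == 1:
            touched.add((math.floor(pts[0][1]), math.floor(pts[0][0])))
        for a, b in zip(pts[:-1], pts[1:]):
            touched.update(_supercover_pixels(a, b))
        for r, c in touched:
            if 0 <= r < nrow and 0 <= c < ncol:
                density[r, c] += 1
    return density
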