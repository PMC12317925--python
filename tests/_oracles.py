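"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's membership and selection code paths:
square membership is integer index arithmetic, hex membership is a
brute-force nearest-centre (Voronoi) search, and the greedy step is a plain
argmin.  They are slow and only suitable for tiny grids.
"""

import math

import numpy as np

SQRT3 = math.sqrt(3.0)


def square_members(surface, i, j, k):
    """Pixels of lattice cell (i, j) when nsize = k * resolution, anchored
    at the raster origin: the k x k index block."""
    return [(r, c) for r in range(i * k, (i + 1) * k) for c in range(j * k, (j + 1) * k)]


def hex_centre(q, r, s, anchor=(0.0, 0.0)):
    return (anchor[0] + s * (q + r / 2.0), anchor[1] - s * (SQRT3 / 2.0) * r)


def hex_members(surface, q, r, s, anchor=(0.0, 0.0)):
    """Pixels whose centre is nearer to hex (q, r) than to any other hex
    centre, found by exhaustive search over a generous axial range."""
    xs, ys = surface.pixel_centres()
    cx, cy = hex_centre(q, r, s, anchor)
    out = []
    half = s / 2.0 + surface.resolution
    for ri, y in enumerate(ys):
        if abs(y - cy) > s / SQRT3 + surface.resolution:
            continue
        for ci, x in enumerate(xs):
            if abs(x - cx) > half:
                continue
            best, best_d = None, math.inf
            for qq in range(q - 2, q + 3):
                for rr in range(r - 2, r + 3):
                    ox, oy = hex_centre(qq, rr, s, anchor)
                    d = (x - ox) ** 2 + (y - oy) ** 2
                    if d < best_d - 1e-12:
                        best, best_d = (qq, rr), d
            if best == (q, r):
                out.append((ri, ci))
    return out


def greedy_walk(surface, shape, nsize, start_cell, n_steps, anchor=(0.0, 0.0)):
    """Greedy minimum-mean-cost walk with visited exclusion.

    Stops (truncates) at the first tie within 1e-9, at the first all-visited
    situation, or when no candidate footprint is fully inside the extent —
    i.e. exactly where the walker's behaviour becomes random.  Returns the
    deterministic prefix of the path.
    """
    res = surface.resolution
    nrow, ncol = surface.shape
    xmin, ymin, xmax, ymax = surface.bounds

    if shape == "square":
        offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
        k = int(round(nsize / res))

        def cost(cell):
            mem = square_members(surface, *cell, k)
            vals = [surface.values[r, c] for r, c in mem if not surface.nodata_mask[r, c]]
            return float(np.mean(vals)) if vals else None

        def in_extent(cell):
            i, j = cell
            return 0 <= i and 0 <= j and (i + 1) * k <= nrow and (j + 1) * k <= ncol
    else:
        offsets = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]

        def cost(cell):
            mem = hex_members(surface, *cell, nsize, anchor)
            vals = [surface.values[r, c] for r, c in mem if not surface.nodata_mask[r, c]]
            return float(np.mean(vals)) if vals else None

        def in_extent(cell):
            cx, cy = hex_centre(*cell, nsize, anchor)
            return (
                cx - nsize / 2 >= xmin - 1e-9 and cx + nsize / 2 <= xmax + 1e-9
                and cy - nsize / SQRT3 >= ymin - 1e-9 and cy + nsize / SQRT3 <= ymax + 1e-9
            )

    path = [start_cell]
    visited = {start_cell}
    for _ in range(n_steps):
        cur = path[-1]
        cands = []
        for di, dj in offsets:
            cell = (cur[0] + di, cur[1] + dj)
            if not in_extent(cell):
                continue
            c = cost(cell)
            if c is not None:
                cands.append((cell, c))
        unvisited = [(cell, c) for cell, c in cands if cell not in visited]
        if not cands or not unvisited:
            break
        m = min(c for _, c in unvisited)
        tied = [cell for cell, c in unvisited if abs(c - m) <= 1e-9 * max(abs(m), 1e-3)]
        if len(tied) > 1:
            break
        path.append(tied[0])
        visited.add(tied[0])
    return path
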