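"""The cellular-automata transition rule and single-walk driver.

At each timestep the agent inspects its single-ring neighbourhood, computes
the mean cost of each neighbour cell, and relocates to the cell with the
minimum cost.  Three refinements make the rule well defined on real
surfaces:

* **Tie-breaking** — when two or more candidates share the minimum cost
  (within a small relative tolerance), one is drawn uniformly at random.
* **Visited exclusion** — cells the agent has already occupied are removed
  from the candidate set, preventing see-saw oscillation between two cells.
* **All-visited fallback** — when every candidate has been visited, the next
  cell is drawn uniformly at random from all candidates; each such event is
  recorded on the walk.

A walk ends after ``n_steps`` moves, or earlier with status ``hit_edge``
when no candidate cell lies fully inside the raster extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lattice import (
    CostSurface,
    NeighbourhoodSpec,
    cell_centre,
    cell_containing,
    neighbourhood_costs,
    _footprint_in_extent,
    aggregate_cell_cost,
    cell_footprint,
)

__all__ = ["Walk", "WalkState", "select_next", "run_walk", "random_start_cell"]

#: Relative tolerance within which two candidate costs count as tied.  Exact
#: float comparison would make ties vanish on continuous surfaces although
#: they are expected on flat or integer-valued terrain; the small absolute
#: floor handles exact-zero costs (flat slope).
TIE_REL_TOL = 1e-9
TIE_ABS_TOL = 1e-12


@dataclass
class WalkState:
    """Mutable state of an in-progress walk."""

    current: tuple[int, int]
    visited: set[tuple[int, int]]
    step_index: int = 0


@dataclass
class Walk:
    """A completed walk: the cell path plus bookkeeping for analysis.

    ``cells`` holds lattice coordinates in visit order; ``centres`` the
    matching world coordinates; ``step_lengths`` the centre-to-centre
    distance of each move.  ``fallback_steps`` lists the step indices at
    which the all-visited random fallback fired (needed to audit the
    no-revisit guarantee).  ``status`` is ``"completed_steps"`` when the
    walk ran its full length and ``"hit_edge"`` when it terminated at the
    map edge.
    """

    cells: list[tuple[int, int]]
    centres: np.ndarray  # (n, 2) world coords
    step_lengths: np.ndarray
    status: str
    spec: NeighbourhoodSpec
    anchor: tuple[float, float]
    seed_record: object = None
    fallback_steps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert len(self.step_lengths) == len(self.cells) - 1

    @property
    def n_steps(self) -> int:
        return len(self.cells) - 1

    @property
    def start(self) -> tuple[float, float]:
        return tuple(self.centres[0])

    @property
    def end(self) -> tuple[float, float]:
        return tuple(self.centres[-1])


def select_next(
    costs: dict[tuple[int, int], float],
    visited: set[tuple[int, int]],
    centre: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Choose the next-move offset by the minimum-cost rule.

    Candidates are the keys of ``costs`` (offsets of valid neighbours).
    Previously visited cells are excluded; among the remaining candidates
    the minimum-cost one is returned, ties broken uniformly at random.  If
    every candidate is visited, one is drawn uniformly from all of them
    (the caller records the fallback).  Returns ``None`` when ``costs`` is
    empty — the edge-of-map termination signal.
    """
    if not costs:
        return None
    ci, cj = centre
    unvisited = [
        off for off in costs if (ci + off[0], cj + off[1]) not in visited
    ]
    if not unvisited:
        offs = list(costs)
        return offs[int(rng.integers(len(offs)))]
    m = min(costs[o] for o in unvisited)
    tied = [
        o
        for o in unvisited
        if math.isclose(costs[o], m, rel_tol=TIE_REL_TOL, abs_tol=TIE_ABS_TOL)
    ]
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


def _cell_is_valid(
    coords: tuple[int, int],
    spec: NeighbourhoodSpec,
    anchor: tuple[float, float],
    surface: CostSurface,
) -> bool:
    if not _footprint_in_extent(coords, spec, anchor, surface):
        return False
    return aggregate_cell_cost(surface, cell_footprint(coords, spec, anchor)) is not None


def random_start_cell(
    surface: CostSurface,
    spec: NeighbourhoodSpec,
    rng: np.random.Generator,
    anchor: tuple[float, float] | None = None,
    max_tries: int = 10000,
) -> tuple[int, int]:
    """Uniformly random valid lattice cell, by rejection sampling.

    Draws points uniformly over the raster extent and keeps the first whose
    containing lattice cell is fully inside the extent with a valid cost.
    Interior cells all have equal area, so accepted cells are exactly
    uniform over the valid interior cells.
    """
    if anchor is None:
        anchor = surface.origin
    xmin, ymin, xmax, ymax = surface.bounds
    for _ in range(max_tries):
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        coords = cell_containing((x, y), spec, anchor)
        if _cell_is_valid(coords, spec, anchor, surface):
            return coords
    raise ValueError("no valid interior lattice cell found for a random start")


def run_walk(
    surface: CostSurface,
    spec: NeighbourhoodSpec,
    start: tuple[float, float] | str,
    n_steps: int,
    rng: np.random.Generator,
    anchor: tuple[float, float] | None = None,
    seed_record: object = None,
) -> Walk:
    """Run one walk of up to ``n_steps`` moves from ``start``.

    ``start`` is a world coordinate (the walk begins in the lattice cell
    containing it) or the string ``"random"``.  Termination: after
    ``n_steps`` moves (status ``completed_steps``) or when no valid
    candidate remains (status ``hit_edge``).  The lattice ``anchor``
    defaults to the raster origin.
    """
    if anchor is None:
        anchor = surface.origin
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if isinstance(start, str):
        if start != "random":
            raise ValueError(f"start must be a coordinate or 'random', got {start!r}")
        current = random_start_cell(surface, spec, rng, anchor)
    else:
        current = cell_containing(tuple(start), spec, anchor)
        if not _cell_is_valid(current, spec, anchor, surface):
            raise ValueError(
                f"start {start} maps to lattice cell {current} which is outside "
                "the raster extent or has no valid cost"
            )

    state = WalkState(current=current, visited={current})
    cells = [current]
    centres = [cell_centre(current, spec, anchor)]
    step_lengths: list[float] = []
    fallback_steps: list[int] = []
    status = "completed_steps"

    for t in range(n_steps):
        costs = neighbourhood_costs(surface, state.current, spec, anchor)
        ci, cj = state.current
        unvisited_exists = any(
            (ci + o[0], cj + o[1]) not in state.visited for o in costs
        )
        off = select_next(costs, state.visited, state.current, rng)
        if off is None:
            status = "hit_edge"
            break
        if not unvisited_exists:
            fallback_steps.append(t)
        nxt = (ci + off[0], cj + off[1])
        c_prev = centres[-1]
        c_next = cell_centre(nxt, spec, anchor)
        step_lengths.append(math.hypot(c_next[0] - c_prev[0], c_next[1] - c_prev[1]))
        cells.append(nxt)
        centres.append(c_next)
        state.visited.add(nxt)
        state.current = nxt
        state.step_index = t + 1

    return Walk(
        cells=cells,
        centres=np.asarray(centres, dtype=float),
        step_lengths=np.asarray(step_lengths, dtype=float),
        status=status,
        spec=spec,
        anchor=anchor,
        seed_record=seed_record,
        fallback_steps=fallback_steps,
    )
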