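"""Cost-distance travel time to the nearest facility.

The friction surface induces a graph on the raster: each traversable cell is
a node joined to its 8 neighbors, and crossing the edge between cells *a* and
*b* costs

    t(a, b) = d(a, b) * (1/v_a + 1/v_b) / 2

minutes, where *d* is the center-to-center distance (cell size for axis
moves, cell size * sqrt(2) diagonally) and *v* the cell speeds — time accrues
half in each cell at that cell's pace.  Travel time per cell is the exact
multi-source Dijkstra distance to the nearest facility cell; barrier cells
never enter the graph, and cells with no barrier-free path to any facility
come out as +inf ("unreachable"), kept as a sentinel all the way through (on
disk: -1).

Administrative borders play no role: the graph is never clipped by region
polygons, so routes may cross regions at no extra cost.
"""

from __future__ import annotations

import heapq
import logging
import math

import numpy as np

from .friction import FrictionSurface
from .grid import GridSpec, Raster
from .registry import FacilitySet

logger = logging.getLogger(__name__)

__all__ = ["snap_facilities", "cost_distance", "aggregate_to_population_grid"]

UNREACHABLE = float("inf")

# 8-connected neighborhood with center-to-center distance factors
_NEIGHBORS = [
    (-1, -1, math.sqrt(2)), (-1, 0, 1.0), (-1, 1, math.sqrt(2)),
    (0, -1, 1.0), (0, 1, 1.0),
    (1, -1, math.sqrt(2)), (1, 0, 1.0), (1, 1, math.sqrt(2)),
]


def snap_facilities(
    facilities: FacilitySet,
    friction: FrictionSurface,
    max_snap_radius: int = 10,
) -> list[tuple[int, int]]:
    """Map facility points to traversable source cells.

    Each facility becomes its containing cell.  A facility whose cell is a
    barrier is snapped to the nearest traversable cell (Euclidean cell
    distance, ties broken by (row, col)) within ``max_snap_radius`` cells, or
    dropped with a warning.  Returns the deduplicated, sorted source cells.
    """
    if len(facilities) == 0:
        raise ValueError("no facilities to snap: empty facility set")
    grid = friction.grid
    barrier = friction.barrier_mask
    sources: set[tuple[int, int]] = set()
    for rec in facilities:
        if not grid.contains(rec.x, rec.y):
            logger.warning("facility %s is outside the grid extent; dropped", rec.id)
            continue
        row, col = grid.index_of(rec.x, rec.y)
        if not barrier[row, col]:
            sources.add((row, col))
            continue
        snapped = _nearest_traversable(barrier, row, col, max_snap_radius)
        if snapped is None:
            logger.warning(
                "facility %s sits on a barrier with no traversable cell within "
                "%d cells; dropped", rec.id, max_snap_radius,
            )
        else:
            sources.add(snapped)
    if not sources:
        raise ValueError("no facility could be placed on a traversable cell")
    return sorted(sources)


def _nearest_traversable(
    barrier: np.ndarray, row: int, col: int, radius: int
) -> tuple[int, int] | None:
    n_rows, n_cols = barrier.shape
    r0, r1 = max(0, row - radius), min(n_rows, row + radius + 1)
    c0, c1 = max(0, col - radius), min(n_cols, col + radius + 1)
    window = ~barrier[r0:r1, c0:c1]
    if not window.any():
        return None
    rows, cols = np.nonzero(window)
    rows, cols = rows + r0, cols + c0
    d2 = (rows - row) ** 2 + (cols - col) ** 2
    order = np.lexsort((cols, rows, d2))
    best = order[0]
    if d2[best] > radius**2:
        return None
    return int(rows[best]), int(cols[best])


def cost_distance(
    friction: FrictionSurface, sources: list[tuple[int, int]]
) -> Raster:
    """Exact multi-source Dijkstra travel time (minutes) over the cell graph.

    Priority-queue entries are ordered (time, row, col) so expansion order —
    and therefore the output — is bit-stable across runs.  Returns a raster
    with 0 at source cells, +inf where no path exists, and NaN on barriers.
    """
    grid = friction.grid
    n_rows, n_cols = grid.shape
    barrier = friction.barrier_mask
    if not sources:
        raise ValueError("cost_distance needs at least one source cell")
    for r, c in sources:
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"source cell {(r, c)} outside the grid")
        if barrier[r, c]:
            raise ValueError(f"source cell {(r, c)} is a barrier")

    # minutes to cross half a cell per meter of distance: pace (min/km) / 2
    half_pace = np.where(barrier, np.nan, 60.0 / np.maximum(friction.speed, 1e-300) / 2.0)
    cell_km = grid.cell_size / 1000.0

    time = np.full((n_rows, n_cols), UNREACHABLE)
    done = np.zeros((n_rows, n_cols), dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r, c in sorted(set(sources)):
        time[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))

    push, pop = heapq.heappush, heapq.heappop
    while heap:
        t, r, c = pop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        hp = half_pace[r, c]
        for dr, dc, f in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and not done[rr, cc] and not barrier[rr, cc]:
                nt = t + f * cell_km * (hp + half_pace[rr, cc])
                if nt < time[rr, cc]:
                    time[rr, cc] = nt
                    push(heap, (nt, rr, cc))

    time[barrier] = np.nan
    return Raster(grid, time)


def aggregate_to_population_grid(
    tt: Raster, grid_coarse: GridSpec, stat: str = "mean"
) -> Raster:
    """Aggregate 100 m travel times onto the coarser population grid.

    The fine grid must nest exactly into the coarse one (e.g. 10x10 blocks of
    100 m cells per 1 km cell).  Each coarse value is the ``stat`` (mean by
    default; ``min`` and ``median`` available) of the *finite* fine values in
    its block; a block whose traversable cells are all unreachable stays
    unreachable, and a block that is entirely barrier/nodata becomes NaN.
    """
    fine = tt.grid
    if not fine.same_extent(grid_coarse):
        raise ValueError("coarse grid must cover the same extent as the fine grid")
    factor = grid_coarse.cell_size / fine.cell_size
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("grids do not nest: cell sizes are not integer multiples")
    factor = int(round(factor))
    if fine.n_rows != grid_coarse.n_rows * factor or fine.n_cols != grid_coarse.n_cols * factor:
        raise ValueError("grids do not nest: dimensions are not exact multiples")
    if stat not in ("mean", "min", "median"):
        raise ValueError(f"stat must be mean|min|median, got {stat!r}")

    blocks = tt.values.reshape(grid_coarse.n_rows, factor, grid_coarse.n_cols, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(grid_coarse.n_rows, grid_coarse.n_cols, -1)
    finite = np.isfinite(blocks)
    out = np.full(grid_coarse.shape, np.nan)
    any_finite = finite.any(axis=2)
    masked = np.where(finite, blocks, np.nan)
    import warnings

    with warnings.catch_warnings():
        # all-NaN blocks are legitimate (fully barrier / unreachable)
        warnings.simplefilter("ignore", RuntimeWarning)
        if stat == "mean":
            agg = np.nanmean(masked, axis=2)
        elif stat == "min":
            agg = np.nanmin(masked, axis=2)
        else:
            agg = np.nanmedian(masked, axis=2)
    out[any_finite] = agg[any_finite]
    # traversable but unreachable blocks stay unreachable, not nodata
    has_traversable = ~np.isnan(blocks).all(axis=2)
    out[~any_finite & has_traversable] = UNREACHABLE
    return Raster(grid_coarse, out)
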