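"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _scipy_dijkstra

from geoaccess import FrictionSurface, GridSpec, SyntheticScenario


def oracle_cost_distance(friction: FrictionSurface, sources: list[tuple[int, int]]) -> np.ndarray:
    """Brute-force reference travel time via an explicit edge list.

    Builds the full 8-connected edge list (edge minutes =
    distance × ½(1/v_a + 1/v_b) × 60) as a sparse matrix and runs
    scipy.sparse.csgraph.dijkstra — an implementation path fully independent
    of the production priority-queue code.
    """
    grid = friction.grid
    n_rows, n_cols = grid.shape
    n = n_rows * n_cols
    barrier = friction.barrier_mask
    with np.errstate(divide="ignore"):
        pace_min_per_km = 60.0 / friction.speed  # minutes per km, invalid on barriers
    cell_km = grid.cell_size / 1000.0

    rows, cols, data = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            if barrier[r, c]:
                continue
            for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and not barrier[rr, cc]:
                    dist = cell_km * (math.sqrt(2.0) if dr and dc else 1.0)
                    w = dist * (pace_min_per_km[r, c] + pace_min_per_km[rr, cc]) / 2.0
                    rows.append(r * n_cols + c)
                    cols.append(rr * n_cols + cc)
                    data.append(w)
    graph = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    idx = [r * n_cols + c for r, c in sources]
    dist = _scipy_dijkstra(graph, directed=True, indices=idx, min_only=True)
    out = dist.reshape(n_rows, n_cols)
    out[barrier] = np.nan
    return out


def random_friction(rng: np.random.Generator, n_rows: int, n_cols: int,
                    barrier_prob: float = 0.2) -> FrictionSurface:
    """Random friction surface with at least one traversable cell."""
    speed = rng.uniform(1.0, 100.0, size=(n_rows, n_cols))
    barrier = rng.uniform(size=(n_rows, n_cols)) < barrier_prob
    if barrier.all():
        barrier[n_rows // 2, n_cols // 2] = False
    speed[barrier] = 0.0
    return FrictionSurface(GridSpec(n_rows, n_cols, 100.0), speed, barrier)


def random_sources(rng: np.random.Generator, friction: FrictionSurface, k: int) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(~friction.barrier_mask)
    pick = rng.choice(len(rows), size=min(k, len(rows)), replace=False)
    return [(int(rows[i]), int(cols[i])) for i in pick]


@pytest.fixture
def model_grid() -> GridSpec:
    """Small 100 m model grid that tiles exactly into 1 km summary cells."""
    return GridSpec(60, 60, 100.0)


@pytest.fixture
def scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=11, n_settlements=5, total_population=10_000.0)
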