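"""Synthetic landscapes for offline testing of the accessibility pipeline.

The generators emulate the *structure* of the real inputs — a categorical
land-cover raster with contiguous water and forest, a road network joining
settlements, a clustered 60+ population surface on a coarser grid, and two
partially overlapping facility registries — without any resemblance to real
geography.  Everything is a pure function of (scenario, grid): the scenario's
single integer seed is split into independent per-generator substreams, so the
same scenario always reproduces bit-identical outputs.

Land-cover semantics follow the accessibility model's needs: WATER is an
absolute barrier, FOREST is slow on foot, BARREN and BUILT_UP are ordinary
walking terrain, and roads (rasterized downstream) override all of them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .grid import GridSpec, Raster
from .registry import FacilityRecord, FacilitySet

__all__ = [
    "LandCover",
    "RoadClass",
    "RoadSegment",
    "RoadNetwork",
    "SyntheticScenario",
    "generate_landscape",
    "generate_population",
    "generate_facilities",
]


class LandCover(enum.IntEnum):
    WATER = 1
    FOREST = 2
    BARREN = 3
    BUILT_UP = 4


class RoadClass(enum.IntEnum):
    """Road hierarchy; lower value = faster class."""

    PRIMARY = 1
    SECONDARY = 2
    TERTIARY = 3


@dataclass(frozen=True)
class RoadSegment:
    """Polyline (vertices in planar meters) with a road class."""

    vertices: tuple[tuple[float, float], ...]
    road_class: RoadClass

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("a road segment needs at least 2 vertices")


@dataclass
class RoadNetwork:
    segments: list[RoadSegment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def to_geojson(self, path) -> None:
        import json

        features = [
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(v) for v in seg.vertices]},
                "properties": {"road_class": seg.road_class.name},
            }
            for seg in self.segments
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "RoadNetwork":
        import json

        with open(path) as fh:
            collection = json.load(fh)
        segments = []
        for feat in collection["features"]:
            verts = tuple(tuple(map(float, v)) for v in feat["geometry"]["coordinates"])
            segments.append(RoadSegment(verts, RoadClass[feat["properties"]["road_class"]]))
        return cls(segments)


@dataclass(frozen=True)
class SyntheticScenario:
    """Knobs of the synthetic world.

    Parameters
    ----------
    seed
        Single master seed; per-generator substreams are derived from it.
    n_settlements
        Number of settlement centers; roads form a spanning tree over them.
    settlement_spread
        Gaussian scale (meters) of the population kernel around each
        settlement; also sets the built-up halo radius.
    n_facilities
        Mapping source -> raw_type -> count, e.g.
        ``{"MFL": {"hospital": 2, "health_centre": 6}, "OSM": {"clinic": 4}}``.
    water_fraction, forest_fraction
        Target share of cells covered by water / forest blobs; their sum must
        not exceed 1.
    duplicate_fraction
        Share of OSM facilities placed at a jittered copy of an MFL facility's
        location, emulating the (never deduplicated) registry overlap.
    total_population
        Adults aged 60+ summed over the population raster.
    """

    seed: int = 0
    n_settlements: int = 8
    settlement_spread: float = 3_000.0
    n_facilities: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            "MFL": {"health_centre": 10, "hospital": 2},
            "OSM": {"clinic": 5, "doctors": 3, "hospital": 2},
        }
    )
    water_fraction: float = 0.08
    forest_fraction: float = 0.25
    duplicate_fraction: float = 0.3
    total_population: float = 50_000.0

    def __post_init__(self) -> None:
        for name in ("water_fraction", "forest_fraction", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.water_fraction + self.forest_fraction > 1.0:
            raise ValueError("water_fraction + forest_fraction must not exceed 1")
        if self.n_settlements < 1:
            raise ValueError("n_settlements must be >= 1")
        if self.total_population < 0:
            raise ValueError("total_population must be >= 0")
        for source, by_type in self.n_facilities.items():
            for raw_type, count in by_type.items():
                if count < 0:
                    raise ValueError(f"facility count for {source}/{raw_type} must be >= 0")

    def substream(self, name: str) -> np.random.Generator:
        """Independent deterministic RNG substream for one generator stage."""
        payload = [self.seed] + [ord(c) for c in name]
        return np.random.default_rng(np.random.SeedSequence(payload))


# ---------------------------------------------------------------------------
# land cover, elevation, roads


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return ndimage.gaussian_filter(noise, sigma=sigma)


def _blob_mask(rng: np.random.Generator, shape: tuple[int, int], fraction: float, sigma: float) -> np.ndarray:
    """Contiguous random blobs covering ≈``fraction`` of the grid."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    f = _smooth_field(rng, shape, sigma)
    return f >= np.quantile(f, 1.0 - fraction)


def _settlement_points(scenario: SyntheticScenario, grid: GridSpec) -> np.ndarray:
    """Settlement centers (x, y), kept away from the outer 5% margin."""
    rng = scenario.substream("settlements")
    x0, y0, x1, y1 = grid.extent
    mx, my = 0.05 * (x1 - x0), 0.05 * (y1 - y0)
    xs = rng.uniform(x0 + mx, x1 - mx, scenario.n_settlements)
    ys = rng.uniform(y0 + my, y1 - my, scenario.n_settlements)
    return np.column_stack([xs, ys])


def generate_landscape(
    scenario: SyntheticScenario, grid: GridSpec
) -> tuple[Raster, RoadNetwork, Raster]:
    """Generate (land cover, road network, elevation) on the model grid.

    Water and forest are placed as contiguous blobs from thresholded smooth
    random fields (water wins where they overlap); a built-up halo surrounds
    each settlement; everything else is barren.  Roads are the edges of the
    Euclidean minimum spanning tree over settlement centers, each edge a
    two-vertex polyline classed PRIMARY / SECONDARY / TERTIARY by length rank
    (long trunk edges fastest, short spurs slowest).
    """
    shape = grid.shape
    sigma = max(2.0, min(shape) / 12.0)

    water = _blob_mask(scenario.substream("water"), shape, scenario.water_fraction, sigma)
    forest = _blob_mask(scenario.substream("forest"), shape, scenario.forest_fraction, sigma)

    classes = np.full(shape, int(LandCover.BARREN), dtype=np.int16)
    classes[forest] = int(LandCover.FOREST)

    settlements = _settlement_points(scenario, grid)
    xx, yy = grid.cell_centers()
    halo = scenario.settlement_spread / 3.0
    for sx, sy in settlements:
        near = (xx - sx) ** 2 + (yy - sy) ** 2 <= halo**2
        classes[near] = int(LandCover.BUILT_UP)
    classes[water] = int(LandCover.WATER)  # water beats everything

    elev_field = _smooth_field(scenario.substream("elevation"), shape, sigma)
    span = elev_field.max() - elev_field.min()
    elev = (elev_field - elev_field.min()) / (span if span > 0 else 1.0) * 1500.0

    roads = _spanning_tree_roads(scenario, settlements)
    return Raster(grid, classes), roads, Raster(grid, elev)


def _spanning_tree_roads(scenario: SyntheticScenario, settlements: np.ndarray) -> RoadNetwork:
    n = len(settlements)
    if n < 2:
        return RoadNetwork([])
    dist = squareform(pdist(settlements))
    mst = minimum_spanning_tree(dist).tocoo()
    edges = sorted(zip(mst.row, mst.col), key=lambda e: (e[0], e[1]))
    lengths = np.array([dist[i, j] for i, j in edges])
    # longest edges are trunk roads: top third PRIMARY, middle SECONDARY
    order = np.argsort(-lengths, kind="stable")
    ranks = np.empty(len(edges), dtype=int)
    ranks[order] = np.arange(len(edges))
    segments = []
    for (i, j), rank in zip(edges, ranks):
        if rank < len(edges) / 3:
            cls = RoadClass.PRIMARY
        elif rank < 2 * len(edges) / 3:
            cls = RoadClass.SECONDARY
        else:
            cls = RoadClass.TERTIARY
        segments.append(RoadSegment((tuple(settlements[i]), tuple(settlements[j])), cls))
    return RoadNetwork(segments)


# ---------------------------------------------------------------------------
# population


def generate_population(
    scenario: SyntheticScenario, landcover: Raster, grid_coarse: GridSpec
) -> Raster:
    """Adults 60+ per coarse (1 km) cell, clustered at settlements.

    Counts follow isotropic Gaussian kernels centered on the settlements
    (scale = ``settlement_spread``), are zeroed on majority-water cells, and
    are normalized so their sum equals ``total_population`` exactly (within
    floating tolerance).  A fully water-covered landscape is rejected: there
    is nowhere to put people.
    """
    if not landcover.grid.same_extent(grid_coarse):
        raise ValueError("population grid must cover the same extent as the land-cover grid")
    factor = int(round(grid_coarse.cell_size / landcover.grid.cell_size))
    water_fine = landcover.values == int(LandCover.WATER)
    # coarse cell is water when more than half of its fine cells are
    blocks = water_fine.reshape(
        grid_coarse.n_rows, factor, grid_coarse.n_cols, factor
    ).mean(axis=(1, 3))
    water_coarse = blocks > 0.5

    settlements = _settlement_points(scenario, landcover.grid)
    xx, yy = grid_coarse.cell_centers()
    rng = scenario.substream("population")
    weights = rng.uniform(0.5, 1.5, len(settlements))  # unequal settlement sizes
    dens = np.zeros(grid_coarse.shape)
    s2 = 2.0 * scenario.settlement_spread**2
    for (sx, sy), w in zip(settlements, weights):
        dens += w * np.exp(-((xx - sx) ** 2 + (yy - sy) ** 2) / s2)
    dens[water_coarse] = 0.0
    total = dens.sum()
    if total <= 0:
        raise ValueError("landscape has no habitable (non-water) populated cells")
    return Raster(grid_coarse, dens * (scenario.total_population / total))


# ---------------------------------------------------------------------------
# facilities


def generate_facilities(scenario: SyntheticScenario, landcover: Raster) -> FacilitySet:
    """Facility points for both registries, near settlements, never on water.

    Each requested (source, raw_type) count is honored exactly.  A
    ``duplicate_fraction`` share of OSM facilities is placed at a small jitter
    of an already placed MFL facility, emulating the real registries' partial
    overlap (which the pooled analysis set keeps, undeduplicated).
    """
    grid = landcover.grid
    water = landcover.values == int(LandCover.WATER)
    if water.all():
        raise ValueError("cannot place facilities: every cell is water")
    rng = scenario.substream("facilities")
    settlements = _settlement_points(scenario, grid)
    x0, y0, x1, y1 = grid.extent

    def draw_point() -> tuple[float, float]:
        for _ in range(10_000):
            sx, sy = settlements[rng.integers(len(settlements))]
            x = np.clip(rng.normal(sx, scenario.settlement_spread / 2), x0, x1)
            y = np.clip(rng.normal(sy, scenario.settlement_spread / 2), y0, y1)
            if not water[grid.index_of(x, y)]:
                return float(x), float(y)
        # extreme water coverage: fall back to any non-water cell center
        rows, cols = np.nonzero(~water)
        k = rng.integers(len(rows))
        return grid.cell_center(int(rows[k]), int(cols[k]))

    records: list[FacilityRecord] = []
    mfl_coords: list[tuple[float, float]] = []
    for source in ("MFL", "OSM"):  # MFL first so OSM can duplicate it
        for raw_type, count in sorted(scenario.n_facilities.get(source, {}).items()):
            for i in range(count):
                if (
                    source == "OSM"
                    and mfl_coords
                    and rng.uniform() < scenario.duplicate_fraction
                ):
                    bx, by = mfl_coords[rng.integers(len(mfl_coords))]
                    jitter = grid.cell_size / 4.0
                    x = float(np.clip(bx + rng.normal(0, jitter), x0, x1))
                    y = float(np.clip(by + rng.normal(0, jitter), y0, y1))
                    if water[grid.index_of(x, y)]:
                        x, y = draw_point()
                else:
                    x, y = draw_point()
                records.append(FacilityRecord(f"{source}:{raw_type}:{i}", x, y, source, raw_type))
                if source == "MFL":
                    mfl_coords.append((x, y))
    return FacilitySet(records)
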