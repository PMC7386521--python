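"""Traversal-speed (friction/impedance) surface from land cover and roads.

Every cell gets the speed at which it can be crossed: vehicle speeds on road
cells (100 km/h motorway/primary, 50 km/h secondary, 30 km/h tertiary),
walking speeds elsewhere (5 km/h on barren and built-up land, 2 km/h through
forest), and open water is an absolute barrier.  Roads override land cover,
including water — a road crossing water is a bridge.  The downstream
cost-distance step converts speeds into per-edge crossing times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.draw import line as _draw_line

from .grid import GridSpec, Raster
from .landscape import LandCover, RoadClass, RoadNetwork

logger = logging.getLogger(__name__)

__all__ = ["SpeedTable", "FrictionSurface", "rasterize_roads", "build_friction"]

BARRIER = float("nan")  # marker inside SpeedTable mappings


@dataclass(frozen=True)
class SpeedTable:
    """Travel speed (km/h) per road class and land-cover class.

    Defaults are the study parameters: motorways/primary 100, secondary 50,
    tertiary 30 km/h; barren and built-up 5 km/h and forest 2 km/h walking;
    water has no speed at all (barrier).
    """

    road_speeds: dict[RoadClass, float] = field(
        default_factory=lambda: {
            RoadClass.PRIMARY: 100.0,
            RoadClass.SECONDARY: 50.0,
            RoadClass.TERTIARY: 30.0,
        }
    )
    landcover_speeds: dict[LandCover, float] = field(
        default_factory=lambda: {
            LandCover.BARREN: 5.0,
            LandCover.BUILT_UP: 5.0,
            LandCover.FOREST: 2.0,
            LandCover.WATER: BARRIER,
        }
    )

    def __post_init__(self) -> None:
        for cls, v in self.road_speeds.items():
            if not v > 0:
                raise ValueError(f"road speed for {cls!r} must be > 0, got {v}")
        for cls, v in self.landcover_speeds.items():
            if not (math.isnan(v) or v > 0):
                raise ValueError(f"speed for {cls!r} must be > 0 or barrier, got {v}")

    def is_barrier(self, landcover_class: LandCover) -> bool:
        return math.isnan(self.landcover_speeds[landcover_class])

    def with_road_speed(self, road_class: RoadClass, speed: float) -> "SpeedTable":
        return replace(self, road_speeds={**self.road_speeds, road_class: speed})

    def with_landcover_speed(self, landcover: LandCover, speed: float) -> "SpeedTable":
        return replace(self, landcover_speeds={**self.landcover_speeds, landcover: speed})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeedTable":
        import yaml

        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def from_mapping(cls, raw: dict) -> "SpeedTable":
        """Build from nested dicts, e.g. {"roads": {"primary": 100}, ...}."""
        roads = {RoadClass[k.upper()]: float(v) for k, v in raw.get("roads", {}).items()}
        lcs = {
            LandCover[k.upper()]: (BARRIER if v in (None, "barrier") else float(v))
            for k, v in raw.get("landcover", {}).items()
        }
        base = cls()
        return cls(
            road_speeds={**base.road_speeds, **roads},
            landcover_speeds={**base.landcover_speeds, **lcs},
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        raw = {
            "roads": {k.name.lower(): v for k, v in self.road_speeds.items()},
            "landcover": {
                k.name.lower(): ("barrier" if math.isnan(v) else v)
                for k, v in self.landcover_speeds.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass
class FrictionSurface:
    """Per-cell traversal speed (km/h) plus an untraversable-cell mask."""

    grid: GridSpec
    speed: np.ndarray
    barrier_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.speed.shape != self.grid.shape or self.barrier_mask.shape != self.grid.shape:
            raise ValueError("speed/barrier arrays must match the grid shape")
        if not (self.speed[~self.barrier_mask] > 0).all():
            raise ValueError("non-barrier cells must have positive speed")

    def to_ascii_grid(self, path: str | Path) -> None:
        vals = self.speed.astype(float).copy()
        vals[self.barrier_mask] = np.nan
        from .grid import write_ascii_grid

        write_ascii_grid(Raster(self.grid, vals), path)

    @classmethod
    def from_ascii_grid(cls, path: str | Path) -> "FrictionSurface":
        from .grid import read_ascii_grid

        raster = read_ascii_grid(path)
        barrier = np.isnan(raster.values)
        speed = np.where(barrier, 1.0, raster.values)
        return cls(raster.grid, speed, barrier)


def rasterize_roads(roads: RoadNetwork, grid: GridSpec) -> np.ndarray:
    """Burn road polylines into a per-cell road-class raster.

    Returns an int array, 0 where no road crosses the cell, else the
    :class:`RoadClass` value of the fastest class touching it (classes are
    ordered fastest-first, so the *smallest* nonzero code wins).  Segments
    entirely outside the grid are skipped with a warning.
    """
    out = np.zeros(grid.shape, dtype=np.int16)
    # burn slowest class first so faster classes overwrite at crossings
    for seg in sorted(roads.segments, key=lambda s: -int(s.road_class)):
        burned_any = False
        verts = seg.vertices
        for (xa, ya), (xb, yb) in zip(verts[:-1], verts[1:]):
            ra, ca = grid.index_of(xa, ya)
            rb, cb = grid.index_of(xb, yb)
            rr, cc = _draw_line(ra, ca, rb, cb)
            keep = (rr >= 0) & (rr < grid.n_rows) & (cc >= 0) & (cc < grid.n_cols)
            if keep.any():
                out[rr[keep], cc[keep]] = int(seg.road_class)
                burned_any = True
        if not burned_any:
            logger.warning("road segment %s lies entirely outside the grid; ignored", seg)
    return out


def build_friction(
    landcover: Raster,
    road_raster: np.ndarray,
    speeds: SpeedTable | None = None,
    elevation: Raster | None = None,
    slope_correction: bool = False,
) -> FrictionSurface:
    """Merge land-cover and road speeds into the cost (friction) surface.

    Cell speed is the road speed where a road is present, else the land-cover
    walking speed.  Water without a road is a barrier; a road across water is
    a bridge and keeps its road speed.

    With ``slope_correction=True`` (an optional extension, off by default)
    walking speeds on non-road cells are scaled by a Tobler-style exponential
    factor exp(−3.5·|S + 0.05|) / exp(−0.175) computed from the elevation
    raster's local slope S, normalized so flat terrain is unchanged.  Vehicle
    (road) speeds are never slope-adjusted.
    """
    speeds = speeds or SpeedTable()
    grid = landcover.grid
    if road_raster.shape != grid.shape:
        raise ValueError("land cover and road raster must share one grid")

    codes = np.unique(landcover.values[~np.isnan(np.asarray(landcover.values, dtype=float))])
    known = {int(c) for c in LandCover}
    unknown = [int(c) for c in codes if int(c) not in known]
    if unknown:
        raise ValueError(f"unknown land-cover class codes: {unknown}")

    speed = np.zeros(grid.shape)
    barrier = np.zeros(grid.shape, dtype=bool)
    for lc in LandCover:
        sel = landcover.values == int(lc)
        if speeds.is_barrier(lc):
            barrier[sel] = True
        else:
            speed[sel] = speeds.landcover_speeds[lc]
    if slope_correction:
        if elevation is None:
            raise ValueError("slope_correction requires an elevation raster")
        if elevation.grid != grid:
            raise ValueError("elevation must share the land-cover grid")
        speed *= _tobler_factor(np.asarray(elevation.values, dtype=float), grid.cell_size)
    for rc in RoadClass:
        sel = road_raster == int(rc)
        speed[sel] = speeds.road_speeds[rc]
        barrier[sel] = False  # bridges: roads cross water
    speed[barrier] = 0.0
    return FrictionSurface(grid, speed, barrier)


def _tobler_factor(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    """Walking-speed multiplier from local slope, 1.0 on flat terrain."""
    dz_dr, dz_dc = np.gradient(elevation, cell_size)
    slope = np.hypot(dz_dr, dz_dc)  # rise over run, unsigned (isotropic model)
    return np.exp(-3.5 * np.abs(slope + 0.05)) / np.exp(-3.5 * 0.05)
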