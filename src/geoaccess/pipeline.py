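"""End-to-end pipeline: inputs -> friction -> travel time -> summaries.

A :class:`PipelineConfig` names either a synthetic scenario or paths to real
input files (never both), the speed table, the aggregation statistic and the
Wilson denominator policy.  :func:`run_pipeline` executes every stage twice —
once targeting hospitals only, once any facility — writes all intermediate
rasters, vectors and summary tables to the output directory, and returns the
summaries.  The run is a pure function of (config, seed): summary CSVs are
byte-identical across repeat runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .friction import FrictionSurface, SpeedTable, build_friction, rasterize_roads
from .grid import GridSpec, Raster, read_ascii_grid, write_ascii_grid
from .landscape import (
    RoadNetwork,
    SyntheticScenario,
    generate_facilities,
    generate_landscape,
    generate_population,
)
from .registry import FacilitySet
from .stats import (
    ANY_FACILITY_SCHEME,
    HOSPITAL_SCHEME,
    AccessSummary,
    categorize_map,
    distribution_table,
    summarize_access,
)
from .traveltime import aggregate_to_population_grid, cost_distance, snap_facilities

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_maps"]

SUMMARY_FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one accessibility analysis.

    Exactly one of ``scenario`` (synthetic world) or ``inputs`` (paths to
    land-cover/population ASCII grids and roads/facilities GeoJSON) must be
    given.  The model grid runs at 100 m cells and summaries at 1 km by
    default, mirroring the analysis design.
    """

    out_dir: str | Path = "geoaccess_out"
    scenario: SyntheticScenario | None = None
    inputs: dict[str, str] | None = None
    model_cell_size: float = 100.0
    summary_cell_size: float = 1000.0
    n_rows: int = 200
    n_cols: int = 200
    speeds: SpeedTable = field(default_factory=SpeedTable)
    aggregation: str = "mean"
    wilson_n: float | str = "populated_cells"
    snap_radius: int = 10
    write_maps: bool = True

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.inputs is None):
            raise ValueError("supply exactly one of `scenario` (synthetic) or `inputs` (files)")
        factor = self.summary_cell_size / self.model_cell_size
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError("summary cell size must be an integer multiple of the model cell size")
        if self.n_rows % int(round(factor)) or self.n_cols % int(round(factor)):
            raise ValueError("model grid dimensions must tile exactly into summary cells")
        if self.inputs is not None:
            missing = [p for p in self.inputs.values() if not Path(p).exists()]
            if missing:
                raise ValueError(f"input files not found: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scenario" in raw and raw["scenario"] is not None:
            raw["scenario"] = SyntheticScenario(**raw["scenario"])
        if "speeds" in raw:
            raw["speeds"] = SpeedTable.from_mapping(raw["speeds"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    summaries: dict[str, AccessSummary]
    travel_time_1km: dict[str, Raster]
    population: Raster
    friction: FrictionSurface
    out_dir: Path


def _fingerprint(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage(name: str):
    """Context manager logging stage duration and re-labelling failures."""

    class _Stage:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, _time.perf_counter() - self.t0)

    return _Stage()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full accessibility analysis and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("inputs"):
        if config.scenario is not None:
            grid = GridSpec(config.n_rows, config.n_cols, config.model_cell_size)
            factor = int(round(config.summary_cell_size / config.model_cell_size))
            grid_1km = grid.coarsen(factor)
            landcover, roads, elevation = generate_landscape(config.scenario, grid)
            population = generate_population(config.scenario, landcover, grid_1km)
            facilities = generate_facilities(config.scenario, landcover)
            write_ascii_grid(landcover, out / "landcover.asc")
            write_ascii_grid(elevation, out / "elevation.asc")
            write_ascii_grid(population, out / "population_60plus.asc")
            roads.to_geojson(out / "roads.geojson")
            facilities.to_geojson(out / "facilities.geojson")
            with open(out / "scenario.yaml", "w") as fh:
                yaml.safe_dump(
                    {**dataclasses.asdict(config.scenario),
                     "n_facilities": {k: dict(v) for k, v in config.scenario.n_facilities.items()}},
                    fh,
                )
        else:
            landcover = read_ascii_grid(config.inputs["landcover"])
            population = read_ascii_grid(config.inputs["population"])
            roads = RoadNetwork.from_geojson(config.inputs["roads"])
            facilities = FacilitySet.from_geojson(config.inputs["facilities"])
            grid, grid_1km = landcover.grid, population.grid
        for f in sorted(out.glob("*.asc")) + sorted(out.glob("*.geojson")):
            logger.info("input fingerprint %s sha256:%s", f.name, _fingerprint(f))

    with _stage("friction"):
        road_raster = rasterize_roads(roads, grid)
        friction = build_friction(landcover, road_raster, config.speeds)
        friction.to_ascii_grid(out / "friction_kmh.asc")

    targets = {"hospital": facilities.hospitals(), "any": facilities}
    summaries: dict[str, AccessSummary] = {}
    tt_1km: dict[str, Raster] = {}
    for target_name, target_set in targets.items():
        scheme = HOSPITAL_SCHEME if target_name == "hospital" else ANY_FACILITY_SCHEME
        with _stage(f"traveltime[{target_name}]"):
            sources = snap_facilities(target_set, friction, config.snap_radius)
            tt_fine = cost_distance(friction, sources)
            tt_coarse = aggregate_to_population_grid(tt_fine, grid_1km, config.aggregation)
            tt_1km[target_name] = tt_coarse
            write_ascii_grid(tt_fine, out / f"traveltime_{target_name}_100m.asc", unreachable_value=-1)
            write_ascii_grid(tt_coarse, out / f"traveltime_{target_name}_1km.asc", unreachable_value=-1)
        with _stage(f"summarize[{target_name}]"):
            summary = summarize_access(
                tt_coarse, population, scheme, ci_n=config.wilson_n
            )[0]
            summaries[target_name] = summary
            pd.DataFrame([summary.to_row()]).to_csv(
                out / f"summary_{target_name}.csv", index=False, float_format=SUMMARY_FLOAT_FMT
            )
            distribution_table(tt_coarse, population).to_csv(
                out / f"distribution_{target_name}.csv", index=False, float_format=SUMMARY_FLOAT_FMT
            )
            cat = categorize_map(tt_coarse, population, scheme)
            write_ascii_grid(cat, out / f"categories_{target_name}_1km.asc")
            if config.write_maps:
                render_maps(cat, population, scheme, out / f"map_{target_name}.png")

    return PipelineResult(config, summaries, tt_1km, population, friction, out)


def render_maps(cat_raster: Raster, population: Raster, scheme, path: str | Path) -> None:
    """Render the categorical travel-time map next to population density (PNG)."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import BoundaryNorm, ListedColormap

        vals = cat_raster.values
        fig, axes = plt.subplots(1, 2, figsize=(11, 5))
        palette = ListedColormap(["#2c7bb6", "#abd9e9", "#fdae61", "#d7191c"][: scheme.n_categories])
        norm = BoundaryNorm(np.arange(scheme.n_categories + 1) - 0.5, scheme.n_categories)
        if np.isnan(vals).all():
            logger.warning("categorical raster is fully masked; rendering blank map")
        im = axes[0].imshow(vals, cmap=palette, norm=norm, interpolation="nearest")
        cbar = fig.colorbar(im, ax=axes[0], ticks=range(scheme.n_categories), shrink=0.8)
        cbar.ax.set_yticklabels(scheme.labels)
        axes[0].set_title(f"Travel time to nearest {scheme.name}")
        pop = axes[1].imshow(population.values, cmap="viridis", interpolation="nearest")
        fig.colorbar(pop, ax=axes[1], shrink=0.8, label="adults 60+ per km²")
        axes[1].set_title("Population density (60+)")
        for ax in axes:
            ax.set_xticks([])
            ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    except Exception:  # rendering is presentational; never fail the pipeline
        logger.exception("map rendering failed for %s", path)
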