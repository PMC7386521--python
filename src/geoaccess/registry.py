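"""Healthcare-facility registries: classification, pooling, densities.

Facility locations come from two kinds of inventories: crowd-sourced
OpenStreetMap (OSM) points tagged ``hospital`` / ``clinic`` / ``doctors``, and
government or UN master facility lists (MFL) whose levels map onto hospital
vs. primary care.  The analysis pools the two registries *without*
deduplication — travel time to the nearest facility is unchanged by exact
duplicates — and keeps a hospitals-only view, since hospital access and
any-facility access are summarized separately.

Facility density per 100,000 population is the standard comparative measure
across countries; :func:`facility_density` and :func:`density_table` implement
that arithmetic, and a packaged national inventory for 44 sub-Saharan African
countries ships with the module for worked examples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FacilityRecord",
    "FacilitySet",
    "classify_facility",
    "pool_registries",
    "facility_density",
    "density_table",
    "cross_source_pairs",
    "assign_regions",
    "load_national_inventory",
]

SOURCES = ("OSM", "MFL")

#: raw_type values accepted by :func:`classify_facility` (OSM tag values plus
#: common master-facility-list primary-care designations).
HOSPITAL_TYPES = frozenset({"hospital"})
PRIMARY_CARE_TYPES = frozenset(
    {
        "clinic",
        "doctors",
        "health_centre",
        "health_center",
        "health_post",
        "dispensary",
        "primary_care",
    }
)


def classify_facility(raw_type: str) -> bool:
    """True when ``raw_type`` denotes a hospital, False for primary care.

    Accepts the OSM amenity/healthcare tag values (``hospital``, ``clinic``,
    ``doctors``) and common MFL primary-care designations.  Unknown values
    raise rather than silently classifying.
    """
    if not raw_type:
        raise ValueError("raw_type must be a non-empty string")
    key = raw_type.strip().lower()
    if key in HOSPITAL_TYPES:
        return True
    if key in PRIMARY_CARE_TYPES:
        return False
    accepted = sorted(HOSPITAL_TYPES | PRIMARY_CARE_TYPES)
    raise ValueError(f"unknown facility type {raw_type!r}; accepted values: {accepted}")


@dataclass(frozen=True)
class FacilityRecord:
    """One facility point: id, planar coordinates, registry, and class."""

    id: str
    x: float
    y: float
    source: str
    raw_type: str
    is_hospital: bool | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.is_hospital is None:
            object.__setattr__(self, "is_hospital", classify_facility(self.raw_type))


@dataclass
class FacilitySet:
    """An ordered set of facility records with unique ids."""

    records: list[FacilityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate facility ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FacilityRecord]:
        return iter(self.records)

    def hospitals(self) -> "FacilitySet":
        """Hospitals-only subset (pure filter)."""
        return FacilitySet([r for r in self.records if r.is_hospital])

    def from_source(self, source: str) -> "FacilitySet":
        return FacilitySet([r for r in self.records if r.source == source])

    def coordinates(self) -> np.ndarray:
        return np.array([[r.x, r.y] for r in self.records]).reshape(-1, 2)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "x": r.x,
                    "y": r.y,
                    "source": r.source,
                    "raw_type": r.raw_type,
                    "is_hospital": r.is_hospital,
                }
                for r in self.records
            ],
            columns=["id", "x", "y", "source", "raw_type", "is_hospital"],
        )

    # ---- I/O -------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FacilitySet":
        df = pd.read_csv(path)
        return cls(
            [
                FacilityRecord(str(r.id), float(r.x), float(r.y), r.source, r.raw_type)
                for r in df.itertuples()
            ]
        )

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r.x, r.y]},
                "properties": {
                    "id": r.id,
                    "source": r.source,
                    "raw_type": r.raw_type,
                    "is_hospital": r.is_hospital,
                },
            }
            for r in self.records
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "FacilitySet":
        with open(path) as fh:
            collection = json.load(fh)
        records = []
        for feat in collection["features"]:
            x, y = feat["geometry"]["coordinates"]
            props = feat["properties"]
            records.append(
                FacilityRecord(str(props["id"]), float(x), float(y), props["source"], props["raw_type"])
            )
        return cls(records)


def pool_registries(osm: FacilitySet, mfl: FacilitySet) -> FacilitySet:
    """Union of the two registries without deduplication.

    Ids are namespaced by source so the pooled set keeps unique ids even when
    the same facility appears in both inventories.  Overlap between registries
    is deliberately left in place: the nearest-facility travel time is
    invariant to co-located duplicates (see :func:`cross_source_pairs` for a
    diagnostic that never alters the analysis set).
    """

    def namespaced(records: Iterable[FacilityRecord]) -> list[FacilityRecord]:
        out = []
        for r in records:
            if not r.id.startswith(r.source + ":"):
                r = replace(r, id=f"{r.source}:{r.id}")
            out.append(r)
        return out

    return FacilitySet(namespaced(osm.records) + namespaced(mfl.records))


def cross_source_pairs(facilities: FacilitySet, radius: float) -> int:
    """Count OSM–MFL pairs closer than ``radius`` meters (diagnostic only)."""
    osm = facilities.from_source("OSM").coordinates()
    mfl = facilities.from_source("MFL").coordinates()
    if len(osm) == 0 or len(mfl) == 0:
        return 0
    from scipy.spatial import cKDTree

    return int(cKDTree(osm).count_neighbors(cKDTree(mfl), radius))


def facility_density(count: int, population: float) -> float:
    """Facilities per 100,000 population."""
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return 100_000.0 * count / population


def assign_regions(facilities: FacilitySet, regions: Mapping[str, object]) -> dict[str, str | None]:
    """Map each facility id to the name of the region polygon containing it.

    ``regions`` maps region name -> shapely polygon.  Facilities outside all
    polygons map to None and are logged; they are counted in no region.
    """
    from shapely.geometry import Point

    out: dict[str, str | None] = {}
    for rec in facilities:
        hit = None
        for name, poly in regions.items():
            if poly.covers(Point(rec.x, rec.y)):
                hit = name
                break
        if hit is None:
            logger.warning("facility %s at (%.1f, %.1f) falls outside all regions", rec.id, rec.x, rec.y)
        out[rec.id] = hit
    return out


def density_table(
    facilities: FacilitySet,
    region_populations: Mapping[str, float],
    regions: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Per-(region, source) facility counts and densities per 100,000.

    One row per (region, source) with primary-care, hospital and total counts
    and densities; total = primary + hospital by construction.  With
    ``regions`` polygons supplied, facilities are attributed by
    point-in-polygon; otherwise a single region must be given and receives
    every facility.
    """
    if regions is not None:
        membership = assign_regions(facilities, regions)
    else:
        if len(region_populations) != 1:
            raise ValueError("without region polygons, exactly one region must be supplied")
        only = next(iter(region_populations))
        membership = {r.id: only for r in facilities}

    rows = []
    for region, population in region_populations.items():
        for source in SOURCES:
            recs = [
                r for r in facilities if r.source == source and membership.get(r.id) == region
            ]
            n_hosp = sum(r.is_hospital for r in recs)
            n_prim = len(recs) - n_hosp
            rows.append(
                {
                    "region": region,
                    "source": source,
                    "population": population,
                    "primary_count": n_prim,
                    "hospital_count": n_hosp,
                    "total_count": len(recs),
                    "primary_per_100k": round(facility_density(n_prim, population), 3),
                    "hospital_per_100k": round(facility_density(n_hosp, population), 3),
                    "total_per_100k": round(facility_density(len(recs), population), 3),
                }
            )
    return pd.DataFrame(rows)


def load_national_inventory() -> pd.DataFrame:
    """Packaged national facility counts for 44 sub-Saharan African countries.

    Columns: country, region_group, total and 60+ population (millions), MFL
    and OSM primary-care/hospital counts, and the published densities per
    100,000 for cross-checking the arithmetic.
    """
    with resources.files("geoaccess.data").joinpath("ssa_facility_inventory.csv").open() as fh:
        return pd.read_csv(fh)
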