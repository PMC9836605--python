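"""Spatial filtering against the nested study-area polygons.

Imported occurrence data may cover a larger area than the project
needs, so every record is intersected against two nested polygons: the
inner polygon is the study area proper and yields the final data; the
outer polygon adds a surrounding strip of lower-altitude landscape
whose records form a candidate pool (taxa occurring nearby that may
enter the study area); everything else is discarded.

Geometry is evaluated directly in geographic WGS84 coordinates (plate
carrée): at study-area scale this is adequate and deterministic, and it
keeps point-in-polygon semantics exactly reproducible.  Boundary points
count as inside (conservative for a control-check purpose); grid
quadrants are classified by any-positive-area overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence, Union

from shapely.geometry import Point, box, shape
from shapely.geometry.base import BaseGeometry

from .ceba_grid import DEFAULT_GRID, GridSpec, QuadrantRef, parse_label, quadrant_bounds
from .models import GabretaError, LoadError, OccurrenceRecord


class RegionClass(str, Enum):
    INNER = "INNER"
    OUTER_ONLY = "OUTER_ONLY"
    OUTSIDE = "OUTSIDE"


@dataclass(frozen=True)
class StudyAreaPolygons:
    """The nested inner (study area) and outer (study area + strip) polygons."""

    inner: BaseGeometry
    outer: BaseGeometry

    def __post_init__(self) -> None:
        # containment asserted by vertex sampling: every inner vertex
        # must lie within the outer polygon (boundaries inclusive)
        for geom in getattr(self.inner, "geoms", [self.inner]):
            for ring in [geom.exterior, *geom.interiors]:
                for x, y in ring.coords:
                    if not self.outer.covers(Point(x, y)):
                        raise LoadError(
                            f"inner polygon vertex ({x}, {y}) lies outside the outer polygon"
                        )


def _load_geometry(source: Union[str, Path, dict]) -> BaseGeometry:
    if isinstance(source, dict):
        doc = source
    else:
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    if doc.get("type") == "FeatureCollection":
        doc = doc["features"][0]
    if doc.get("type") == "Feature":
        doc = doc["geometry"]
    geom = shape(doc)
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise LoadError(f"expected Polygon/MultiPolygon, got {geom.geom_type}")
    return geom


def load_study_area(
    inner: Union[str, Path, dict], outer: Union[str, Path, dict]
) -> StudyAreaPolygons:
    """Load the two nested polygons from GeoJSON (WGS84, lon-lat order)."""
    return StudyAreaPolygons(inner=_load_geometry(inner), outer=_load_geometry(outer))


def classify_point(
    latitude: float, longitude: float, polygons: StudyAreaPolygons
) -> RegionClass:
    """INNER if in the inner polygon, else OUTER_ONLY if in the outer, else OUTSIDE.

    Uses even-odd containment with inclusive boundaries (`covers`).
    """
    pt = Point(longitude, latitude)
    if polygons.inner.covers(pt):
        return RegionClass.INNER
    if polygons.outer.covers(pt):
        return RegionClass.OUTER_ONLY
    return RegionClass.OUTSIDE


def classify_quadrant(
    q: QuadrantRef, polygons: StudyAreaPolygons, spec: GridSpec = DEFAULT_GRID
) -> RegionClass:
    """Classify a grid quadrant by any-positive-area overlap.

    A quadrant straddling the inner boundary is INNER: portal maps show
    whole quadrants clipped by the study area, so partial overlap counts.
    """
    south, west, north, east = (float(v) for v in quadrant_bounds(q, spec))
    rect = box(west, south, east, north)
    if polygons.inner.intersection(rect).area > 0:
        return RegionClass.INNER
    if polygons.outer.intersection(rect).area > 0:
        return RegionClass.OUTER_ONLY
    return RegionClass.OUTSIDE


def classify_record(
    record: OccurrenceRecord,
    polygons: StudyAreaPolygons,
    spec: GridSpec = DEFAULT_GRID,
) -> RegionClass:
    """Classify via the point when present, else via the grid code."""
    if record.has_point:
        return classify_point(record.latitude, record.longitude, polygons)
    if record.grid_code:
        return classify_quadrant(parse_label(record.grid_code), polygons, spec)
    raise GabretaError(f"record {record.record_id!r} has no location")  # post-ingest invariant


def partition_records(
    records: Sequence[OccurrenceRecord],
    polygons: StudyAreaPolygons,
    spec: GridSpec = DEFAULT_GRID,
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Partition into (final, candidates, discards); counts are conserved."""
    final: list[OccurrenceRecord] = []
    candidates: list[OccurrenceRecord] = []
    discards: list[OccurrenceRecord] = []
    buckets = {
        RegionClass.INNER: final,
        RegionClass.OUTER_ONLY: candidates,
        RegionClass.OUTSIDE: discards,
    }
    for record in records:
        buckets[classify_record(record, polygons, spec)].append(record)
    return final, candidates, discards
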