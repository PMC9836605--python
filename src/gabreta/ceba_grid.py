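"""CEBA / TK25 mapping grid: coordinate-to-quadrant conversion.

The Central European Basic Area (CEBA) grid tiles the map in base cells
of 10 arc-minutes longitude x 6 arc-minutes latitude, each split into
four "quadrants" of 5 x 3 arc-minutes (TK25/4) -- roughly 5.5 x 6 km at
central-European latitudes, the standard resolution of floristic
atlases.  Rows count southwards from a northwest origin, columns
eastwards, after the German Messtischblatt sheet convention; quadrants
are numbered 1=NW, 2=NE, 3=SW, 4=SE and labelled ``RRCC/Q``.

All degree arithmetic is done in exact rational minutes so that points
on cell boundaries are assigned deterministically: intervals are
half-open, closed on the north and west edges, so a point on a shared
meridian belongs to the eastern neighbour and a point on a shared
parallel to the northern cell.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import IntEnum
from fractions import Fraction
from typing import Iterator, Union

from .models import GabretaError

Number = Union[int, float, Fraction]

#: arc-minutes per base cell / quadrant along each axis
BASE_LON_MIN = Fraction(10)
BASE_LAT_MIN = Fraction(6)
QUAD_LON_MIN = Fraction(5)
QUAD_LAT_MIN = Fraction(3)


class OutOfGridError(GabretaError):
    """Point lies north or west of the grid origin."""


class Quadrant(IntEnum):
    NW = 1
    NE = 2
    SW = 3
    SE = 4


@dataclass(frozen=True)
class GridSpec:
    """Grid origin (northwest reference corner) in exact arc-minutes.

    The default origin 55°06'N, 5°40'E is the TK25 sheet-grid reference
    corner; other national CEBA offsets are obtained by overriding it.
    """

    origin_lat_min: Fraction = Fraction(55 * 60 + 6)  # 55°06'N
    origin_lon_min: Fraction = Fraction(5 * 60 + 40)  # 5°40'E

    @property
    def origin_lat(self) -> Fraction:
        return self.origin_lat_min / 60

    @property
    def origin_lon(self) -> Fraction:
        return self.origin_lon_min / 60


DEFAULT_GRID = GridSpec()


@dataclass(frozen=True, order=True)
class QuadrantRef:
    """One 5'x3' quadrant: base-cell row/col plus quadrant position."""

    base_row: int
    base_col: int
    quadrant: Quadrant

    def __post_init__(self) -> None:
        if self.base_row < 0 or self.base_col < 0:
            raise ValueError("base cell indices must be non-negative")
        if self.quadrant not in (1, 2, 3, 4):
            raise ValueError(f"quadrant must be 1..4, got {self.quadrant}")

    @property
    def label(self) -> str:
        return format_label(self)


_LABEL_RE = re.compile(r"^(\d{2,})(\d{2})/([1-4])$")


def format_label(q: QuadrantRef) -> str:
    """Format as ``RRCC/Q``, row and column zero-padded to two digits."""
    return f"{q.base_row:02d}{q.base_col:02d}/{int(q.quadrant)}"


def parse_label(label: str) -> QuadrantRef:
    """Parse a ``RRCC/Q`` quadrant label; raises ValueError when malformed."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed quadrant label: {label!r}")
    row, col, quad = int(m.group(1)), int(m.group(2)), int(m.group(3))
    return QuadrantRef(row, col, Quadrant(quad))


def point_to_quadrant(
    latitude: Number, longitude: Number, spec: GridSpec = DEFAULT_GRID
) -> QuadrantRef:
    """Assign a WGS84 point to the unique quadrant containing it.

    Uses exact rational arithmetic when given Fractions or ints;
    floats are converted via Fraction(float) so the half-open rule
    stays exact for representable inputs.
    """
    lat_min = Fraction(latitude) * 60
    lon_min = Fraction(longitude) * 60
    south_of_origin = spec.origin_lat_min - lat_min  # grows southwards
    east_of_origin = lon_min - spec.origin_lon_min  # grows eastwards
    if south_of_origin < 0 or east_of_origin < 0:
        raise OutOfGridError(
            f"point ({float(latitude)}, {float(longitude)}) lies north/west of grid origin"
        )
    # closed on north and west edges: exact multiples floor to the
    # cell whose north/west edge carries the point
    base_row = int(south_of_origin // BASE_LAT_MIN)
    base_col = int(east_of_origin // BASE_LON_MIN)
    sub_row = int((south_of_origin - base_row * BASE_LAT_MIN) // QUAD_LAT_MIN)
    sub_col = int((east_of_origin - base_col * BASE_LON_MIN) // QUAD_LON_MIN)
    quadrant = Quadrant(1 + sub_col + 2 * sub_row)
    return QuadrantRef(base_row, base_col, quadrant)


def quadrant_bounds(
    q: QuadrantRef, spec: GridSpec = DEFAULT_GRID
) -> tuple[Fraction, Fraction, Fraction, Fraction]:
    """Exact (south, west, north, east) bounds in decimal degrees."""
    sub_row = 0 if q.quadrant in (Quadrant.NW, Quadrant.NE) else 1
    sub_col = 0 if q.quadrant in (Quadrant.NW, Quadrant.SW) else 1
    north_min = spec.origin_lat_min - q.base_row * BASE_LAT_MIN - sub_row * QUAD_LAT_MIN
    west_min = spec.origin_lon_min + q.base_col * BASE_LON_MIN + sub_col * QUAD_LON_MIN
    south_min = north_min - QUAD_LAT_MIN
    east_min = west_min + QUAD_LON_MIN
    return (south_min / 60, west_min / 60, north_min / 60, east_min / 60)


def quadrant_centre(q: QuadrantRef, spec: GridSpec = DEFAULT_GRID) -> tuple[Fraction, Fraction]:
    """(latitude, longitude) of the quadrant centre, exact."""
    south, west, north, east = quadrant_bounds(q, spec)
    return ((south + north) / 2, (west + east) / 2)


def quadrant_polygon(
    q: QuadrantRef, spec: GridSpec = DEFAULT_GRID
) -> list[tuple[float, float]]:
    """Closed 5-point rectangular ring in (lon, lat) order, CCW."""
    south, west, north, east = (float(v) for v in quadrant_bounds(q, spec))
    return [(west, south), (east, south), (east, north), (west, north), (west, south)]


def quadrants_geojson(
    quads: Iterator[QuadrantRef], spec: GridSpec = DEFAULT_GRID
) -> dict:
    """GeoJSON FeatureCollection of quadrant rectangles (WGS84 lon-lat)."""
    features = []
    for q in quads:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [
                    [list(pt) for pt in quadrant_polygon(q, spec)]
                ]},
                "properties": {"label": format_label(q)},
            }
        )
    return {"type": "FeatureCollection", "features": features}
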