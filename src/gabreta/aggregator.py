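"""Quadrant-level aggregation into distribution-map cells.

Filtered, taxon-mapped records are generalised to the CEBA quadrant
grid: one map cell per (consensus taxon, quadrant), labelled by the
highest reliability status reached by any record in that cell, with a
temporal split flagging whether the occurrence was confirmed recently
(year >= 2000 by default) or only historically.  Erroneous records are
counted but can neither establish presence nor set the label; a cell
exists only where at least one non-erroneous record falls.  Curators
can force a cell's reliability (or create a data-free cell) through a
manual override table, applied last so it survives re-aggregation.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

from .ceba_grid import (
    DEFAULT_GRID,
    GridSpec,
    QuadrantRef,
    format_label,
    parse_label,
    point_to_quadrant,
    quadrant_polygon,
)
from .models import GabretaError, MappedOccurrence, Reject, Reliability
from .status_crosswalk import max_reliability

#: first year counted as "recent" (the pre/post split of the atlas maps)
DEFAULT_BOUNDARY_YEAR = 2000

AmbiguityPolicy = Literal["all", "exclude"]


@dataclass
class QuadrantTaxonStatus:
    """One aggregated map cell: consensus taxon x quadrant."""

    fsg_id: str
    quadrant: QuadrantRef
    best_reliability: Optional[Reliability]
    n_records: int = 0
    n_recent: int = 0
    n_historical: int = 0
    undated_count: int = 0
    ambiguous_only: bool = False
    overridden: bool = False

    @property
    def recent(self) -> bool:
        return self.n_recent > 0

    @property
    def historical(self) -> bool:
        return self.n_historical > 0

    @property
    def label(self) -> str:
        return format_label(self.quadrant)


@dataclass(frozen=True)
class OverrideEntry:
    """Manual quadrant-taxon reliability override, with audit fields."""

    fsg_id: str
    quadrant_label: str
    reliability: Reliability
    note: str = ""
    author: str = ""
    date: str = ""

    def quadrant(self) -> QuadrantRef:
        return parse_label(self.quadrant_label)


def record_quadrant(
    mapped: MappedOccurrence, spec: GridSpec = DEFAULT_GRID
) -> QuadrantRef:
    """Quadrant of a mapped record: from coordinates, else the grid code."""
    rec = mapped.record
    if rec.has_point:
        return point_to_quadrant(rec.latitude, rec.longitude, spec)
    return parse_label(rec.grid_code)


def aggregate(
    mapped_records: Iterable[MappedOccurrence],
    spec: GridSpec = DEFAULT_GRID,
    boundary_year: int = DEFAULT_BOUNDARY_YEAR,
    ambiguity: AmbiguityPolicy = "all",
) -> tuple[list[QuadrantTaxonStatus], list[Reject]]:
    """Group mapped records into map cells.

    Ambiguous records (mapping to several consensus taxa) contribute
    presence to every mapped taxon under the default ``"all"`` policy,
    or are dropped entirely under ``"exclude"``.  Records whose grid
    code fails to parse are rejected, not fatal.  Cells whose records
    are all ERRONEOUS are suppressed; cells fed only by ambiguous
    records are flagged ``ambiguous_only``.
    """
    groups: dict[tuple[str, QuadrantRef], list[MappedOccurrence]] = {}
    rejects: list[Reject] = []
    for i, mapped in enumerate(mapped_records):
        if ambiguity == "exclude" and mapped.ambiguous:
            continue
        try:
            quadrant = record_quadrant(mapped, spec)
        except (ValueError, GabretaError) as exc:  # parse/out-of-grid
            rejects.append(Reject(i, str(exc), mapped.record.record_id))
            continue
        for fsg_id in mapped.fsg_ids:
            groups.setdefault((fsg_id, quadrant), []).append(mapped)

    cells: list[QuadrantTaxonStatus] = []
    for (fsg_id, quadrant), members in groups.items():
        reliabilities = [
            m.record.reliability or Reliability.NOT_YET_REVISED for m in members
        ]
        best = max_reliability(reliabilities)
        if best is None:  # only erroneous evidence: no presence
            continue
        n_recent = n_historical = undated = 0
        for m in members:
            year = m.record.event_year
            if year is None:
                undated += 1
            elif year >= boundary_year:
                n_recent += 1
            else:
                n_historical += 1
        cells.append(
            QuadrantTaxonStatus(
                fsg_id=fsg_id,
                quadrant=quadrant,
                best_reliability=best,
                n_records=len(members),
                n_recent=n_recent,
                n_historical=n_historical,
                undated_count=undated,
                ambiguous_only=all(m.ambiguous for m in members),
            )
        )
    cells.sort(key=lambda c: (c.fsg_id, c.quadrant))
    return cells, rejects


def load_overrides(source: Union[str, Path, io.TextIOBase]) -> list[OverrideEntry]:
    """Load the manual override CSV; malformed quadrant labels name the row."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        fh: io.TextIOBase = open(source, newline="", encoding="utf-8")
        close = True
    elif isinstance(source, str):
        fh, close = io.StringIO(source), False
    else:
        fh, close = source, False
    entries: list[OverrideEntry] = []
    try:
        for row_no, row in enumerate(csv.DictReader(fh), start=1):
            entry = OverrideEntry(
                fsg_id=row["fsg_id"].strip(),
                quadrant_label=row["quadrant"].strip(),
                reliability=Reliability(row["reliability"].strip().upper()),
                note=(row.get("note") or "").strip(),
                author=(row.get("author") or "").strip(),
                date=(row.get("date") or "").strip(),
            )
            try:
                entry.quadrant()
            except ValueError as exc:
                raise ValueError(f"override row {row_no}: {exc}") from None
            entries.append(entry)
    finally:
        if close:
            fh.close()
    return entries


def apply_overrides(
    cells: Sequence[QuadrantTaxonStatus], overrides: Sequence[OverrideEntry]
) -> list[QuadrantTaxonStatus]:
    """Apply manual overrides, creating missing cells (n_records=0).

    An override replaces the cell's best_reliability and marks it
    overridden; all other cells pass through untouched.
    """
    by_key = {(c.fsg_id, c.quadrant): replace(c) for c in cells}
    for entry in overrides:
        key = (entry.fsg_id, entry.quadrant())
        if key in by_key:
            cell = by_key[key]
            cell.best_reliability = entry.reliability
            cell.overridden = True
        else:
            by_key[key] = QuadrantTaxonStatus(
                fsg_id=entry.fsg_id,
                quadrant=entry.quadrant(),
                best_reliability=entry.reliability,
                overridden=True,
            )
    result = list(by_key.values())
    result.sort(key=lambda c: (c.fsg_id, c.quadrant))
    return result


PeriodFilter = Optional[Literal["recent", "historical"]]


def export_map(
    cells: Sequence[QuadrantTaxonStatus],
    fsg_names: Optional[dict[str, str]] = None,
    taxon_filter: Optional[set[str]] = None,
    period_filter: PeriodFilter = None,
    spec: GridSpec = DEFAULT_GRID,
) -> tuple[dict, str]:
    """Export cells as (GeoJSON FeatureCollection, long-format CSV text).

    ``period_filter="recent"`` keeps cells confirmed after the boundary
    year (or overridden/undated-only cells), ``"historical"`` keeps cells
    with any pre-boundary record.  Feature order is deterministic:
    fsg_id, then quadrant label.
    """
    names = fsg_names or {}
    selected = []
    for cell in sorted(cells, key=lambda c: (c.fsg_id, c.quadrant)):
        if taxon_filter is not None and cell.fsg_id not in taxon_filter:
            continue
        if period_filter == "recent" and cell.historical and not cell.recent:
            continue  # historical-only cells drop out of the recent view
        if period_filter == "historical" and not cell.historical:
            continue
        selected.append(cell)

    features = []
    csv_buf = io.StringIO()
    writer = csv.writer(csv_buf, lineterminator="\n")
    writer.writerow(
        ["fsg_id", "name", "label", "best_reliability", "recent", "historical",
         "n_recent", "n_historical", "undated_count", "n_records", "ambiguous_only",
         "overridden"]
    )
    for cell in selected:
        props = {
            "fsg_id": cell.fsg_id,
            "name": names.get(cell.fsg_id, ""),
            "label": cell.label,
            "best_reliability": cell.best_reliability.value if cell.best_reliability else None,
            "recent": cell.recent,
            "historical": cell.historical,
            "n_records": cell.n_records,
            "overridden": cell.overridden,
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(pt) for pt in quadrant_polygon(cell.quadrant, spec)]],
                },
                "properties": props,
            }
        )
        writer.writerow(
            [
                cell.fsg_id,
                names.get(cell.fsg_id, ""),
                cell.label,
                cell.best_reliability.value if cell.best_reliability else "",
                cell.recent,
                cell.historical,
                cell.n_recent,
                cell.n_historical,
                cell.undated_count,
                cell.n_records,
                cell.ambiguous_only,
                cell.overridden,
            ]
        )
    collection = {"type": "FeatureCollection", "features": features}
    return collection, csv_buf.getvalue()


def cells_to_csv(cells: Sequence[QuadrantTaxonStatus]) -> str:
    """Serialise cells for inter-stage hand-off."""
    _, text = export_map(cells)
    return text


def cells_from_csv(text: Union[str, Path]) -> list[QuadrantTaxonStatus]:
    """Read cells back from the inter-stage CSV."""
    if isinstance(text, Path) or "\n" not in str(text):
        text = Path(text).read_text(encoding="utf-8")
    cells = []
    for row in csv.DictReader(io.StringIO(text)):
        cells.append(
            QuadrantTaxonStatus(
                fsg_id=row["fsg_id"],
                quadrant=parse_label(row["label"]),
                best_reliability=Reliability(row["best_reliability"])
                if row["best_reliability"]
                else None,
                n_records=int(row["n_records"]),
                n_recent=int(row["n_recent"]),
                n_historical=int(row["n_historical"]),
                undated_count=int(row["undated_count"]),
                ambiguous_only=row["ambiguous_only"] == "True",
                overridden=row["overridden"] == "True",
            )
        )
    return cells


def map_geojson_text(collection: dict) -> str:
    return json.dumps(collection, indent=2, sort_keys=True)
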