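"""Reading and writing occurrence records.

Two source shapes are supported: ABCD 2.1-style XML archives (the
exchange format in which the Bavarian collection database publishes its
validated occurrence data, optionally zipped) and delimited text tables
with a header row (the spreadsheet/CSV route used for direct user
contributions).  Both are normalised into :class:`OccurrenceRecord`;
units or rows that violate the record invariants are returned in a
separate reject list with their position and reason, never dropped
silently and never a crash.

Only a reduced element set is read from the ABCD documents.  The exact
unit-level paths are a documented, overridable table
(:class:`AbcdPathConfig`) following ABCD 2.1 element naming; the four
``Identification/References/Reference`` elements carry the persistent
taxon-name PID of the source checklist, which is extracted from the
Reference URI or GUID.
"""

from __future__ import annotations

import csv
import io
import re
import zipfile
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence, Union

from lxml import etree

from .models import (
    LoadError,
    OccurrenceRecord,
    RecordBasis,
    Reject,
    Reliability,
    SourceSystem,
    parse_record_basis,
)

# ---------------------------------------------------------------------------
# ABCD XML
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbcdPathConfig:
    """Unit-relative element paths (local names, '/'-separated).

    Defaults follow ABCD 2.1 element naming; the grid-code path is a
    project choice (grid-referenced units name their quadrant as a
    gathering NamedArea) and deliberately configurable because the
    standard does not prescribe where atlas grid codes live.
    """

    unit_id: str = "UnitID"
    record_basis: str = "RecordBasis"
    full_scientific_name: str = (
        "Identification/Result/TaxonIdentified/ScientificName/FullScientificNameString"
    )
    reference: str = "Identification/References/Reference"
    reference_guid: str = "ReferenceGUID"
    reference_title: str = "TitleCitation"
    reference_citation: str = "CitationDetail"
    reference_uri: str = "URI"
    gathering_date: str = "Gathering/DateTime/ISODateTimeBegin"
    latitude: str = (
        "Gathering/SiteCoordinateSets/SiteCoordinates/CoordinatesLatLong/LatitudeDecimal"
    )
    longitude: str = (
        "Gathering/SiteCoordinateSets/SiteCoordinates/CoordinatesLatLong/LongitudeDecimal"
    )
    grid_code: str = "Gathering/NamedAreas/NamedArea/AreaName"


DEFAULT_ABCD_PATHS = AbcdPathConfig()

_PID_RE = re.compile(r"(\d+)/?\s*$")
_YEAR_RE = re.compile(r"(\d{4})")


def extract_taxref_pid(uri_or_guid: str) -> Optional[str]:
    """Pull the trailing numeric PID out of a Reference URI or GUID."""
    m = _PID_RE.search(uri_or_guid.strip())
    return m.group(1) if m else None


def parse_event_year(text: str) -> Optional[int]:
    """Accept ISO dates and bare years; only the year is retained."""
    m = _YEAR_RE.search(text.strip())
    return int(m.group(1)) if m else None


def _local_find(element, path: str):
    """Namespace-agnostic descent by local element names."""
    current = [element]
    for name in path.split("/"):
        nxt = []
        for el in current:
            nxt.extend(
                child
                for child in el
                if isinstance(child.tag, str) and etree.QName(child).localname == name
            )
        current = nxt
        if not current:
            return None
    return current[0]


def _local_text(element, path: str) -> Optional[str]:
    found = _local_find(element, path)
    if found is None or found.text is None:
        return None
    text = found.text.strip()
    return text or None


def _iter_units(root) -> list:
    return [
        el
        for el in root.iter()
        if isinstance(el.tag, str) and etree.QName(el).localname == "Unit"
    ]


def read_abcd(
    source: Union[str, Path, bytes],
    paths: AbcdPathConfig = DEFAULT_ABCD_PATHS,
    source_system: SourceSystem = SourceSystem.BFL,
    default_reliability: Optional[Reliability] = Reliability.RELIABLE,
) -> tuple[list[OccurrenceRecord], list[Reject]]:
    """Parse an ABCD-style XML document (or ``.zip`` of documents).

    Returns accepted records in document order plus rejects for units
    lacking a unit ID or any usable location.  Records published via the
    validated archives carry no explicit reliability status and default
    to RELIABLE (they are validated by definition); pass
    ``default_reliability=None`` to leave them unset.

    Malformed XML raises ``lxml.etree.XMLSyntaxError`` (which names the
    offending line).
    """
    documents: list[bytes] = []
    if isinstance(source, bytes):
        documents.append(source)
    else:
        path = Path(source)
        if path.suffix.lower() == ".zip":
            with zipfile.ZipFile(path) as zf:
                for name in sorted(zf.namelist()):
                    if name.lower().endswith(".xml"):
                        documents.append(zf.read(name))
        else:
            documents.append(path.read_bytes())

    records: list[OccurrenceRecord] = []
    rejects: list[Reject] = []
    index = 0
    for doc in documents:
        root = etree.fromstring(doc)
        for unit in _iter_units(root):
            index += 1
            unit_id = _local_text(unit, paths.unit_id)
            if unit_id is None:
                rejects.append(Reject(index, "missing unit id"))
                continue
            pid: Optional[str] = None
            ref = _local_find(unit, paths.reference)
            if ref is not None:
                for ref_path in (paths.reference_uri, paths.reference_guid):
                    raw = _local_text(ref, ref_path)
                    if raw:
                        pid = extract_taxref_pid(raw)
                        if pid:
                            break
            lat_text = _local_text(unit, paths.latitude)
            lon_text = _local_text(unit, paths.longitude)
            try:
                lat = float(lat_text) if lat_text is not None else None
                lon = float(lon_text) if lon_text is not None else None
            except ValueError:
                rejects.append(Reject(index, "unparseable coordinates", unit_id))
                continue
            date_text = _local_text(unit, paths.gathering_date)
            record = OccurrenceRecord(
                record_id=unit_id,
                source_system=source_system,
                scientific_name=_local_text(unit, paths.full_scientific_name) or "",
                source_taxon_pid=pid,
                latitude=lat,
                longitude=lon,
                grid_code=_local_text(unit, paths.grid_code),
                event_year=parse_event_year(date_text) if date_text else None,
                record_basis=parse_record_basis(_local_text(unit, paths.record_basis)),
                reliability=default_reliability,
            )
            error = record.validation_error()
            if error:
                rejects.append(Reject(index, error, unit_id))
            else:
                records.append(record)
    return records, rejects


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

#: fixed output column order; identity column mapping for round trips
COLUMNS: tuple[str, ...] = tuple(f.name for f in dc_fields(OccurrenceRecord))

IDENTITY_MAPPING: dict[str, str] = {c: c for c in COLUMNS}

_MANDATORY_FIELDS = ("record_id", "scientific_name")


def _open_text(source: Union[str, Path, io.TextIOBase]):
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return open(source, newline="", encoding="utf-8"), True
    if isinstance(source, str):
        return io.StringIO(source), False
    return source, False


def read_occurrence_table(
    source: Union[str, Path, io.TextIOBase],
    column_mapping: Optional[dict[str, str]] = None,
    delimiter: str = ",",
) -> tuple[list[OccurrenceRecord], list[Reject]]:
    """Read records from delimited text with a header row.

    ``column_mapping`` maps OccurrenceRecord field names to source
    column names (identity by default).  An unmapped mandatory field
    (record_id, scientific_name) is a configuration error raised before
    any row is read; rows violating record invariants become rejects
    carrying their 1-based data row number.
    """
    mapping = dict(column_mapping) if column_mapping is not None else dict(IDENTITY_MAPPING)
    for field in _MANDATORY_FIELDS:
        if field not in mapping:
            raise LoadError(f"column mapping lacks mandatory field {field!r}")
    fh, close = _open_text(source)
    records: list[OccurrenceRecord] = []
    rejects: list[Reject] = []
    try:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [col for col in (mapping[f] for f in _MANDATORY_FIELDS) if col not in header]
        if missing:
            raise LoadError(f"mandatory column(s) missing from header: {missing}")
        for row_no, row in enumerate(reader, start=1):
            def cell(field: str) -> Optional[str]:
                col = mapping.get(field)
                if col is None or col not in row:
                    return None
                value = (row[col] or "").strip()
                return value or None

            try:
                record = OccurrenceRecord(
                    record_id=cell("record_id") or "",
                    source_system=SourceSystem(cell("source_system") or "OTHER"),
                    scientific_name=cell("scientific_name") or "",
                    source_taxon_pid=cell("source_taxon_pid"),
                    latitude=float(cell("latitude")) if cell("latitude") else None,
                    longitude=float(cell("longitude")) if cell("longitude") else None,
                    grid_code=cell("grid_code"),
                    event_year=int(cell("event_year")) if cell("event_year") else None,
                    record_basis=RecordBasis(cell("record_basis"))
                    if cell("record_basis") in RecordBasis.__members__
                    else parse_record_basis(cell("record_basis")),
                    floristic_status_code=cell("floristic_status_code"),
                    reliability=Reliability(cell("reliability")) if cell("reliability") else None,
                    licence=cell("licence") or "",
                    project_tag=cell("project_tag"),
                )
            except (ValueError, KeyError) as exc:
                rejects.append(Reject(row_no, f"unparseable row: {exc}", cell("record_id")))
                continue
            error = record.validation_error()
            if error:
                rejects.append(Reject(row_no, error, record.record_id))
            else:
                records.append(record)
    finally:
        if close:
            fh.close()
    return records, rejects


def write_occurrence_table(
    records: Sequence[OccurrenceRecord],
    destination: Union[str, Path, io.TextIOBase, None] = None,
    delimiter: str = ",",
) -> str:
    """Write records as delimited text in the fixed documented column order.

    Lossless: ``read_occurrence_table(write_occurrence_table(x))`` is the
    identity on valid records.  Returns the text; also writes to
    ``destination`` when given.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(COLUMNS)
    for rec in records:
        row = []
        for col in COLUMNS:
            value = getattr(rec, col)
            if value is None:
                row.append("")
            elif isinstance(value, float):
                row.append(repr(value))
            elif hasattr(value, "value"):  # enums
                row.append(value.value)
            else:
                row.append(str(value))
        writer.writerow(row)
    text = buf.getvalue()
    if destination is not None:
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text, encoding="utf-8")
        else:
            destination.write(text)
    return text
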