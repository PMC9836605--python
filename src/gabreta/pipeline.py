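"""End-to-end orchestration of the seven integration steps.

ingest -> resolve/convert/crosswalk (harmonize) -> spatial filter ->
aggregate -> overrides -> export.  Stages hand off through documented
CSV schemas rather than an internal database, mirroring the batch
design of the source infrastructure, so every stage can also be run
standalone on the previous stage's outputs and chaining the stages is
byte-identical to the one-shot run.

Rejects (invalid rows, unmapped taxa, unparseable grid codes) are data
outcomes written to reject files and tallied in the machine-readable
run report; only structural errors (missing files, corrupt tables)
abort a run.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import aggregator, records_io, spatial_filter, status_crosswalk, taxon_converter
from .aggregator import AmbiguityPolicy, QuadrantTaxonStatus
from .ceba_grid import DEFAULT_GRID, GridSpec
from .models import LoadError, MappedOccurrence, OccurrenceRecord, Reject, SourceSystem
from .taxon_converter import ConverterTable
from .taxon_registry import TaxonRegistry, load_registry


@dataclass
class PipelineConfig:
    """Paths and policies for a full run."""

    records: Path
    registry: Path
    converter_pladias: Path
    converter_bfl: Path
    consensus_names: Path
    inner: Path
    outer: Path
    out_dir: Path
    abcd: Optional[Path] = None
    overrides: Optional[Path] = None
    crosswalk: Optional[Path] = None
    boundary_year: int = aggregator.DEFAULT_BOUNDARY_YEAR
    ambiguity: AmbiguityPolicy = "all"
    delimiter: str = ","
    grid: GridSpec = field(default_factory=lambda: DEFAULT_GRID)

    def validate_paths(self) -> None:
        for name in ("records", "registry", "converter_pladias", "converter_bfl",
                     "consensus_names", "inner", "outer", "abcd", "overrides",
                     "crosswalk"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input {name!r} not found: {path}")


def _write_rejects(path: Path, rejects: Sequence[Reject]) -> None:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["index", "record_id", "reason"])
    for rej in rejects:
        writer.writerow([rej.index, rej.record_id or "", rej.reason])
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_ingest(
    records_path: Path,
    abcd_path: Optional[Path] = None,
    delimiter: str = ",",
) -> tuple[list[OccurrenceRecord], list[Reject]]:
    """Read the delimited table and optionally an ABCD archive; concatenate."""
    records, rejects = records_io.read_occurrence_table(records_path, delimiter=delimiter)
    if abcd_path is not None:
        abcd_records, abcd_rejects = records_io.read_abcd(abcd_path)
        records += abcd_records
        rejects += abcd_rejects
    return records, rejects


MAPPED_COLUMNS = ("accepted_source_pid", "fsg_ids", "ambiguous",
                  "pladias_origin", "poss_native", "poss_introduced", "poss_cultivated")


def stage_harmonize(
    records: Sequence[OccurrenceRecord],
    registry: TaxonRegistry,
    table: ConverterTable,
    crosswalk: Optional[dict] = None,
) -> tuple[list[MappedOccurrence], list[Reject], list[dict]]:
    """Resolve names, map to consensus taxa, crosswalk floristic statuses.

    Returns mapped occurrences, taxon rejects, and per-record status
    annotations (the origin/POSS translation of BFL status codes).
    """
    mapped: list[MappedOccurrence] = []
    rejects: list[Reject] = []
    annotations: list[dict] = []
    for i, record in enumerate(records, start=1):
        outcome = taxon_converter.map_record(record, registry, table, index=i)
        if isinstance(outcome, Reject):
            rejects.append(outcome)
            continue
        mapped.append(outcome)
        annotation = {"record_id": record.record_id, "pladias_origin": "",
                      "poss_native": "", "poss_introduced": "", "poss_cultivated": ""}
        if record.source_system is SourceSystem.BFL and record.floristic_status_code:
            result = status_crosswalk.crosswalk_bfl_status(
                record.floristic_status_code, crosswalk
            )
            annotation.update(
                pladias_origin=result.pladias_origin.value,
                poss_native=result.poss_native,
                poss_introduced=result.poss_introduced,
                poss_cultivated=result.poss_cultivated,
            )
        annotations.append(annotation)
    return mapped, rejects, annotations


def mapped_to_csv(mapped: Sequence[MappedOccurrence]) -> str:
    """Inter-stage serialisation of mapped occurrences."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(list(records_io.COLUMNS) + ["accepted_source_pid", "fsg_ids"])
    base_rows = records_io.write_occurrence_table([m.record for m in mapped]).splitlines()[1:]
    for m, base in zip(mapped, base_rows):
        writer.writerow(next(csv.reader([base])) + [m.accepted_source_pid,
                                                    "|".join(sorted(m.fsg_ids))])
    return buf.getvalue()


def mapped_from_csv(source: Path | str) -> list[MappedOccurrence]:
    text = Path(source).read_text(encoding="utf-8") if "\n" not in str(source) else str(source)
    reader = csv.DictReader(io.StringIO(text))
    base_cols = list(records_io.COLUMNS)
    mapped = []
    for row in reader:
        base_text_buf = io.StringIO()
        w = csv.writer(base_text_buf, lineterminator="\n")
        w.writerow(base_cols)
        w.writerow([row[c] for c in base_cols])
        records, rejects = records_io.read_occurrence_table(base_text_buf.getvalue())
        if rejects:
            raise LoadError(f"corrupt mapped row: {rejects[0].reason}")
        mapped.append(
            MappedOccurrence(
                record=records[0],
                accepted_source_pid=row["accepted_source_pid"],
                fsg_ids=frozenset(row["fsg_ids"].split("|")),
            )
        )
    return mapped


def stage_filter(
    mapped: Sequence[MappedOccurrence],
    polygons: spatial_filter.StudyAreaPolygons,
    grid: GridSpec = DEFAULT_GRID,
) -> tuple[list[MappedOccurrence], list[MappedOccurrence], list[MappedOccurrence]]:
    """Partition mapped occurrences by study-area region."""
    final: list[MappedOccurrence] = []
    candidates: list[MappedOccurrence] = []
    discards: list[MappedOccurrence] = []
    buckets = {
        spatial_filter.RegionClass.INNER: final,
        spatial_filter.RegionClass.OUTER_ONLY: candidates,
        spatial_filter.RegionClass.OUTSIDE: discards,
    }
    for m in mapped:
        buckets[spatial_filter.classify_record(m.record, polygons, grid)].append(m)
    return final, candidates, discards


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write stage outputs + a JSON run report.

    Returns the report dict.  Raises on structural errors (missing
    inputs, corrupt tables); rejects never raise.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ingest
    records, ingest_rejects = stage_ingest(config.records, config.abcd, config.delimiter)
    records_io.write_occurrence_table(records, out / "ingested.csv")
    _write_rejects(out / "rejects_ingest.csv", ingest_rejects)

    # harmonize
    registry = load_registry(config.registry)
    table = taxon_converter.load_converter(
        config.converter_pladias, config.converter_bfl, config.consensus_names
    )
    crosswalk = (
        status_crosswalk.crosswalk_table(config.crosswalk) if config.crosswalk else None
    )
    mapped, taxon_rejects, annotations = stage_harmonize(records, registry, table, crosswalk)
    (out / "mapped.csv").write_text(mapped_to_csv(mapped), encoding="utf-8")
    _write_rejects(out / "rejects_taxon.csv", taxon_rejects)
    _write_annotations(out / "status_annotations.csv", annotations)

    # spatial filter
    polygons = spatial_filter.load_study_area(config.inner, config.outer)
    final, candidates, discards = stage_filter(mapped, polygons, config.grid)
    for name, bucket in (("final", final), ("candidates", candidates), ("discards", discards)):
        (out / f"{name}.csv").write_text(mapped_to_csv(bucket), encoding="utf-8")

    # aggregate + overrides
    cells, grid_rejects = aggregator.aggregate(
        final, config.grid, config.boundary_year, config.ambiguity
    )
    _write_rejects(out / "rejects_grid.csv", grid_rejects)
    if config.overrides:
        overrides = aggregator.load_overrides(config.overrides)
        cells = aggregator.apply_overrides(cells, overrides)
    else:
        overrides = []

    # export
    collection, cells_csv = aggregator.export_map(cells, fsg_names=table.fsg_names,
                                                  spec=config.grid)
    (out / "map.geojson").write_text(aggregator.map_geojson_text(collection), encoding="utf-8")
    (out / "map.csv").write_text(cells_csv, encoding="utf-8")

    report = {
        "ingest": {"accepted": len(records), "rejected": len(ingest_rejects)},
        "harmonize": {
            "mapped": len(mapped),
            "rejected": len(taxon_rejects),
            "ambiguous": sum(1 for m in mapped if m.ambiguous),
        },
        "filter": {
            "final": len(final),
            "candidates": len(candidates),
            "discards": len(discards),
        },
        "aggregate": {
            "cells": len(cells),
            "grid_rejects": len(grid_rejects),
            "overrides_applied": len(overrides),
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")
    return report


def _write_annotations(path: Path, annotations: Sequence[dict]) -> None:
    buf = io.StringIO()
    writer = csv.DictWriter(
        buf,
        fieldnames=["record_id", "pladias_origin", "poss_native", "poss_introduced",
                    "poss_cultivated"],
        lineterminator="\n",
    )
    writer.writeheader()
    writer.writerows(annotations)
    path.write_text(buf.getvalue(), encoding="utf-8")


def cells_as_dicts(cells: Sequence[QuadrantTaxonStatus]) -> list[dict]:
    """Canonical comparable form of aggregated cells (for oracle tests)."""
    return [
        {
            "fsg_id": c.fsg_id,
            "label": c.label,
            "best_reliability": c.best_reliability.value if c.best_reliability else None,
            "n_records": c.n_records,
            "n_recent": c.n_recent,
            "n_historical": c.n_historical,
            "undated_count": c.undated_count,
            "ambiguous_only": c.ambiguous_only,
        }
        for c in sorted(cells, key=lambda c: (c.fsg_id, c.label))
    ]
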