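"""Two-part many-to-many taxon converter onto the consensus taxonomy.

Because the Czech (Pladias) and Bavarian (BFL) reference checklists use
different taxon concepts and classifications, neither can be mapped
one-to-one onto the other.  The converter therefore links both to a
third, agreed (consensus, "FSG") taxonomy through two independent
many-to-many parts: Pladias taxon IDs -> FSG taxon IDs, and BFL TaxRef
PIDs -> FSG taxon IDs.  The converter is curated by experts; taxa it
does not cover yield rejects, never errors, so pipelines survive gaps
between converter updates.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .models import (
    GabretaError,
    LoadError,
    MappedOccurrence,
    OccurrenceRecord,
    Reject,
    SourceSystem,
)
from .taxon_registry import TaxonRegistry, resolve_accepted_pid

Source = Union[str, Path, io.TextIOBase]


@dataclass
class ConverterTable:
    """The two mapping parts plus consensus names, indexed both ways."""

    pladias_part: set[tuple[str, str]] = field(default_factory=set)  # (pladias_id, fsg_id)
    bfl_part: set[tuple[str, str]] = field(default_factory=set)  # (bfl_pid, fsg_id)
    fsg_names: dict[str, str] = field(default_factory=dict)

    def _index(self, part: set[tuple[str, str]]) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {}
        for src, fsg in part:
            idx.setdefault(src, set()).add(fsg)
        return idx

    @property
    def pladias_index(self) -> dict[str, set[str]]:
        return self._index(self.pladias_part)

    @property
    def bfl_index(self) -> dict[str, set[str]]:
        return self._index(self.bfl_part)

    def fsg_ids(self) -> set[str]:
        return {fsg for _, fsg in self.pladias_part} | {fsg for _, fsg in self.bfl_part}

    def unsourced_fsg_ids(self) -> list[str]:
        """FSG ids named in fsg_names but paired in neither part (warning list)."""
        mapped = self.fsg_ids()
        return sorted(fsg for fsg in self.fsg_names if fsg not in mapped)

    def validate(self) -> None:
        nameless = sorted(fsg for fsg in self.fsg_ids() if fsg not in self.fsg_names)
        if nameless:
            raise LoadError(f"fsg_id(s) without a consensus name: {nameless}")


def _open(source: Source):
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return open(source, newline="", encoding="utf-8"), True
    if isinstance(source, str):
        return io.StringIO(source), False
    return source, False


def _read_pairs(source: Source, src_col: str) -> set[tuple[str, str]]:
    fh, close = _open(source)
    pairs: set[tuple[str, str]] = set()
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return pairs
        if src_col not in reader.fieldnames or "fsg_id" not in reader.fieldnames:
            raise LoadError(f"converter part must have columns [{src_col}, fsg_id]")
        for i, row in enumerate(reader, start=2):
            pair = (row[src_col].strip(), row["fsg_id"].strip())
            if not pair[0] or not pair[1]:
                raise LoadError(f"empty identifier in converter row {i}")
            if pair in pairs:
                warnings.warn(f"duplicate converter pair {pair} (row {i}), deduplicated")
            pairs.add(pair)
    finally:
        if close:
            fh.close()
    return pairs


def load_converter(pladias_csv: Source, bfl_csv: Source, names_csv: Source) -> ConverterTable:
    """Load the two converter parts and the consensus-name list.

    Columns: ``pladias_id,fsg_id`` / ``bfl_pid,fsg_id`` / ``fsg_id,name``.
    Duplicate pairs are deduplicated with a warning; an fsg_id appearing
    in a part without a consensus name is a load error.
    """
    table = ConverterTable()
    table.pladias_part = _read_pairs(pladias_csv, "pladias_id")
    table.bfl_part = _read_pairs(bfl_csv, "bfl_pid")
    fh, close = _open(names_csv)
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is not None:
            if "fsg_id" not in reader.fieldnames or "name" not in reader.fieldnames:
                raise LoadError("consensus-name CSV must have columns [fsg_id, name]")
            for row in reader:
                table.fsg_names[row["fsg_id"].strip()] = row["name"].strip()
    finally:
        if close:
            fh.close()
    table.validate()
    return table


def map_source_taxon(
    source_system: SourceSystem, source_id: str, table: ConverterTable
) -> set[str]:
    """FSG taxon ids paired with a source taxon id; empty set if unmapped."""
    if source_system is SourceSystem.PLADIAS:
        return set(table.pladias_index.get(source_id, set()))
    if source_system is SourceSystem.BFL:
        return set(table.bfl_index.get(source_id, set()))
    raise GabretaError(f"source system {source_system} has no converter part")


def map_record(
    record: OccurrenceRecord,
    registry: TaxonRegistry,
    table: ConverterTable,
    index: int = 0,
) -> Union[MappedOccurrence, Reject]:
    """Annotate a record with its consensus taxa.

    For BFL records the source PID (or, failing that, the reported
    scientific name) is first resolved to its accepted PID through the
    name registry; Pladias identifiers are plain database IDs outside
    that registry and go straight to the converter.  Unknown names and
    unmapped taxa become rejects for curator review, not errors.
    """
    query: Optional[str] = record.source_taxon_pid or record.scientific_name
    if not query:
        return Reject(index, "no taxon reference", record.record_id)
    if record.source_system is SourceSystem.BFL:
        try:
            accepted = resolve_accepted_pid(query, registry)
        except GabretaError as exc:
            return Reject(index, f"registry resolution failed: {exc}", record.record_id)
    elif record.source_taxon_pid:
        accepted = record.source_taxon_pid
    else:
        return Reject(index, "no source taxon id", record.record_id)
    try:
        fsg_ids = map_source_taxon(record.source_system, accepted, table)
    except GabretaError as exc:
        return Reject(index, str(exc), record.record_id)
    if not fsg_ids:
        return Reject(index, f"accepted pid {accepted!r} unmapped in converter", record.record_id)
    return MappedOccurrence(record=record, accepted_source_pid=accepted, fsg_ids=frozenset(fsg_ids))
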