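"""Local taxon-name registry with persistent IDs and synonym resolution.

Mirrors the semantics of a taxon-names REST lookup service as two pure
functions over a loaded table: resolve any name string or persistent ID
(PID) to the PID of its currently accepted name, and fetch the stored
scientific name for a PID.  Name records carry a category (accepted
name, synonym or basionym) and, for non-accepted names, a pointer to
the name they resolve through; pointer chains must terminate at an
accepted record without cycles, which is validated at load time.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from .models import AmbiguousNameError, LoadError, NotFoundError


class NameCategory(str, Enum):
    ACCEPTED = "ACCEPTED"
    SYNONYM = "SYNONYM"
    BASIONYM = "BASIONYM"


_WS = re.compile(r"\s+")


def normalise_name(name: str) -> str:
    return _WS.sub(" ", name.strip())


@dataclass(frozen=True)
class TaxonNameRecord:
    pid: str
    full_name: str
    category: NameCategory
    accepted_pid: Optional[str] = None
    vernacular_names: tuple[tuple[str, str], ...] = ()


@dataclass
class TaxonRegistry:
    """Validated set of name records with a name index for bare-name lookup."""

    records: dict[str, TaxonNameRecord] = field(default_factory=dict)
    name_index: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def add(self, rec: TaxonNameRecord) -> None:
        if rec.pid in self.records:
            raise LoadError(f"duplicate pid {rec.pid!r}")
        self.records[rec.pid] = rec
        self.name_index.setdefault(normalise_name(rec.full_name), set()).add(rec.pid)

    def validate(self) -> None:
        """Check pointer integrity: no dangling accepted_pid, no cycles."""
        dangling = []
        for rec in self.records.values():
            if rec.category is not NameCategory.ACCEPTED and rec.accepted_pid is None:
                dangling.append(rec.pid)
            elif rec.accepted_pid is not None and rec.accepted_pid not in self.records:
                dangling.append(rec.pid)
        if dangling:
            raise LoadError(f"dangling accepted_pid pointers for pids: {sorted(dangling)}")
        cyclic = []
        for pid in self.records:
            seen = set()
            cur = pid
            while True:
                rec = self.records[cur]
                if rec.category is NameCategory.ACCEPTED:
                    break
                if cur in seen:
                    cyclic.append(pid)
                    break
                seen.add(cur)
                cur = rec.accepted_pid
        if cyclic:
            raise LoadError(f"accepted_pid cycles involving pids: {sorted(set(cyclic))}")


def load_registry(source: Union[str, Path, io.TextIOBase]) -> TaxonRegistry:
    """Load a registry CSV (pid, full_name, category, accepted_pid[, vernaculars]).

    `vernaculars` is an optional column of `lang:name` pairs joined by `|`.
    Raises LoadError on duplicate PIDs, dangling pointers or cycles.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        fh: io.TextIOBase = open(source, newline="", encoding="utf-8")
        close = True
    elif isinstance(source, str):
        fh, close = io.StringIO(source), False
    else:
        fh, close = source, False
    registry = TaxonRegistry()
    try:
        reader = csv.DictReader(fh)
        required = {"pid", "full_name", "category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise LoadError(f"registry CSV must have columns {sorted(required)}")
        for row in reader:
            try:
                category = NameCategory(row["category"].strip().upper())
            except ValueError:
                raise LoadError(f"unknown name category {row['category']!r} for pid {row['pid']!r}")
            vern: tuple[tuple[str, str], ...] = ()
            raw_vern = (row.get("vernaculars") or "").strip()
            if raw_vern:
                vern = tuple(
                    tuple(part.split(":", 1)) for part in raw_vern.split("|") if ":" in part
                )
            accepted = (row.get("accepted_pid") or "").strip() or None
            if category is NameCategory.ACCEPTED and accepted == row["pid"].strip():
                accepted = None  # self-pointer on accepted names is permitted, normalised away
            registry.add(
                TaxonNameRecord(
                    pid=row["pid"].strip(),
                    full_name=normalise_name(row["full_name"]),
                    category=category,
                    accepted_pid=accepted,
                    vernacular_names=vern,
                )
            )
    finally:
        if close:
            fh.close()
    registry.validate()
    return registry


def resolve_accepted_pid(query: str, registry: TaxonRegistry) -> str:
    """Resolve a PID or a scientific-name string to its accepted PID.

    Follows accepted-name pointers until an ACCEPTED record is reached.
    Raises NotFoundError for unknown queries and AmbiguousNameError when a
    bare name is a homonym matching more than one PID.
    """
    if query in registry.records:
        pid = query
    else:
        candidates = registry.name_index.get(normalise_name(query), set())
        if not candidates:
            raise NotFoundError(f"name or pid {query!r} not in registry")
        if len(candidates) > 1:
            raise AmbiguousNameError(query, list(candidates))
        (pid,) = candidates
    # chain length is bounded by registry size (validated acyclic)
    for _ in range(len(registry.records) + 1):
        rec = registry.records[pid]
        if rec.category is NameCategory.ACCEPTED:
            return pid
        pid = rec.accepted_pid  # type: ignore[assignment]
    raise NotFoundError(f"resolution of {query!r} did not terminate")  # pragma: no cover


def get_scientific_name(pid: str, registry: TaxonRegistry) -> str:
    """Return the stored full scientific name for a PID, verbatim."""
    rec = registry.records.get(pid)
    if rec is None:
        raise NotFoundError(f"pid {pid!r} not in registry")
    return rec.full_name
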