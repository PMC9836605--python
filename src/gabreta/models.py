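"""Core domain types shared across the integration pipeline.

A normalised occurrence record is the unit of exchange between every
pipeline stage: it carries the taxon reference as reported by the source
system, one of two location forms (a WGS84 point or a grid-quadrant
label), the observation year, the basis of record, the source-system
floristic status code and the expert-revision reliability status.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class SourceSystem(str, Enum):
    """Origin platform of a record."""

    PLADIAS = "PLADIAS"
    BFL = "BFL"
    OTHER = "OTHER"


class RecordBasis(str, Enum):
    """Basis-of-record vocabulary (three named categories + fallback)."""

    PRESERVED_SPECIMEN = "PRESERVED_SPECIMEN"
    HUMAN_OBSERVATION = "HUMAN_OBSERVATION"
    LITERATURE = "LITERATURE"
    UNKNOWN = "UNKNOWN"


class Reliability(str, Enum):
    """Expert-revision outcome of a record."""

    RELIABLE = "RELIABLE"
    UNCERTAIN = "UNCERTAIN"
    ERRONEOUS = "ERRONEOUS"
    NOT_YET_REVISED = "NOT_YET_REVISED"


_BASIS_ALIASES = {
    "preservedspecimen": RecordBasis.PRESERVED_SPECIMEN,
    "preserved_specimen": RecordBasis.PRESERVED_SPECIMEN,
    "humanobservation": RecordBasis.HUMAN_OBSERVATION,
    "human_observation": RecordBasis.HUMAN_OBSERVATION,
    "literature": RecordBasis.LITERATURE,
}


def parse_record_basis(value: Optional[str]) -> RecordBasis:
    """Match a basis-of-record string case-insensitively; anything else is UNKNOWN."""
    if not value:
        return RecordBasis.UNKNOWN
    return _BASIS_ALIASES.get(value.strip().lower(), RecordBasis.UNKNOWN)


@dataclass(frozen=True)
class OccurrenceRecord:
    """One normalised observation / specimen / literature record.

    Exactly one of the two location forms may be absent but not both:
    either decimal-degree WGS84 coordinates or a grid-quadrant label.
    """

    record_id: str
    source_system: SourceSystem
    scientific_name: str
    source_taxon_pid: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    grid_code: Optional[str] = None
    event_year: Optional[int] = None
    record_basis: RecordBasis = RecordBasis.UNKNOWN
    floristic_status_code: Optional[str] = None
    reliability: Optional[Reliability] = None
    licence: str = ""
    project_tag: Optional[str] = None

    def validation_error(self) -> Optional[str]:
        """Return the first invariant violation, or None when valid."""
        if not self.record_id:
            return "missing record_id"
        if not self.scientific_name:
            return "missing scientific_name"
        has_point = self.latitude is not None and self.longitude is not None
        if not has_point and not self.grid_code:
            return "no location"
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            return "latitude out of range"
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            return "longitude out of range"
        if self.event_year is not None:
            if not 1000 <= self.event_year <= datetime.date.today().year:
                return "event_year out of range"
        return None

    @property
    def has_point(self) -> bool:
        return self.latitude is not None and self.longitude is not None

    def with_(self, **changes) -> "OccurrenceRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class Reject:
    """A record/unit/row that failed validation, with provenance and reason."""

    index: int
    reason: str
    record_id: Optional[str] = None


@dataclass(frozen=True)
class MappedOccurrence:
    """An occurrence annotated with its consensus-taxonomy assignment.

    ``fsg_ids`` holds every consensus taxon the accepted source taxon maps
    to; more than one entry marks the record ambiguous (the converter is
    many-to-many by design).
    """

    record: OccurrenceRecord
    accepted_source_pid: str
    fsg_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.fsg_ids:
            raise ValueError("MappedOccurrence requires a non-empty fsg_id set")

    @property
    def ambiguous(self) -> bool:
        return len(self.fsg_ids) > 1


class GabretaError(Exception):
    """Base class for pipeline errors."""


class NotFoundError(GabretaError):
    """A name or identifier is absent from a registry/table."""


class AmbiguousNameError(GabretaError):
    """A bare name matches more than one identifier (homonym)."""

    def __init__(self, name: str, candidates: list[str]):
        super().__init__(f"name {name!r} matches multiple PIDs: {sorted(candidates)}")
        self.candidates = sorted(candidates)


class LoadError(GabretaError):
    """Structural error while loading an input table."""
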