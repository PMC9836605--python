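"""Loaders for the small reference tables shipped with the package.

The consensus-mapping worked example (the *Aconitum plicatum* case,
where two Czech taxa and four Bavarian names all resolve to one
consensus taxon) doubles as documentation of the converter format and
as a smoke-test input.  The corpus source counts document the two
Bavarian occurrence data sources feeding the integration.
"""

from __future__ import annotations

import csv
import io
from importlib import resources

from .taxon_converter import ConverterTable, load_converter
from .taxon_registry import TaxonRegistry, load_registry


def _text(name: str) -> str:
    return resources.files("gabreta.data").joinpath(name).read_text(encoding="utf-8")


def load_example_converter() -> ConverterTable:
    """The bundled worked-example two-part converter (one consensus taxon)."""
    return load_converter(
        _text("consensus_example_pladias.csv"),
        _text("consensus_example_bfl.csv"),
        _text("consensus_example_names.csv"),
    )


def load_example_registry() -> TaxonRegistry:
    """Name registry covering the worked example's Bavarian names."""
    return load_registry(_text("example_registry.csv"))


def load_bfl_source_counts() -> dict[str, int]:
    """Record counts of the two Bavarian source systems, by source name."""
    return {
        row["source"]: int(row["records"])
        for row in csv.DictReader(io.StringIO(_text("bfl_source_counts.csv")))
    }


def total_source_records(counts: dict[str, int] | None = None) -> int:
    """Total records contributed across the tallied sources."""
    counts = counts if counts is not None else load_bfl_source_counts()
    return sum(counts.values())
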