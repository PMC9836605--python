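"""Floristic-status crosswalk and the reliability ordering.

The Bavarian source system describes each "in situ" occurrence with one
of 13 floristic status codes (indigenous, established, casual,
cultivated, ...).  The Czech system uses a four-value taxon origin
vocabulary (native / non-native / planted / not set), and the TDWG POSS
pre-standard splits establishment into three independent axes (native,
introduced, cultivated status).  This module ships the agreed
translation table between the three vocabularies and exposes it as a
lookup; several BFL codes have no Pladias origin equivalent and map to
the explicit WITHOUT_EQUIVALENT marker.

It also fixes the total order on the record-reliability vocabulary used
when a grid cell is labelled by the best evidence available:
RELIABLE > UNCERTAIN > NOT_YET_REVISED, with ERRONEOUS records excluded
from documenting presence altogether.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .models import GabretaError, Reliability


class PladiasOrigin(str, Enum):
    NATIVE = "NATIVE"
    NON_NATIVE = "NON_NATIVE"
    PLANTED = "PLANTED"
    NOT_SET = "NOT_SET"
    WITHOUT_EQUIVALENT = "WITHOUT_EQUIVALENT"


_ORIGIN_ALIASES = {
    "native": PladiasOrigin.NATIVE,
    "non-native": PladiasOrigin.NON_NATIVE,
    "planted": PladiasOrigin.PLANTED,
    "not set": PladiasOrigin.NOT_SET,
    "without equivalent": PladiasOrigin.WITHOUT_EQUIVALENT,
}


@dataclass(frozen=True)
class CrosswalkResult:
    """One translation row: Pladias origin plus the three POSS axes."""

    code: str
    label: str
    pladias_origin: PladiasOrigin
    poss_native: str
    poss_introduced: str
    poss_cultivated: str


class UnknownStatusCodeError(GabretaError):
    def __init__(self, code: str):
        super().__init__(f"unknown BFL floristic status code {code!r}")
        self.code = code


def _load_table(source: Union[str, Path, None] = None) -> dict[str, CrosswalkResult]:
    if source is None:
        text = resources.files("gabreta.data").joinpath("bfl_status_crosswalk.csv").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(source).read_text(encoding="utf-8")
    table: dict[str, CrosswalkResult] = {}
    for row in csv.DictReader(io.StringIO(text)):
        code = row["code"].strip()
        table[code] = CrosswalkResult(
            code=code,
            label=row["label"].strip(),
            pladias_origin=_ORIGIN_ALIASES[row["pladias_origin"].strip().lower()],
            poss_native=row["poss_native"].strip(),
            poss_introduced=row["poss_introduced"].strip(),
            poss_cultivated=row["poss_cultivated"].strip(),
        )
    return table


_TABLE: dict[str, CrosswalkResult] = _load_table()

#: the 13 BFL floristic "in situ" status codes
BFL_STATUS_CODES: frozenset[str] = frozenset(_TABLE)


def crosswalk_table(custom: Union[str, Path, None] = None) -> dict[str, CrosswalkResult]:
    """The full crosswalk, bundled by default or from a user-supplied CSV."""
    return dict(_TABLE) if custom is None else _load_table(custom)


def crosswalk_bfl_status(
    code: str, table: Optional[dict[str, CrosswalkResult]] = None
) -> CrosswalkResult:
    """Translate one BFL floristic status code; unknown codes raise."""
    lookup = _TABLE if table is None else table
    try:
        return lookup[code.strip()]
    except KeyError:
        raise UnknownStatusCodeError(code) from None


#: rank of each reliability status; higher documents presence better.
#: ERRONEOUS is absent: an erroneous record cannot document occurrence.
RELIABILITY_RANK: dict[Reliability, int] = {
    Reliability.NOT_YET_REVISED: 1,
    Reliability.UNCERTAIN: 2,
    Reliability.RELIABLE: 3,
}


def max_reliability(statuses: Iterable[Reliability]) -> Optional[Reliability]:
    """Highest reliability in a non-empty set, after dropping ERRONEOUS.

    Returns None when only ERRONEOUS statuses are present; raises on an
    empty input, which indicates a caller bug rather than data.
    """
    statuses = list(statuses)
    if not statuses:
        raise GabretaError("max_reliability requires a non-empty status set")
    ranked = [s for s in statuses if s in RELIABILITY_RANK]
    if not ranked:
        return None
    return max(ranked, key=RELIABILITY_RANK.__getitem__)
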