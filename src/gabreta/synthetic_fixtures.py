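"""Synthetic worlds for exercising every pipeline stage without downloads.

A generated "world" contains all six pipeline inputs in the exact file
formats the other modules consume: a taxon-name registry with synonym
chains, the two-part taxon converter (with a controllable rate of
many-to-many entries), a normalised occurrence table mixing point- and
grid-referenced records across all 13 floristic status codes, an
ABCD-style XML serialisation of the Bavarian subset, and two nested
study-area rectangles as GeoJSON.

Alongside the inputs, :func:`generate_world` computes ``expected_cells``
— the aggregated map a correct pipeline must produce — with a
deliberately plain reference implementation (nested loops over
generative truths recorded at sampling time; no use of the pipeline
modules), so end-to-end tests have an independent oracle.

The default configuration mirrors the source mix of the real corpus:
records are mostly grid-referenced, drawn from observation, specimen
and literature bases, with Bavarian records arriving pre-validated
(reliable) and Czech records spanning the four reliability statuses.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from lxml import etree

from .models import OccurrenceRecord, RecordBasis, Reliability, SourceSystem

# independent grid constants (plain floats, no ceba_grid import)
_LAT0 = 55.0 + 6.0 / 60.0  # 55°06'N
_LON0 = 5.0 + 40.0 / 60.0  # 5°40'E
_BASE_LAT = 0.1  # 6'
_BASE_LON = 1.0 / 6.0  # 10'
_QUAD_LAT = 0.05  # 3'
_QUAD_LON = 1.0 / 12.0  # 5'

_BFL_CODES = ["I", "*", "E", "D", "U", "T", "W", "K", "S", "A", "R", "?", "Z"]

Rect = tuple[float, float, float, float]  # (south, west, north, east)


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for world generation; defaults are the study conditions."""

    seed: int = 0
    n_accepted_taxa: int = 8
    synonym_rate: float = 0.4
    chain_rate: float = 0.3  # fraction of synonyms that point to another synonym
    many_to_many_rate: float = 0.15
    n_records: int = 200
    fraction_point_vs_grid: float = 0.4  # the majority of source records are grid-based
    unmapped_rate: float = 0.04  # records whose taxon the converter does not (yet) cover
    undated_rate: float = 0.1
    year_range: tuple[int, int] = (1950, 2021)
    bfl_fraction: float = 0.6
    region_weights: tuple[float, float, float] = (0.6, 0.25, 0.15)  # inner/ring/outside
    reliability_distribution: tuple[tuple[Reliability, float], ...] = (
        (Reliability.RELIABLE, 0.5),
        (Reliability.UNCERTAIN, 0.2),
        (Reliability.NOT_YET_REVISED, 0.2),
        (Reliability.ERRONEOUS, 0.1),
    )
    status_code_weights: Optional[tuple[float, ...]] = None  # uniform over the 13 codes
    inner_rect: Rect = (48.852, 13.262, 49.148, 13.738)
    outer_rect: Rect = (48.762, 13.122, 49.238, 13.878)
    concave_inner: bool = False  # notch the inner polygon to stress point-in-polygon

    def validate(self) -> None:
        if self.n_records > 0 and self.n_accepted_taxa <= 0:
            raise ValueError("cannot generate records for a world with zero taxa")
        for name in ("synonym_rate", "chain_rate", "many_to_many_rate",
                     "fraction_point_vs_grid", "unmapped_rate", "undated_rate",
                     "bfl_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        si, wi, ni, ei = self.inner_rect
        so, wo, no, eo = self.outer_rect
        if not (so < si and wo < wi and no > ni and eo > ei):
            raise ValueError("inner rectangle must lie strictly inside the outer one")


@dataclass
class SyntheticWorld:
    """All generated inputs plus the independent reference outputs."""

    config: FixtureConfig
    registry_csv: str
    pladias_csv: str
    bfl_csv: str
    names_csv: str
    records_csv: str
    abcd_xml: bytes
    inner_geojson: dict
    outer_geojson: dict
    records: list[OccurrenceRecord]
    record_truths: list[dict]  # per-record generative truth (label, region, fsg ids)
    expected_cells: list[dict]
    expected_partition: tuple[int, int, int]  # (final, candidates, discards)
    expected_unmapped: int
    fsg_names: dict[str, str] = field(default_factory=dict)

    def write_to(self, directory: Path | str) -> dict[str, Path]:
        """Materialise every input file; returns the path map."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        text_files = {
            "registry.csv": self.registry_csv,
            "converter_pladias.csv": self.pladias_csv,
            "converter_bfl.csv": self.bfl_csv,
            "consensus_names.csv": self.names_csv,
            "records.csv": self.records_csv,
            "inner.geojson": json.dumps(self.inner_geojson, sort_keys=True),
            "outer.geojson": json.dumps(self.outer_geojson, sort_keys=True),
        }
        for name, text in text_files.items():
            path = directory / name
            path.write_text(text, encoding="utf-8")
            paths[name.split(".")[0]] = path
        abcd = directory / "bfl_units.xml"
        abcd.write_bytes(self.abcd_xml)
        paths["abcd"] = abcd
        return paths


# ---------------------------------------------------------------------------
# independent grid / region helpers (plain float arithmetic, generator-side)
# ---------------------------------------------------------------------------


def _quad_bounds(row: int, col: int, qpos: int) -> Rect:
    north = _LAT0 - row * _BASE_LAT - (_QUAD_LAT if qpos in (3, 4) else 0.0)
    west = _LON0 + col * _BASE_LON + (_QUAD_LON if qpos in (2, 4) else 0.0)
    return (north - _QUAD_LAT, west, north, west + _QUAD_LON)


def _label(row: int, col: int, qpos: int) -> str:
    return f"{row:02d}{col:02d}/{qpos}"


def _point_in_rect(lat: float, lon: float, rect: Rect) -> bool:
    s, w, n, e = rect
    return s <= lat <= n and w <= lon <= e


def _in_notch(lat: float, lon: float, cfg: FixtureConfig) -> bool:
    """The rectangular notch cut out of a concave inner polygon."""
    s, w, n, e = cfg.inner_rect
    return lat > s + 0.75 * (n - s) and lon < w + 0.25 * (e - w)


def _point_region(lat: float, lon: float, cfg: FixtureConfig) -> str:
    inside_inner = _point_in_rect(lat, lon, cfg.inner_rect)
    if inside_inner and cfg.concave_inner and _in_notch(lat, lon, cfg):
        inside_inner = False
    if inside_inner:
        return "INNER"
    if _point_in_rect(lat, lon, cfg.outer_rect):
        return "OUTER_ONLY"
    return "OUTSIDE"


def _rect_overlap(a: Rect, b: Rect) -> bool:
    return (
        min(a[2], b[2]) - max(a[0], b[0]) > 0
        and min(a[3], b[3]) - max(a[1], b[1]) > 0
    )


def _quad_region(bounds: Rect, cfg: FixtureConfig) -> str:
    # concave variant keeps the rectangle test for grid records: the
    # notch area is excluded for points only, never spans whole quadrants
    if _rect_overlap(bounds, cfg.inner_rect):
        if cfg.concave_inner:
            s, w, n, e = cfg.inner_rect
            notch = (s + 0.75 * (n - s), w, n, w + 0.25 * (e - w))
            rest_covers = _rect_overlap(bounds, (s, w, s + 0.75 * (n - s), e)) or _rect_overlap(
                bounds, (s, w + 0.25 * (e - w), n, e)
            )
            if not rest_covers and _rect_overlap(bounds, notch):
                return "OUTER_ONLY"
        return "INNER"
    if _rect_overlap(bounds, cfg.outer_rect):
        return "OUTER_ONLY"
    return "OUTSIDE"


def _rect_polygon_geojson(rect: Rect) -> dict:
    s, w, n, e = rect
    ring = [[w, s], [e, s], [e, n], [w, n], [w, s]]
    return {"type": "Polygon", "coordinates": [ring]}


def _concave_inner_geojson(cfg: FixtureConfig) -> dict:
    s, w, n, e = cfg.inner_rect
    ns, we = s + 0.75 * (n - s), w + 0.25 * (e - w)  # notch corner
    ring = [[w, s], [e, s], [e, n], [we, n], [we, ns], [w, ns], [w, s]]
    return {"type": "Polygon", "coordinates": [ring]}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _weighted(rng: random.Random, pairs):
    values, weights = zip(*pairs)
    return rng.choices(values, weights=weights, k=1)[0]


def generate_world(config: FixtureConfig = FixtureConfig()) -> SyntheticWorld:
    """Build a fully reproducible synthetic world from the seed."""
    config.validate()
    rng = random.Random(config.seed)

    # --- taxonomy: consensus taxa, BFL names (+synonym chains), Pladias ids
    fsg_ids = [str(10 + i) for i in range(config.n_accepted_taxa)]
    fsg_names = {fsg: f"Synthetica species{i} agg." for i, fsg in enumerate(fsg_ids)}
    registry_rows = [("pid", "full_name", "category", "accepted_pid")]
    accepted_of: dict[str, str] = {}  # generative truth: any BFL pid -> accepted pid
    bfl_pids_per_taxon: list[list[str]] = []
    bfl_map: dict[str, set[str]] = {}
    pladias_map: dict[str, set[str]] = {}
    pladias_ids: list[str] = []
    next_syn = 2000
    for i, fsg in enumerate(fsg_ids):
        acc = str(1000 + i)
        name = f"Synthetica species{i} L."
        registry_rows.append((acc, name, "ACCEPTED", ""))
        accepted_of[acc] = acc
        pids = [acc]
        if rng.random() < config.synonym_rate:
            syn = str(next_syn)
            next_syn += 1
            category = rng.choice(["SYNONYM", "BASIONYM"])
            registry_rows.append((syn, f"Vetusta species{i} auct.", category, acc))
            accepted_of[syn] = acc
            pids.append(syn)
            if rng.random() < config.chain_rate:
                syn2 = str(next_syn)
                next_syn += 1
                registry_rows.append((syn2, f"Antiqua species{i} hort.", "SYNONYM", syn))
                accepted_of[syn2] = acc
                pids.append(syn2)
        bfl_pids_per_taxon.append(pids)
        bfl_map[acc] = {fsg}
        if config.n_accepted_taxa > 1 and rng.random() < config.many_to_many_rate:
            bfl_map[acc].add(fsg_ids[(i + 1) % config.n_accepted_taxa])
        pl = str(5000 + i)
        pladias_ids.append(pl)
        pladias_map[pl] = {fsg}

    # --- study-area quadrants classified by region (generator-side truth)
    window = (
        config.outer_rect[0] - 2 * _QUAD_LAT,
        config.outer_rect[1] - 2 * _QUAD_LON,
        config.outer_rect[2] + 2 * _QUAD_LAT,
        config.outer_rect[3] + 2 * _QUAD_LON,
    )
    quads_by_region: dict[str, list[tuple[int, int, int, Rect]]] = {
        "INNER": [], "OUTER_ONLY": [], "OUTSIDE": []
    }
    row_min = int((_LAT0 - window[2]) / _BASE_LAT) - 1
    row_max = int((_LAT0 - window[0]) / _BASE_LAT) + 1
    col_min = int((window[1] - _LON0) / _BASE_LON) - 1
    col_max = int((window[3] - _LON0) / _BASE_LON) + 1
    for row in range(max(row_min, 0), row_max + 1):
        for col in range(max(col_min, 0), col_max + 1):
            for qpos in (1, 2, 3, 4):
                bounds = _quad_bounds(row, col, qpos)
                if not _rect_overlap(bounds, window):
                    continue
                quads_by_region[_quad_region(bounds, config)].append((row, col, qpos, bounds))

    # --- occurrence records with per-record generative truth
    records: list[OccurrenceRecord] = []
    truths: list[dict] = []
    region_pairs = list(zip(("INNER", "OUTER_ONLY", "OUTSIDE"), config.region_weights))
    y0, y1 = config.year_range
    status_weights = config.status_code_weights or tuple([1.0] * len(_BFL_CODES))
    for j in range(config.n_records):
        is_bfl = rng.random() < config.bfl_fraction
        taxon_idx = rng.randrange(config.n_accepted_taxa)
        unmapped = rng.random() < config.unmapped_rate
        if is_bfl:
            pid = "9" * 5 + str(j) if unmapped else rng.choice(bfl_pids_per_taxon[taxon_idx])
            name = f"Synthetica species{taxon_idx} L."
            reliability = Reliability.RELIABLE  # published BFL archives are validated
            status = _weighted(rng, list(zip(_BFL_CODES, status_weights)))
            source = SourceSystem.BFL
        else:
            pid = str(8000 + j) if unmapped else pladias_ids[taxon_idx]
            name = f"Synthetica species{taxon_idx} agg."
            reliability = _weighted(rng, config.reliability_distribution)
            status = None
            source = SourceSystem.PLADIAS
        if unmapped:
            fsg: set[str] = set()
        elif is_bfl:
            fsg = bfl_map[accepted_of[pid]]
        else:
            fsg = pladias_map[pid]

        # location: pick a region, then a quadrant of that region
        region_target = _weighted(rng, region_pairs)
        pool = quads_by_region[region_target] or quads_by_region["OUTSIDE"]
        row, col, qpos, bounds = rng.choice(pool)
        if rng.random() < config.fraction_point_vs_grid:
            s, w, n, e = bounds
            lat = s + (0.05 + 0.9 * rng.random()) * (n - s)
            lon = w + (0.05 + 0.9 * rng.random()) * (e - w)
            record_kwargs = {"latitude": round(lat, 7), "longitude": round(lon, 7)}
            region = _point_region(record_kwargs["latitude"], record_kwargs["longitude"], config)
        else:
            record_kwargs = {"grid_code": _label(row, col, qpos)}
            region = _quad_region(bounds, config)
        year = None if rng.random() < config.undated_rate else rng.randint(y0, y1)
        basis = rng.choice(
            [RecordBasis.HUMAN_OBSERVATION, RecordBasis.PRESERVED_SPECIMEN,
             RecordBasis.LITERATURE]
        )
        records.append(
            OccurrenceRecord(
                record_id=f"R{j:05d}",
                source_system=source,
                scientific_name=name,
                source_taxon_pid=pid,
                event_year=year,
                record_basis=basis,
                floristic_status_code=status,
                reliability=reliability,
                licence="CC-BY",
                project_tag="FSG",
                **record_kwargs,
            )
        )
        truths.append(
            {
                "record_id": f"R{j:05d}",
                "fsg_ids": sorted(fsg),
                "region": region,
                "label": _label(row, col, qpos),
                "reliability": reliability,
                "year": year,
                "ambiguous": len(fsg) > 1,
            }
        )

    # --- independent plain-loop reference aggregation (boundary year 2000)
    rank = {"NOT_YET_REVISED": 1, "UNCERTAIN": 2, "RELIABLE": 3}
    groups: dict[tuple[str, str], list[dict]] = {}
    n_final = n_cand = n_disc = 0
    n_unmapped = 0
    for truth in truths:
        if not truth["fsg_ids"]:
            n_unmapped += 1
            continue
        if truth["region"] == "INNER":
            n_final += 1
        elif truth["region"] == "OUTER_ONLY":
            n_cand += 1
            continue
        else:
            n_disc += 1
            continue
        for fsg in truth["fsg_ids"]:
            groups.setdefault((fsg, truth["label"]), []).append(truth)
    expected_cells: list[dict] = []
    for (fsg, label), members in groups.items():
        best = None
        for m in members:
            r = m["reliability"].value
            if r in rank and (best is None or rank[r] > rank[best]):
                best = r
        if best is None:
            continue  # erroneous-only evidence never documents presence
        n_recent = sum(1 for m in members if m["year"] is not None and m["year"] >= 2000)
        n_hist = sum(1 for m in members if m["year"] is not None and m["year"] < 2000)
        undated = sum(1 for m in members if m["year"] is None)
        expected_cells.append(
            {
                "fsg_id": fsg,
                "label": label,
                "best_reliability": best,
                "n_records": len(members),
                "n_recent": n_recent,
                "n_historical": n_hist,
                "undated_count": undated,
                "ambiguous_only": all(m["ambiguous"] for m in members),
            }
        )
    expected_cells.sort(key=lambda c: (c["fsg_id"], c["label"]))

    # --- serialisations
    registry_csv = _csv_text(registry_rows)
    pladias_csv = _csv_text(
        [("pladias_id", "fsg_id")]
        + sorted((pl, fsg) for pl, fsgs in pladias_map.items() for fsg in fsgs)
    )
    bfl_csv = _csv_text(
        [("bfl_pid", "fsg_id")]
        + sorted((pid, fsg) for pid, fsgs in bfl_map.items() for fsg in fsgs)
    )
    names_csv = _csv_text([("fsg_id", "name")] + [(f, fsg_names[f]) for f in fsg_ids])
    from .records_io import write_occurrence_table

    records_csv = write_occurrence_table(records)
    abcd_xml = generate_abcd_xml(
        [r for r in records if r.source_system is SourceSystem.BFL]
    )
    inner_geojson = (
        _concave_inner_geojson(config) if config.concave_inner
        else _rect_polygon_geojson(config.inner_rect)
    )
    return SyntheticWorld(
        config=config,
        registry_csv=registry_csv,
        pladias_csv=pladias_csv,
        bfl_csv=bfl_csv,
        names_csv=names_csv,
        records_csv=records_csv,
        abcd_xml=abcd_xml,
        inner_geojson=inner_geojson,
        outer_geojson=_rect_polygon_geojson(config.outer_rect),
        records=records,
        record_truths=truths,
        expected_cells=expected_cells,
        expected_partition=(n_final, n_cand, n_disc),
        expected_unmapped=n_unmapped,
        fsg_names=fsg_names,
    )


def _csv_text(rows) -> str:
    import csv as _csv

    buf = io.StringIO()
    writer = _csv.writer(buf, lineterminator="\n")
    writer.writerows(rows)
    return buf.getvalue()


_BASIS_XML = {
    RecordBasis.PRESERVED_SPECIMEN: "PreservedSpecimen",
    RecordBasis.HUMAN_OBSERVATION: "HumanObservation",
    RecordBasis.LITERATURE: "Literature",
    RecordBasis.UNKNOWN: "Unknown",
}


def generate_abcd_xml(records: list[OccurrenceRecord]) -> bytes:
    """Serialise records as an ABCD-style unit list (reduced element set)."""
    root = etree.Element("DataSets")
    dataset = etree.SubElement(root, "DataSet")
    units = etree.SubElement(dataset, "Units")
    for rec in records:
        unit = etree.SubElement(units, "Unit")
        etree.SubElement(unit, "UnitID").text = rec.record_id
        etree.SubElement(unit, "RecordBasis").text = _BASIS_XML[rec.record_basis]
        ident = etree.SubElement(unit, "Identification")
        result = etree.SubElement(ident, "Result")
        taxon = etree.SubElement(result, "TaxonIdentified")
        sci = etree.SubElement(taxon, "ScientificName")
        etree.SubElement(sci, "FullScientificNameString").text = rec.scientific_name
        if rec.source_taxon_pid:
            refs = etree.SubElement(ident, "References")
            ref = etree.SubElement(refs, "Reference")
            etree.SubElement(ref, "TitleCitation").text = "Taxonomic reference list"
            etree.SubElement(ref, "URI").text = (
                f"https://names.example.org/rest/names/plants/{rec.source_taxon_pid}"
            )
        gathering = etree.SubElement(unit, "Gathering")
        if rec.event_year is not None:
            dt = etree.SubElement(gathering, "DateTime")
            etree.SubElement(dt, "ISODateTimeBegin").text = str(rec.event_year)
        if rec.has_point:
            sets = etree.SubElement(gathering, "SiteCoordinateSets")
            coords = etree.SubElement(sets, "SiteCoordinates")
            latlon = etree.SubElement(coords, "CoordinatesLatLong")
            etree.SubElement(latlon, "LatitudeDecimal").text = repr(rec.latitude)
            etree.SubElement(latlon, "LongitudeDecimal").text = repr(rec.longitude)
        if rec.grid_code:
            areas = etree.SubElement(gathering, "NamedAreas")
            area = etree.SubElement(areas, "NamedArea")
            etree.SubElement(area, "AreaName").text = rec.grid_code
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def abcd_comparable(record: OccurrenceRecord) -> tuple:
    """The fields round-tripped through the reduced ABCD element set."""
    return (
        record.record_id,
        record.scientific_name,
        record.source_taxon_pid,
        record.latitude,
        record.longitude,
        record.grid_code,
        record.event_year,
        record.record_basis,
    )
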