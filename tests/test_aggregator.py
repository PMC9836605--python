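"""Quadrant aggregation, manual overrides and map export."""

import random

import pytest

from gabreta.aggregator import (
    aggregate,
    apply_overrides,
    cells_from_csv,
    cells_to_csv,
    export_map,
    load_overrides,
    OverrideEntry,
)
from gabreta.ceba_grid import parse_label
from gabreta.models import (
    MappedOccurrence,
    OccurrenceRecord,
    Reliability,
    SourceSystem,
)


def _mapped(fsg_ids, grid_code="6945/1", year=2010, reliability=Reliability.RELIABLE,
            record_id="r"):
    record = OccurrenceRecord(
        record_id=record_id, source_system=SourceSystem.BFL,
        scientific_name="Synthetica spec.", grid_code=grid_code,
        event_year=year, reliability=reliability,
    )
    return MappedOccurrence(record=record, accepted_source_pid="1000",
                            fsg_ids=frozenset(fsg_ids))


class TestAggregate:
    def test_best_reliability_with_erroneous_counted(self):
        mapped = [
            _mapped({"10"}, reliability=Reliability.UNCERTAIN, record_id="a"),
            _mapped({"10"}, reliability=Reliability.RELIABLE, record_id="b"),
            _mapped({"10"}, reliability=Reliability.ERRONEOUS, record_id="c"),
        ]
        cells, rejects = aggregate(mapped)
        assert not rejects and len(cells) == 1
        cell = cells[0]
        assert cell.best_reliability is Reliability.RELIABLE
        assert cell.n_records == 3

    def test_erroneous_only_cell_suppressed(self):
        cells, _ = aggregate([_mapped({"10"}, reliability=Reliability.ERRONEOUS)])
        assert cells == []

    def test_temporal_split_flags(self):
        mapped = [_mapped({"10"}, year=1987, record_id="a"),
                  _mapped({"10"}, year=2005, record_id="b")]
        (cell,), _ = aggregate(mapped)
        assert cell.recent and cell.historical
        assert cell.n_recent == 1 and cell.n_historical == 1

    def test_year_2000_counts_as_recent_by_default(self):
        (cell,), _ = aggregate([_mapped({"10"}, year=2000)])
        assert cell.recent and not cell.historical

    def test_boundary_year_configurable(self):
        (cell,), _ = aggregate([_mapped({"10"}, year=2000)], boundary_year=2001)
        assert cell.historical and not cell.recent

    def test_undated_records_count_but_set_no_flag(self):
        (cell,), _ = aggregate([_mapped({"10"}, year=None)])
        assert not cell.recent and not cell.historical
        assert cell.undated_count == 1 and cell.n_records == 1

    def test_tallies_sum_to_n_records(self):
        mapped = [_mapped({"10"}, year=y, record_id=str(i))
                  for i, y in enumerate([1990, None, 2001, 2015, None])]
        (cell,), _ = aggregate(mapped)
        assert cell.n_recent + cell.n_historical + cell.undated_count == cell.n_records == 5

    def test_ambiguous_contributes_to_every_taxon_by_default(self):
        cells, _ = aggregate([_mapped({"10", "11"})])
        assert {c.fsg_id for c in cells} == {"10", "11"}
        assert all(c.ambiguous_only for c in cells)

    def test_exclude_policy_drops_ambiguous(self):
        cells, _ = aggregate([_mapped({"10", "11"})], ambiguity="exclude")
        assert cells == []

    def test_unparseable_grid_code_rejects(self):
        bad = _mapped({"10"}, grid_code="bogus")
        cells, rejects = aggregate([bad])
        assert cells == [] and len(rejects) == 1

    def test_point_records_assigned_via_grid(self):
        record = OccurrenceRecord(
            record_id="p", source_system=SourceSystem.PLADIAS,
            scientific_name="S", latitude=49.0, longitude=13.5,
            reliability=Reliability.RELIABLE,
        )
        mapped = MappedOccurrence(record=record, accepted_source_pid="x",
                                  fsg_ids=frozenset({"10"}))
        (cell,), _ = aggregate([mapped])
        assert cell.label  # quadrant derived from coordinates

    def test_matches_brute_force_group_by(self):
        """200 random records equal an independent plain group-by."""
        rng = random.Random(13)
        labels = ["6945/1", "6945/2", "7046/3", "7046/4"]
        mapped = []
        for i in range(200):
            mapped.append(
                _mapped(
                    {rng.choice(["10", "11", "12"])},
                    grid_code=rng.choice(labels),
                    year=rng.choice([None, 1980, 1999, 2000, 2015]),
                    reliability=rng.choice(list(Reliability)),
                    record_id=f"r{i}",
                )
            )
        cells, rejects = aggregate(mapped)
        assert not rejects
        # independent group-by
        rank = {Reliability.NOT_YET_REVISED: 1, Reliability.UNCERTAIN: 2,
                Reliability.RELIABLE: 3}
        groups = {}
        for m in mapped:
            key = (next(iter(m.fsg_ids)), m.record.grid_code)
            groups.setdefault(key, []).append(m)
        expected = {}
        for key, members in groups.items():
            ranked = [m.record.reliability for m in members
                      if m.record.reliability in rank]
            if not ranked:
                continue
            best = max(ranked, key=rank.__getitem__)
            expected[key] = (
                best, len(members),
                sum(1 for m in members if (m.record.event_year or 0) >= 2000),
                sum(1 for m in members
                    if m.record.event_year is not None and m.record.event_year < 2000),
            )
        got = {
            (c.fsg_id, c.label): (c.best_reliability, c.n_records, c.n_recent,
                                  c.n_historical)
            for c in cells
        }
        assert got == expected

    def test_permutation_invariance(self):
        rng = random.Random(5)
        mapped = [_mapped({rng.choice(["10", "11"])},
                          grid_code=rng.choice(["6945/1", "6945/2"]),
                          year=rng.choice([1990, 2010, None]),
                          reliability=rng.choice(list(Reliability)),
                          record_id=f"r{i}") for i in range(60)]
        reference, _ = aggregate(mapped)
        for _ in range(5):
            rng.shuffle(mapped)
            shuffled, _ = aggregate(mapped)
            assert shuffled == reference

    def test_doubling_input_preserves_labels_and_flags(self):
        mapped = [_mapped({"10"}, year=1990, reliability=Reliability.UNCERTAIN),
                  _mapped({"10"}, year=2005, record_id="b")]
        once, _ = aggregate(mapped)
        twice, _ = aggregate(mapped + mapped)
        assert len(once) == len(twice) == 1
        assert twice[0].n_records == 2 * once[0].n_records
        assert twice[0].best_reliability == once[0].best_reliability
        assert (twice[0].recent, twice[0].historical) == (once[0].recent,
                                                          once[0].historical)

    def test_sum_conservation(self):
        rng = random.Random(99)
        mapped = [_mapped({"10"}, grid_code=rng.choice(["6945/1", "6945/2", "7046/3"]),
                          reliability=rng.choice(
                              [Reliability.RELIABLE, Reliability.UNCERTAIN]),
                          record_id=f"r{i}") for i in range(50)]
        cells, _ = aggregate(mapped)
        assert sum(c.n_records for c in cells) == 50


class TestOverrides:
    def test_override_on_empty_map_creates_cell(self):
        entry = OverrideEntry("10", "6945/1", Reliability.UNCERTAIN)
        cells = apply_overrides([], [entry])
        assert len(cells) == 1
        assert cells[0].overridden and cells[0].n_records == 0
        assert cells[0].best_reliability is Reliability.UNCERTAIN

    def test_override_downgrades_existing_cell(self):
        (cell,), _ = aggregate([_mapped({"10"})])
        assert cell.best_reliability is Reliability.RELIABLE
        entry = OverrideEntry("10", cell.label, Reliability.UNCERTAIN)
        (updated,) = apply_overrides([cell], [entry])
        assert updated.best_reliability is Reliability.UNCERTAIN and updated.overridden
        assert updated.n_records == cell.n_records

    def test_empty_override_table_is_identity(self):
        cells, _ = aggregate([_mapped({"10"}), _mapped({"11"}, record_id="b")])
        assert apply_overrides(cells, []) == cells

    def test_untouched_cells_pass_through(self):
        cells, _ = aggregate([_mapped({"10"}), _mapped({"11"}, record_id="b")])
        entry = OverrideEntry("10", cells[0].label, Reliability.NOT_YET_REVISED)
        updated = apply_overrides(cells, [entry])
        others = [c for c in updated if c.fsg_id == "11"]
        assert others == [c for c in cells if c.fsg_id == "11"]

    def test_malformed_label_in_override_csv_names_row(self):
        csv_text = ("fsg_id,quadrant,reliability,note,author,date\n"
                    "10,NOT-A-LABEL,RELIABLE,,,\n")
        with pytest.raises(ValueError, match="row 1"):
            load_overrides(csv_text)

    def test_override_csv_round(self):
        csv_text = ("fsg_id,quadrant,reliability,note,author,date\n"
                    "10,6945/1,uncertain,checked in field,ab,2023-05-01\n")
        (entry,) = load_overrides(csv_text)
        assert entry.reliability is Reliability.UNCERTAIN
        assert entry.quadrant() == parse_label("6945/1")


class TestExport:
    def _cells(self):
        mapped = [
            _mapped({"10"}, year=1987, record_id="a"),  # historical-only
            _mapped({"11"}, year=2010, grid_code="7046/2", record_id="b"),
        ]
        cells, _ = aggregate(mapped)
        return cells

    def test_features_match_cells(self):
        collection, csv_text = export_map(self._cells(), fsg_names={"10": "Ten"})
        assert len(collection["features"]) == 2
        assert len(csv_text.strip().splitlines()) - 1 == 2
        f0 = collection["features"][0]
        assert f0["properties"]["fsg_id"] == "10"
        assert f0["properties"]["name"] == "Ten"
        ring = f0["geometry"]["coordinates"][0]
        assert len(ring) == 5 and ring[0] == ring[-1]

    def test_recent_filter_drops_historical_only(self):
        collection, _ = export_map(self._cells(), period_filter="recent")
        assert [f["properties"]["fsg_id"] for f in collection["features"]] == ["11"]

    def test_historical_filter(self):
        collection, _ = export_map(self._cells(), period_filter="historical")
        assert [f["properties"]["fsg_id"] for f in collection["features"]] == ["10"]

    def test_taxon_filter(self):
        collection, _ = export_map(self._cells(), taxon_filter={"11"})
        assert [f["properties"]["fsg_id"] for f in collection["features"]] == ["11"]

    def test_deterministic_order(self):
        cells = self._cells()
        a, _ = export_map(cells)
        b, _ = export_map(list(reversed(cells)))
        assert a == b

    def test_cells_csv_round_trip(self):
        cells = self._cells()
        assert cells_from_csv(cells_to_csv(cells)) == cells
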