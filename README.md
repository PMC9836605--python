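# gabreta

Cross-border integration of plant occurrence data into grid-quadrant
distribution maps.

## The problem

Floristic atlases for regions spanning a national border have to merge
occurrence records from source systems that disagree on almost
everything: exchange formats (ABCD XML archives vs. spreadsheet
exports), taxon reference lists (different checklists circumscribe
"the same" species differently), floristic-status vocabularies, and
georeferencing (GPS points vs. atlas grid codes). `gabreta` implements
the data-integration machinery such a project needs, modelled on the
infrastructure used for the flora of the Bohemian Forest
(Šumava/Bavarian Forest), where Czech (Pladias) and Bavarian (BFL /
Diversity Workbench) sources are joined:

1. **Ingest** — parse ABCD 2.1-style XML unit lists (optionally
   zipped) and delimited tables into normalised occurrence records;
   invalid rows become rejects with reasons, never silent drops.
2. **Harmonize** — resolve each Bavarian taxon-name PID through a
   synonym-aware registry to its accepted name, then map both national
   identifiers onto an agreed **consensus taxonomy** through a
   curated, deliberately **many-to-many two-part converter**
   (Pladias-ID → consensus-ID and BFL-TaxRef-PID → consensus-ID);
   translate the 13-category Bavarian floristic status vocabulary to
   Czech origin categories and the three TDWG POSS axes.
3. **Filter** — intersect records against two nested study-area
   polygons: the inner polygon yields final data, the surrounding
   strip a candidate pool, the rest is discarded.
4. **Aggregate** — generalise to the CEBA/TK25 grid (base cells of
   10′ × 6′, quadrants of 5′ × 3′ ≈ 5.5 × 6 km), labelling each
   (taxon, quadrant) cell with the **highest reached reliability
   status** (reliable > uncertain > not yet revised; erroneous records
   never document presence) and a pre/post-2000 temporal split, then
   export GeoJSON + CSV map products. Curators can force cell statuses
   through a manual override table.

A synthetic-world generator (`gabreta.synthetic_fixtures`) produces
all six pipeline inputs with controllable synonym-chain, many-to-many
and location-mix rates, together with an independently computed
reference output, so the whole pipeline is testable without any
external service.

## Worked example

Generate a reproducible synthetic world and run the full pipeline:

```
gabreta simulate --seed 7 --n-records 120 --out-dir demo/in
gabreta run \
  --records demo/in/records.csv --registry demo/in/registry.csv \
  --converter-pladias demo/in/converter_pladias.csv \
  --converter-bfl demo/in/converter_bfl.csv \
  --consensus-names demo/in/consensus_names.csv \
  --inner demo/in/inner.geojson --outer demo/in/outer.geojson \
  --out-dir demo/out
```

prints the machine-readable run report:

```json
{
  "ingest":    {"accepted": 120, "rejected": 0},
  "harmonize": {"mapped": 115, "rejected": 5, "ambiguous": 43},
  "filter":    {"final": 70, "candidates": 28, "discards": 17},
  "aggregate": {"cells": 78, "grid_rejects": 0, "overrides_applied": 0}
}
```

Reading: all 120 generated records ingest cleanly; 5 carry taxon IDs
the converter does not (yet) cover and land in the curator reject
stream; of the 115 mapped records, 70 fall inside the study area, 28
in the surrounding candidate strip and 17 outside; the final records
aggregate to 78 map cells. `demo/out/map.csv` holds one row per cell:

```
fsg_id,name,label,best_reliability,recent,historical,n_recent,n_historical,undated_count,n_records,ambiguous_only,overridden
10,Synthetica species0 agg.,5945/4,RELIABLE,True,False,1,0,0,1,True,False
```

— consensus taxon 10 is confirmed after 2000 with reliable evidence in
quadrant `5945/4` (grid row 59, column 45, quadrant 4 = SE).
`demo/out/map.geojson` carries the same cells as WGS84 quadrant
rectangles for web mapping.

Every stage is also callable as a library function; the bundled
worked example of the consensus mapping (the *Aconitum plicatum*
case, in which two Czech taxa and four Bavarian names all resolve to
one consensus taxon) is available via `gabreta.bundled`:

```python
>>> from gabreta.bundled import load_example_converter
>>> from gabreta.taxon_converter import map_source_taxon
>>> from gabreta.models import SourceSystem
>>> map_source_taxon(SourceSystem.PLADIAS, "1444", load_example_converter())
{'14'}
```

## Layout

| module | role |
| --- | --- |
| `gabreta.records_io` | ABCD XML + delimited-table reading/writing |
| `gabreta.taxon_registry` | PID/name → accepted-name resolution |
| `gabreta.taxon_converter` | two-part many-to-many consensus mapping |
| `gabreta.status_crosswalk` | floristic-status vocabulary translation, reliability order |
| `gabreta.ceba_grid` | CEBA/TK25 quadrant arithmetic, labels, polygons |
| `gabreta.spatial_filter` | nested-polygon classification and partitioning |
| `gabreta.aggregator` | quadrant × taxon map cells, overrides, export |
| `gabreta.synthetic_fixtures` | reproducible synthetic worlds + reference output |
| `gabreta.pipeline`, `gabreta.cli` | stage orchestration and the `gabreta` command |
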