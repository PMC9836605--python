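# Methods

This note documents the models, conventions and numerical choices
behind `gabreta`, and what the synthetic test worlds do and do not
demonstrate about real data.

## Record model and validation

An `OccurrenceRecord` is valid when it carries a record ID, a reported
scientific name, and at least one location form: a WGS84 point
(latitude in [−90, 90], longitude in [−180, 180]) or a grid-quadrant
label. Event dates are reduced to the year at ingest, because every
downstream consumer (the temporal split of the maps) needs only the
year; ISO dates and bare years are both accepted. Basis-of-record
strings are matched case-insensitively against the three categories in
use (`PreservedSpecimen`, `HumanObservation`, `Literature`); anything
else is `UNKNOWN`. Input is UTF-8, the delimiter configurable
(default comma). Violations are returned as rejects carrying the unit
index or data row number and a reason — parsing a batch never throws
on bad rows, only on structural problems (malformed XML, a missing
mandatory column).

ABCD parsing reads a reduced, documented element set relative to each
`Unit` (`AbcdPathConfig`): unit ID, record basis, full scientific name
string, the `Identification/References/Reference` block
(GUID/title/citation/URI), gathering date, decimal coordinates, and a
named-area element used for grid codes. The persistent taxon-name PID
is extracted as the trailing numeric path segment of the Reference URI
(falling back to the GUID). The grid-code path is a deliberate,
overridable choice: the exchange standard does not prescribe where
atlas grid references live, and source installations differ. Records
arriving through the published validated archives default to
reliability `RELIABLE`, since only validated records are published
that way; the default can be disabled.

## Name resolution

The taxon registry mirrors the two lookup semantics of a
taxon-name REST service as pure functions over a loaded table:
resolve (PID or verbatim name, whitespace-normalised) → accepted PID,
and PID → scientific name. Load-time validation enforces unique PIDs,
pointer presence on non-accepted names, and acyclicity, so resolution
terminates in at most |registry| steps and is idempotent. Homonyms
(one name, several PIDs) raise an explicit ambiguity error listing the
candidates rather than silently picking one, because a silent pick
would corrupt every mapping downstream. Fuzzy name matching is out of
scope. An HTTP facade over the two lookups was considered and dropped:
the pure functions carry the full tested semantics.

## Consensus mapping

The two converter parts (source-ID → consensus-ID pairs) are loaded as
plain pair sets; cardinality is many-to-many by design and is not
"fixed" — differing taxon concepts between checklists cannot be
reconciled one-to-one, and the converter is the curated product of
expert discussion, not something derivable from name similarity.
Consequences implemented here:

- a record mapping to several consensus taxa is **ambiguous**; by
  default it contributes presence to every mapped taxon and cells fed
  only by such records are flagged `ambiguous_only`, so curators can
  see map content that hinges on unresolved concepts. A policy switch
  (`--ambiguity exclude`) drops ambiguous records instead.
- a record whose accepted ID is absent from the converter is a
  **reject**, not an error: the converter is updated on a slower cycle
  than the source databases, and pipelines must survive the gap.
- Bavarian identifiers pass through accepted-name resolution first
  (synonym invariance: a synonym maps exactly as its accepted name);
  Czech identifiers are database-level IDs outside that registry and
  are looked up directly.
- records identified to an aggregate map to exactly what the converter
  states for that aggregate; no propagation to contained taxa.

## Status vocabularies and the reliability order

The bundled crosswalk table translates the 13 Bavarian floristic
"in situ" status codes (I, \*, E, D, U, T, W, K, S, A, R, ?, Z) to the
Czech origin vocabulary (native / non-native / planted / not set) and
the three POSS axes; six codes have no origin equivalent and map to an
explicit `WITHOUT_EQUIVALENT` marker, kept distinct from "not set".
The table ships as package data, column-for-column overridable by a
user file.

The reliability vocabulary has four values; labelling a cell by the
"highest reached" status requires a total order, which is fixed as
RELIABLE > UNCERTAIN > NOT_YET_REVISED, with ERRONEOUS excluded from
presence entirely — a record judged erroneous cannot document
occurrence, but it is still counted in the cell's record tally when
other evidence sustains the cell.

## Grid arithmetic

The mapping grid uses base cells of 10′ longitude × 6′ latitude split
into four 5′ × 3′ quadrants (numbered 1=NW, 2=NE, 3=SW, 4=SE), rows
counted southwards and columns eastwards from a northwest origin fixed
by default at 55°06′ N, 5°40′ E (the German TK25 sheet convention;
the origin is a `GridSpec` parameter so other national offsets are
configurable). Labels are `RRCC/Q`, zero-padded. All arithmetic is
carried out in exact rational arc-minutes (`fractions.Fraction`):
cell assignment is a floor division, intervals are half-open and
closed on the north and west edges, so a point on a shared meridian
deterministically belongs to the eastern neighbour and boundary
results cannot flap with floating-point rounding. At 49° N a quadrant
measures ≈ 5.5 km north–south × ≈ 6.1 km east–west on a spherical
Earth of radius 6371 km.

## Spatial filtering

Both study-area polygons are taken as GeoJSON in geographic
coordinates and evaluated in plate carrée without reprojection: at
study-area scale (tens of kilometres) containment is unaffected and
the computation stays exactly reproducible. Points use even-odd
containment with **inclusive boundaries** (conservative, matching the
candidate-pool purpose of the outer polygon); quadrants are classified
by **any positive-area overlap** rather than centroid, since map
products display whole quadrants clipped by the study area. Nesting
(inner ⊆ outer) is asserted at load by testing every inner vertex
against the outer polygon. The altitude criterion that shaped the real
polygons is embodied in the polygon geometry, not computed.

## Aggregation, temporal split, overrides

Cells are keyed by (consensus taxon, quadrant). The temporal boundary
is `year >= 2000` for "recent" (the boundary year is configurable;
2000 itself counts as recent). Undated records contribute to presence
and to the reliability label but to neither temporal flag. A cell
exists only where at least one non-erroneous record falls; erroneous
records in a surviving cell are included in `n_records`. Aggregation
is permutation-invariant and conserves counts (each ambiguous
contribution counts once per mapped taxon under the default policy).

Manual overrides are applied last and survive re-aggregation: an
override replaces an existing cell's reliability label or creates a
data-free cell (`n_records = 0`, `overridden = True`), supporting
curator knowledge that is not (yet) backed by records in the batch.

## Synthetic worlds

`generate_world` emulates the integration setting end to end: a
consensus taxonomy with Bavarian accepted names, synonym/basionym
chains (including two-step chains), Czech database IDs, a two-part
converter with a controllable many-to-many rate, and occurrence
records mixing point and grid georeferencing (grid-based records in
the majority, matching the source mix), the three record bases, all 13
status codes (uniform by default), years across 1950–2021 with ~10%
undated, and a small rate of records whose taxon the converter does
not cover. Bavarian records are generated pre-validated (reliable);
Czech records span the four reliability statuses (50/20/20/10%
reliable/uncertain/not-yet-revised/erroneous). Default sample sizes
(8 consensus taxa, 200 records) keep whole-pipeline oracle comparisons
fast while still populating every code path; the study-area rectangles
sit over the Bohemian Forest with edges deliberately chosen off grid
lines so overlap classifications are unambiguous.

The expected pipeline output is computed by an independent plain-loop
reference over generative truths recorded at sampling time (the
generator *chooses* each record's quadrant and region, so the
reference needs no grid or geometry code from the package). Tests
compare the full pipeline against this reference across many seeds.

What passing these tests shows: the transformation chain — parsing,
resolution, conversion, filtering, aggregation — is exact with respect
to its specification on data with the structural features above. What
it does not show: robustness to the messiness of real archives
(inconsistent name spellings, truncated coordinates, heterogeneous
date formats beyond ISO/year, encoding damage), realistic
species-abundance structure, or the quality of any real converter
table. The generator makes no attempt at statistically realistic
abundance distributions.

## Numerical and degenerate-input choices

- Grid arithmetic: exact rationals; floats are converted via their
  exact binary value, so repeated classification of the same input is
  stable.
- Tie-breaks: boundary points → north/west-closed cells; polygon
  boundaries → inside; equal reliability → the single maximum under
  the fixed total order (no ties possible).
- Degenerate inputs: empty datasets/tables yield empty outputs with
  zero exit; an empty status set passed to the reliability maximum is
  a contract violation and raises; a world with records but zero taxa
  is rejected at configuration time.
- Export order is deterministic (consensus ID, then quadrant label),
  making stage outputs byte-comparable.
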