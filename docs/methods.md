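# Methods

This note documents the mapping model, the numerical and design choices
behind it, what the synthetic generator does and does not emulate, and the
known limitations.

## Mapping model

The source is a normalized relational transplant EHR; the target is the
i2b2 1.7 star schema (observation_fact, patient/visit/concept/
provider/modifier dimensions, and the `i2b2` metadata table). The mapping
rests on three decisions:

1. **The transplantation is the encounter.** The source's clinical case
   numbers (billing encounters) are not joinable to most tables; the
   transplantation table is. Its identifier becomes `encounter_num` for
   every fact that can reach it by a foreign-key chain of any length
   (breadth-first search over the FK graph, shortest path, lexicographic
   tie-break on (local column, target table); cycles are handled with a
   visited set). The two-hop case is just an instance of this rule. The
   anchor table itself carries its own id (the identity path of length 0).

2. **Timeframes for everything else.** Tables with a patient reference but
   no path to the anchor are attached by date. "Two weeks" is exactly 14
   calendar days; window boundaries are inclusive on both closed ends. A
   non-failed graft's window is open-ended but cut (exclusively) at the
   next transplant's window start; a failed graft's window ends at
   failure + 14 days *regardless* of later transplants, so a failure tail
   can overlap the next window's lead. The tie-break — latest window start
   wins — reflects that a fact ten days before transplant B is pre-B
   documentation; every tie-broken assignment is labelled
   `OVERLAP_TIEBREAK` in the audit log. Facts outside every window get one
   surrogate encounter per (patient, inter-window gap): this groups
   temporally coherent unattached facts into one pseudo-visit, the closest
   analog of an encounter. Surrogate ids are strictly negative (trivially
   disjoint from source transplant ids, visible in the star) and are a pure
   function of the patient's rank and gap index fixed at registry
   construction, so assignment is invariant under fact processing order.
   A failure date preceding its transplant date is a data error and is
   rejected, as are two same-day transplants of one patient (their windows
   could not be ordered).

3. **One fact per non-null value cell.** Wide rows rotate into one pre-EAV
   line per non-null VALUE/FREE_TEXT cell (at most x − y lines for x
   columns with y metadata columns); EAV-ready tables pass through 1:1
   with no rotation stage at all. Null cells emit no fact — an EAV store
   records present observations — and the "value is not set" query
   category is therefore implemented as concept absence. These two
   decisions are a pair: either both hold or neither. They also make the
   count-conservation check exact: per source table,
   |facts| = |non-null value cells|, with join losses (dangling FKs)
   counted and reported, never silent.

## Value encoding and concept codes

Numeric values (not blobs, not categorical codes): valtype `N`,
`nval_num` set, `tval_char = "E"` (equals), unit carried in `units_cd`.
Free-text blobs: valtype `B`, text in `observation_blob`. Everything else:
valtype `T` in `tval_char`. A column declared numeric whose value does not
parse raises an encoding error rather than being coerced. Unit conversion
is deliberately out of scope: units are stored, not normalized.

Concept codes are `PREFIX:table:column` for continuous/free-text columns,
`PREFIX:table:column:value` for categorical (coded) columns, and
`PREFIX:table:conceptvalue` for EAV-ready tables whose concept comes from a
data column. The scheme is deterministic and collision-free by
construction; the ontology paths mirror it
(`\PREFIX\table\column\value\`), folders for tables/columns, one leaf per
concept code, `c_hlevel` = path segments − 1. Whether a column is
categorical is declared in the role map (the generator's schema declares
its coded columns); this keeps classification independent of data
profiling.

Instance numbers: in `GROUPED` mode (default) all facts sharing
(patient, encounter, source event) share one instance number, events
numbered 1.. per patient+encounter ascending by (event date, event key).
The pipeline stamps them with a SQL `DENSE_RANK()` window over the staged
fact table — grouping legitimately spans source tables — and the in-memory
`assign_instance_nums` implements the same rule; a test pins the two
routes to each other. `IDRT_COMPAT` mode reproduces the legacy loader's
global running counter, which makes "collected at one event" queries
unanswerable; it exists so that limitation is demonstrable.

## Star loading

Only observation_fact, patient_dimension and the metadata table are written
from transformed data. visit_dimension (distinct encounters with min/max
fact date), concept_dimension (ontology leaves) and the default provider/
modifier rows are derived by SQL from what is already loaded — deriving
secondary tables is cheaper than exporting them and cannot drift from the
facts. All reads and writes are chunked (default 50,000 rows) so the
resident buffer is bounded; the whole pipeline never holds a table in
memory. Each run is stamped with an `upload_id`; re-running the same
config deletes that run's rows first, making the loader re-entrant. After
loading, three invariants are enforced: fact-key uniqueness
(encounter, patient, concept, provider, date, modifier, instance), patient
referential closure, and concept closure against the dimension.

## Query engine

Criterion concepts match by family (a code matches itself and any
`:`-suffixed extension), so a coded column can be queried as a whole or by
value. Numeric/date checks can carry an anchor event with a day-gap window
(`gap_days`, optionally `gap_days_max`): that is the "A at least x days
after B" constraint attached to a value check; with `MOST_RECENT`
aggregation the check applies only to the fact(s) on the latest qualifying
date (ties on that date pass if any value passes — dates have day
resolution, so ties are possible). Temporal sequences are strict
(same-day events do not qualify as "after"), optionally bounded above by a
second event. Wildcards are SQL-LIKE `%`/`_`, case-insensitive, over
`tval_char` and `observation_blob`. "Still alive" is modeled as absence of
a death-indicator concept, and the ESA-exclusion window of bundled study 4
is read as "no ESA medication started within 0–183 days after a
transplantation" (the alternative reading — a six-month treatment-free
period anywhere — is noted, not implemented). Panels AND/OR their
criteria; panels are conjoined; exclusion panels subtract.

The four bundled studies exercise the eight categories as
{1, 2, 7a}, {2, 4, 7a}, {3, 5, 6, 7a} and {2, 3, 4, 5, 7b}. Their
thresholds and dates live in one parameter table shared with the
independent SQL oracle (`oracle.py`), which answers the same questions
directly on the relational source with no shared evaluation code — answer
equality between the two routes is the package's definition of an
answer-preserving mapping, and is asserted exactly in the acceptance
suite.

## Synthetic generator

The generator emulates the *shape* of a transplant registry, not clinical
truth: patients and donors joined by a central transplantation table
(~1.08 transplants per patient, ~25% graft failure), longitudinal lab
panels with units (Poisson test counts, 3–6 analytes per test, lognormal/
normal values), transplant-linked diagnoses/medications/free-text findings,
and patient-only examinations, some deliberately placed before the first
transplant window so surrogate logic is always exercised. Dates are
ISO-8601 days (the mapping reasons in days); the same seed yields
identical content. The default configuration (200 patients, ≈50k value
cells) is the package's standard test bed; `scale_profile(f)` instead
derives per-patient rates from a large production registry's published
totals (3,493 patients; 3,767 transplants; 54,009 diagnoses; 182,250
medications; 8.65M lab values over 18 years), so `f = 0.01` gives ≈35
patients with ≈86k lab values — the largest size the test suite runs
end to end.

Planted cohorts: for each bundled study the generator constructs the
requested number of patients satisfying the study by construction
(disjoint id blocks, constraint-driven generation), then records as truth
the SQL oracle's answer over the emitted database — planted patients are
always contained in it, background patients may qualify naturally.
Per-patient count distributions (Poisson) and value distributions
(lognormal/normal) are generator conventions chosen for plausibility;
nothing downstream depends on their exact shape. What passing tests on
this data do **not** show: robustness to real-world coding noise,
free-text misspellings, composite keys, or non-ISO date formats.

## Numerical and degenerate-input choices

- Dates are compared at day resolution throughout; no times of day.
- Deterministic ordering everywhere: views stream by base-table primary
  key, ontology nodes sort by path, exports are byte-stable for a fixed
  config and seed. (A CSV-directory source orders keys lexicographically
  rather than numerically, so its row order differs from the same data in
  SQLite; counts and query answers are unaffected.)
- Empty sources, empty tables, zero-patient configs and empty concept sets
  all produce valid empty outputs (vacuously equal verification).
- Composite primary keys / composite FKs are unsupported and rejected at
  config load.
- Chunk size (default 50,000 rows) trades memory for executemany calls;
  any value ≥ 1 is valid.

## Limitations

- No terminology mapping (ICD-10 etc.): the ontology mirrors source
  structure only.
- Modifiers are carried as the i2b2 default `@` and never populated; units
  are stored in `UNITS_CD`, not as modifiers, and are not converted.
- The query engine targets this package's star loads; it is not a general
  i2b2 web-client/XML query implementation.
- The SQL oracle covers the four bundled studies, not arbitrary study
  definitions.
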