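# txstar

Transplant-EHR to i2b2 star-schema ETL, with a cohort query engine and a
synthetic source generator.

## The problem

Clinical documentation systems for organ transplantation store their data in
deeply normalized relational schemas in which the **transplantation** — not
the patient — is the central entity: diagnoses, medications and free-text
findings hang off the transplantation by foreign keys, laboratory values and
examinations reference only the patient. Cohort-identification platforms
such as **i2b2** instead use a generic entity–attribute–value (EAV) star
schema: one `OBSERVATION_FACT` table in which every clinical observation is
a row `(encounter_num, patient_num, concept_cd, start_date, value)`,
surrounded by patient/visit/concept dimensions and a hierarchical metadata
tree. Moving data from the first world to the second without losing the
relationships between entities is the job of this package. It is aimed at
clinical data engineers building research data warehouses from transplant
registries (and structurally similar EHR schemas).

## The method

**Five table types.** Each source table is classified on two axes:

| type | meaning | handling |
|------|---------|----------|
| 1 `EAV_READY` | already one fact per row (labs) | passthrough, no rotation |
| 2 `ANCHOR_LINKED` | FK chain reaches the transplantation | join chain, transplant id = encounter |
| 3 `UNLINKED` | no reference to the transplantation | timeframe assignment (below) |
| 4 `FREE_TEXT_BLOB` | carries free text | value goes to `OBSERVATION_BLOB`, valtype `B` |
| 5 `UNIT_BEARING` | numeric values with units | unit goes to `UNITS_CD` |

Types 4 and 5 are data flags and may co-occur with any structure type.

**Encounters by timeframe.** The transplantation identifier serves as the
i2b2 encounter number. A fact without a foreign key toward the
transplantation is attached by date: transplantation *i* of a patient owns
the window

```
[ tx_date_i − 14 d ,  failure_date_i + 14 d ]        if the graft failed
[ tx_date_i − 14 d ,  tx_date_{i+1} − 14 d )         otherwise (open if last)
```

Both closed ends are inclusive; when a failed graft's tail overlaps the next
transplant's lead, the window with the later start wins. A fact outside
every window gets a deterministic negative **surrogate encounter** (one per
patient and inter-window gap), so no fact is ever dropped.

**EAV rotation.** A wide row with *x* columns of which *y* are metadata
rotates into at most *x − y* facts — exactly one per non-null value cell.
Null cells emit nothing; "value is not set" cohort criteria are answered by
concept absence. Concept codes are `PREFIX:table:column[:value]`, and a
basic i2b2 ontology (`\PREFIX\table\column\value\`) is derived from the
observed concepts, so every loaded fact is navigable. Facts recorded at one
source event (e.g. the analytes of one lab test) share an `INSTANCE_NUM`
(`GROUPED` mode); `IDRT_COMPAT` mode reproduces the legacy behaviour of a
global running counter, which breaks "same event" queries.

**Verification.** After every load, the number of facts per source table is
compared with the number of non-null value cells in the source — an exact,
per-table count-conservation check.

**Cohort queries.** Studies are panels of criteria over eight categories:
same-event (1), numeric comparison (2), date comparison (3), value-not-set
(4), exact string (5), wildcard free-text search (6), temporal order (7a)
and "A at least *x* days after B" (7b). Four bundled transplant studies
exercise all eight, and an independent SQL oracle answers the same questions
directly on the relational source, so star-vs-source answer equality is a
testable property.

## Worked example

```bash
txstar generate --out source.db --seed 7 --n-patients 60
txstar classify --source source.db
txstar etl --source source.db --target star.db
txstar query --star star.db --study 3
txstar profile --study 3
```

`generate` emits a seeded synthetic transplant EHR and prints its exact
per-table value-cell counts:

```json
"per_entity_row_counts": {
 "Transplantation": 63, "LabValue": 14968, "Diagnosis": 258,
 "Examination": 563, "Finding": 111, "Medication": 402
}
```

`classify` shows the five types instantiated (`LabValue` is
`EAV_READY + UNIT_BEARING`, `Finding` is `ANCHOR_LINKED + FREE_TEXT_BLOB`,
`Examination` is `UNLINKED`, `Donor` is reported unclassifiable and routed
to no fact table). `etl` then prints the run report:

```json
{
 "total_facts": 16365,
 "verification_overall_equal": true,
 "encounter_rules": {"LINKED": 834, "SURROGATE": 10478, "WINDOW": 4820}
}
```

16,365 facts were loaded — one per non-null source value cell
(63+14968+258+563+111+402), so verification reports equality for every
table. The rule counts show how encounters were found: 834 facts carried a
foreign-key link, 4,820 fell inside a transplantation timeframe, and 10,478
(mostly labs predating the transplant window) received surrogate
encounters rather than being lost. `query --study 3` returns the patients
with a kidney-not-pancreas transplant, a graft rejection, and a free-text
documented urinary tract infection between the two (11 patients on this
seed), and `profile --study 3` lists the criterion categories it exercises:
`["3", "5", "6", "7a"]`.

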