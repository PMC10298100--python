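# Methods

## Problem and approach

FHIR R4 represents clinical records as nested JSON resources, which is
convenient for exchange but awkward for cohort-level counting and grouping.
`fhirtab` implements the classic warehouse answer at desk scale: retrieve
resources in bulk from a store (local NDJSON/Bundle files or a FHIR REST
endpoint), flatten each resource through a per-type mapping template into a
small relational schema, and run descriptive workflows (counts and integer
percentages by gender, year, allergy label, and test name) as SQL over that
schema. A deterministic synthetic dataset generator supplies referentially
closed inputs whose marginals are known exactly, so every workflow output
can be checked against an independent count over the raw JSON.

## Mapping model

A template is an ordered list of entries, each pairing a dotted element
path with a target table and column. Flattening iterates the entries with a
counter-decrement loop bounded by the template length; for each entry the
path is resolved against the element tree.

Numerical/structural choices:

- **Path addressing, not tag equality.** FHIR elements are nested and
  repeated, so "this template tag matches this resource tag" is realized as
  structured path resolution with `[n]`/`[*]` markers (`name[0].given[0]`,
  `telecom[*].value`). Flat string comparison of tags is ill-defined on
  JSON trees.
- **Repeated elements → child tables.** Entries marked `repeated` share a
  `[*]` repeat root and produce one child-table row per occurrence, carrying
  the parent's logical id. Patient spreads over `patient` +
  `patient_telecom` + `patient_address`; all other types map to one table.
- **Missing elements → NULL** (strict mode aborts instead). FHIR elements
  are almost all optional; a sparse resource is data, not an error.
- **References** are parsed to (type, id) at mapping time and stored as a
  column pair: the raw target id (`*_ref_id`) and the resolved surrogate key
  (`*_key`). A post-load resolution pass re-resolves every pair, which makes
  table contents independent of stream order and turns unresolvable
  references into inspectable orphans rather than lost rows. Bare untyped
  ids are rejected as references because they are ambiguous join keys.
- **Dates stay verbatim** as ISO-8601 strings (possibly partial: `1999`,
  `1999-06`); year extraction in analytics takes the first four characters.
- **Idempotency.** Rows are upserted by the (resource type, logical id)
  natural key, so re-running a load changes nothing. An `append` load mode
  exists to exercise the duplicate-key branch of the integrity check.

The template registry is serializable to YAML/JSON, so mappings can be
edited without code changes. Generic FHIRPath evaluation, profile-driven
schema inference, and terminology validation are out of scope.

## Analytics

All five workflows are single SQL statements over the store, returning
labeled count tables with a recorded total and any exclusions (orphans,
undated rows, failed joins) reported alongside rather than silently
dropped. Allergy cohorts count **distinct patients** per label through the
allergy→patient join, so duplicate recordings of the same allergy do not
inflate the cohort. Zero-count years are omitted by default (sparse
presentation) with a flag to include them; gender values are reported
lowercase as FHIR stores them.

Integer percentages use largest-remainder (Hamilton) apportionment: floor
each share of 100, then hand the leftover points to the largest fractional
remainders, ties broken by earlier index. This is exact when counts sum to
100 and always sums to exactly 100 otherwise; the tie-break makes results
deterministic for any input.

## Synthetic data generator

The generator's central property is **exact-quota assignment**: categorical
attributes are expanded from their configured histograms into lists,
shuffled with the seeded RNG, and assigned one-to-one — never sampled — so
every configured marginal holds with equality on every run. The seed
affects only shuffling and free-text synthesis (names, telecoms,
addresses from small word pools); two runs with the same (config, seed) are
byte-identical.

The default configuration emulates a small two-system hospital extract
(patient registration + laboratory ordering): 100 resources of each of the
seven types (700 total); gender 55 male / 45 female; birth years over
1950–2021 with eight fixed cells (1950→3, 1951→1, 1952→3, 1953→2, 1955→1,
2013→3, 2018→1, 2021→2); seventeen allergy labels with fixed patient counts
summing to 100; eight test names whose counts equal their integer
percentages (HIV 16 … SGPT 9, total 100); and order years over 1950–2021
with eight fixed cells (1951→4, 1952→4, 1953→3, 1955→2, 2010→5, 2015→3,
2019→6, 2020→5). Year mass not fixed explicitly is spread round-robin over
the remaining years in ascending order, keeping the fixed cells exact and
the totals at 100.

Interpretation choices worth stating:

- **Registration year = birth year.** The patient table's only standard
  printed date element is `birthDate` and its configured range matches the
  registration-year range, so the registrations-by-year workflow defaults to
  `date_basis="birth_date"`. A config switch emits an explicit
  registration-date extension instead, and the workflow accepts
  `date_basis="registration_extension"`, keeping both readings available
  without leaving standard FHIR elements.
- **One allergy label per AllergyIntolerance resource, at most one resource
  per (patient, label).** The allergy-label counts sum exactly to the
  AllergyIntolerance resource count, so patients-per-label equals
  resources-per-label and the cohort table is reproducible without
  inventing co-occurrence structure.
- Test names travel in `ServiceRequest.code.coding[0].display` with an
  empty system (labels only, no code system); each DiagnosticReport mirrors
  its ServiceRequest's code and subject via `basedOn`.
- Condition and Appointment resources carry minimal conformant content
  (status/category/code; status/type/priority + patient participant); no
  workflow constrains them, so they exercise mapping and integrity only.
- Default seed 1729, recorded in the manifest with a config digest.

What the generator does **not** emulate: clinically coherent longitudinal
trajectories, coded terminologies (ICD-10/LOINC/SNOMED CT), multi-allergy
patients with realistic co-occurrence, missing data, or malformed inputs
(tests construct those separately). Passing round-trip tests therefore
demonstrates that the pipeline is lossless and count-correct under known
marginals — not that it handles the messiness of production EHR extracts.

## Retrieval

Both source kinds satisfy one contract: an empty parameter map streams the
whole type; `identifier`, `given`, `_id` match exactly and `birthDate`
matches on date prefix. REST retrieval pages through searchset Bundles
following `next` links (page size configurable; counts are
pagination-invariant) with 3 retry attempts and exponential backoff on
idempotent GETs, backing off from 0.2 s. `_id` (resource id) and
`identifier` (business identifier) are deliberately distinct parameters.
FHIR modifiers, chaining, write operations, and the bulk `$export` protocol
are out of scope.

## Store

Embedded SQLite behind a URI (`path`, `sqlite:///path`, or `:memory:`);
the analytics layer speaks plain SQL, so a server-based engine could be
substituted behind the same module surface. Nine tables, surrogate integer
keys, FHIR logical ids preserved as natural keys, declared foreign keys.
`service_request` doubles as the order table; `diagnostic_report.based_on`
links reports to orders. Schema creation is repeat-safe and refuses to
touch a location whose existing tables differ from the declared layout.
The integrity check reports orphan references per foreign key, duplicate
natural keys, and null rates of the analytically load-bearing columns.

## Problem sizes

The default experiment is 700 resources and runs end-to-end (generate,
map, five workflows) in a few seconds. Property checks draw 25 random
valid configurations of 5–40 patients and proportionally sized clinical
resources — large enough to exercise every join and exclusion path while
keeping the full suite fast.

## Known limitations

- Only the seven resource kinds above are supported; an eighth type is a
  template-not-found error by design.
- Search matching is exact-string on a small parameter set.
- Single-writer loads; no migrations, transactions spanning runs, or
  concurrency.
- XML serialization and FHIR profile/terminology validation are not
  implemented.
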