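# Methods

This note documents the procedures skiff implements, the parameters that
matter, what the synthetic data emulates, and the design decisions taken
where the design was genuinely open.

## Retrieval model

All communication with a FHIR server is plain REST search: a query is a
resource type plus a request-parameter multimap (repeated keys are sent as
repeated pairs, which FHIR interprets as AND). The server answers with
searchset Bundles; skiff follows `link[relation=next]` until exhaustion, so
the page size (`_count`, default 100) never changes *what* is retrieved,
only how many round trips it takes. Next links are followed verbatim —
absolute URLs on a different host are honored with a warning, since many
servers return absolute pagination links.

Three retrieval strategies sit on top of this:

* **Single query** (`steal_bundles`) — one search, full pagination,
  optional bundle cap.
* **Time partitioning** (`sail_through_search_space`) — the requested
  interval `[start, end)` is split into at most `n_procs` half-open spans
  `[a_i, b_i)` whose lengths differ by at most one day (remainder days go
  to the earliest spans; the span count is capped at the number of days).
  Each span contributes `date=ge<a_i>` and `date=lt<b_i>` to a sub-query.
  Half-open spans were chosen over inclusive ones because they make
  boundary behavior provable: a resource dated exactly on an interior
  boundary satisfies exactly one span, so the union is duplicate-free and
  gap-free by construction.
* **Per-row constraints** (`trade_rows_for_bundles`) — one sub-query per
  DataFrame row, built by appending each constrained column's cell value as
  a search parameter (prefixed `system|` when a code system is configured).
  Rows with a missing or empty constrained cell are skipped and reported in
  a `skipped` list rather than aborting the run; bulk cohort builds should
  not die on one bad row, while transport errors still fail fast because
  they indicate a systemic problem, not a data problem.

Concurrency is specified as a contract, not a mechanism: for any worker
count the result must equal sequential execution in the stated order (span
order, row order). The implementation uses a thread pool — the workload is
network-bound — and the default worker count is one, so parallelism is
always an explicit opt-in scaled to what the server tolerates.

## Authentication

Sessions support no auth, HTTP basic, and bearer tokens. Token freshness is
maintained both proactively (refresh when the token age reaches
`token_refresh_interval`) and reactively (on a 401, refresh and retry the
request once); the refresh endpoint is tried first and full
reauthentication is the fallback, so both client-side and server-side
expiry are covered. The token endpoint contract (form POST to
`{base}/token`, bearer POST to `{base}/token/refresh`) is the one the
bundled mock server implements; real deployments vary, which is why the
transport and endpoints are configurable. Retries for transport errors and
5xx responses default to `max_retries=3` with exponential backoff starting
at 1 s — deliberately conservative defaults for shared clinical
infrastructure. TLS verification is on unless explicitly disabled.
Credentials never live in config files; they come from environment
variables.

## FHIRPath subset

The extraction language is a bounded FHIRPath subset: dotted member
navigation, integer indexing, `where(member = 'literal')`, `exists()`,
`empty()`, `count()`, `first()`, `replace('a','b')`, `join(sep)`, and an
optional leading resource-type qualifier (`Patient.birthDate`) used to
route attributes in mixed `_include` bundles. Collection semantics follow
the standard: every step maps a collection to a collection, member access
over a list flattens one level, missing members yield the empty collection,
and an empty collection propagates (except through the cardinality probes,
which then yield `false`/`true`/`0`). The `where` predicate supports only
equality against a string or numeric literal — the constructs actually
needed for attribute extraction — and anything outside the grammar fails at
parse time with a character position, so the boundary is explicit rather
than silently approximate. Aggregates, type operations, `resolve()`, and
quantity arithmetic are out of scope.

The engine is validated against an independently written recursive-descent
tree walk (a structurally different algorithm: depth-first per branch
rather than stepwise collection mapping) on thousands of randomized nested
resources.

## Tabulation

The default schema is one row per Bundle entry ("one row ≈ one resource").
Multi-valued path results become ordered list cells rather than exploded
rows, preserving that schema and keeping row counts conservative (rows out
= entries in, for every mode except processing functions, which define
their own schema). Full dumps name columns by dot-and-index paths
(`name.0.family`); this convention is this package's own. One alias may
carry several candidate paths (first non-empty wins), which lets
resource-type-qualified paths from a study and its `_include`d patient feed
the same key column before merging. `merge_rows` combines rows sharing a
key: non-missing beats missing, and genuinely conflicting scalars are kept
as an ordered list cell — lossless and auditable, where first-wins would
silently discard data. Column order is spec order then first-seen order, so
CSV output is deterministic. CSV cells holding lists are serialized as JSON
arrays (RFC 4180 quoting, UTF-8).

## Document triage

Mining is a per-sentence regex pipeline: optional decode (reports are often
stored base64- or HTML-encoded), optional header strip (everything before
the first occurrence of a keyword such as "Findings" — idempotent because
the keyword then sits at offset 0), sentence segmentation, then main
pattern minus exclusion pattern. Matching is case-insensitive by default
because clinical casing is inconsistent. The splitter is rule-based and
deterministic — boundaries at terminal punctuation followed by whitespace
and a capital/digit, with an abbreviation list and an implicit
decimal-number exception — so results are reproducible offline; the
interface accepts a pluggable splitter for users who prefer a statistical
segmenter. The exclusion mechanism is a secondary regex, not sentiment
analysis or negation detection: a sentence matching both patterns is
dropped and counted, which is exactly what "find sarcoma but not
osteosarcoma" needs and nothing more.

## DICOM download

Each table row names a StudyInstanceUID and optionally a SeriesInstanceUID;
resolution expands a bare study to its QIDO-RS series listing. Instances are
retrieved per series over WADO-RS and written as DICOM part-10 files, either
hierarchically (`out/<study>/<series>/`, fewer files per directory) or flat
(`out/<study>_<series>/`). Bulk runs isolate failures: every resolved
(study, series) pair ends in exactly one of two ledgers — successes (folder,
instance count) or failures (category: not_found / transport / write /
corrupt, plus message) — and a failed series' partial folder is removed so a
file count never lies about completeness. Re-running is idempotent: folders
are rebuilt deterministically.

## Synthetic data and what passing tests show

The generator emulates the structure of a metastatic-breast-cancer cohort
study: two ICD-10 Conditions (C50 at prevalence 0.6, C78.0 at 0.5; their
joint carriers form the cohort), the four LOINC marker Observations
(receptor statuses as coded Positive/Negative, TNM stage as a string)
anchored within ±45 days of the metastasis onset so that some fall inside
and some outside the pipeline's ±30-day window, component-bearing
blood-pressure panels (systolic/diastolic, mmHg), base64-encoded
DiagnosticReports with planted positive ("…evidence of sarcoma…") and
excluded ("…known osteosarcoma…") sentences at configurable fractions
(defaults 0.3 and 0.2), and CT ImagingStudies (1–3 series of 1–3 instances)
whose study UIDs are backed by a planted DICOM listing; instances are
rebuilt on demand as minimal valid part-10 files with 4×4 pixel payloads
derived from the SOP UID, so stores serialize as plain text. Deaths are
drawn to postdate every recorded diagnosis so derived survival times are
non-negative. Default sizes (40 patients, one year of activity, 1–3
documents and 0–2 studies per patient) keep whole-stack runs in seconds
while exercising pagination, windows, and merges.

These choices make correctness *exactly* decidable: miner ground truth is
the generator's own label per document, cohort membership is enumerable
from the store, and referential integrity is checked exhaustively. The
corresponding limits should be stated just as plainly: value distributions
are not clinically realistic, documents are templated English rather than
real dictation, the mock server indexes only the search parameters the
toolkit exercises (token, date, reference, `_id`, `_count`, `_include`,
`_history`) and returns 400 on others unless set lenient, and no terminology
semantics or FHIR profile validation exist. Passing tests therefore
demonstrate the client logic — pagination, partitioning, flattening, merge,
triage, ledgers — not robustness to the irregularities of any particular
production server.

The mock runs in-process (no sockets) for fast unit tests and mounts on a
localhost HTTP server for integration tests of the real transport, so the
exact code path used against production servers is also exercised.

## Numerical and degenerate-input choices

Dates compare on their ISO date portion (the first 10 characters), matching
FHIR's date-precision search semantics for the day-granular data used here.
Time partitioning refuses empty ranges; a span count larger than the day
count is capped rather than producing empty spans. `where` numeric literals
compare as floats, with booleans excluded from numeric comparison. A
zero-instance series is classified corrupt rather than silently producing
an empty folder. The example pipeline breaks ties deterministically: when
several Observations of one code fall inside a patient's window, the first
by id order wins; cohort rows sort by patient id; all of this is what makes
the output CSV byte-identical across runs and worker counts.

## Known limitations

Write operations, GraphQL, and the bulk-data `$export` API are out of
scope, as are OAuth2/SMART-on-FHIR flows, DIMSE (C-MOVE/C-GET) transfer,
image conversion, and de-identification. Combining per-row constraints with
time partitioning in a single call is intentionally not offered — the two
parallelization axes compose ambiguously — and server-side patient-identity
deduplication via `Patient.link` is left to servers that implement it.
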