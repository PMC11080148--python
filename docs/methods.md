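# Methods

## Indicator definitions and the approximation they encode

The national audit that publishes these indicators does not disclose its
exact algorithm, so `fedqi` computes the indicators from the published
variable lists and outcome types, making every combination rule explicit:

- **Cohort membership.** A row enters an indicator cohort when its tumor
  localization matches the indicator spec and, by default, it is not
  referred from another center (`exclude_referred=True` for both
  indicators; referral status appears in both variable lists, and this
  flag is how the demo keeps its cohorts exact — see quota mode below).
  Every hosted record is treated as a resection case; a resection-type
  filter can be added at the query level if a deployment needs one.
- **Waiting time (2b).** Wait = `first_therapy_date − date_of_diagnosis`
  in whole days, where the first therapy date is the *earlier* of
  neoadjuvant-therapy start and surgery. "Short" is strictly `< 35` days
  (5 × 7; the published condition prints a strict `<`). Day arithmetic is
  pure calendar-date subtraction — no times of day. Rows without a
  diagnosis date are dropped from the denominator with a logged count.
  The published condition text defines 2b on rectum carcinoma, while the
  published per-center results table reports its counts on the colon
  population; localization is therefore a parameter, and the demo/default
  uses **colon** to reproduce that table. Neither reading is asserted as
  correct.
- **Complications (8).** Crude rate of postoperative complications over
  the rectum cohort. Case-mix variables travel with the retrieval query
  but are not used: no adjustment, matching the proof-of-principle this
  package reproduces.
- **Exactness.** `LocalResult` stores integer counts and the exact float
  ratio. Rounding (integer percentages, 3-decimal rates) happens only in
  display/reporting code.

## Aggregation

The master algorithm averages the per-center ratios **unweighted** by
default. Rationale: the benchmark-style mean line in audit dashboards is
drawn against per-center percentages, and with two centers of sizes 4153
and 7 a pooled mean would be indistinguishable from the large center. The
pooled mode (`Σ numerators / Σ denominators`) is available via
`mean_mode="pooled"`. Centers with undefined ratios (empty or suppressed)
are excluded from the mean with a logged notice; if none remain, the run
fails loudly. Derived quantities: expected events `mean × denominator`
per center, and rate-of-mean `ratio / mean`; with the unweighted mean the
rate-of-mean values average to exactly 1.

## Synthetic cohorts: what the generator states and what it does not

The generator emulates two study centers: a large center whose extraction
yielded 4699 patients (546 colon + 4153 rectum cohort members) and a small
center represented by a 40-patient simulated dataset. The source study
states the simulated cohort's *size* and the per-center marginal counts
but not the underlying distributions, so:

- **Quota mode** reproduces marginal counts exactly: per localization a
  `(denominator, numerator)` pair is hit by shuffled assignment (colon
  numerator = short-wait count, rectum numerator = complication count).
  Quota records are generated non-referred. Records beyond the quota
  denominators — the 23 extra patients of the 40-patient center — are
  generated as *referred*, so the default referral exclusion keeps the
  indicator cohorts exactly at the quota denominators while the station
  still hosts the full table. This is this package's own construction;
  the source states only the size and the margins.
- **Bernoulli mode** draws every marginal independently
  (localization/referral/complication probabilities, a waiting-time
  distribution or a `short_wait_fraction`).
- **Case-mix distributions are fixtures, not claims**: age truncated
  normal (mean 68, sd 11, 18–95 y), BMI log-normal (median ≈ 26 kg/m²,
  σ_log 0.15, 15–50), Charlson truncated Poisson (λ 1.2, cap 12), ASA
  categorical (12/55/28/4.5/0.5 % for classes 1–5), preoperative
  complications Bernoulli 0.25, waiting time uniform 7–62 days. They make
  the tables look like a plausible elderly surgical cohort; no indicator
  value depends on them, and no clinical correlation (e.g. ASA ×
  complications) is modelled beyond the configured marginals.
- Waiting time is realized as an integer day offset from the diagnosis
  date; when a record has neoadjuvant therapy the offset places the
  neoadjuvant start and surgery follows 14–60 days later, otherwise it
  places surgery. This makes waiting-time cohort membership exactly
  controllable.
- All randomness flows through one `numpy` generator from an explicit
  integer seed; identical (config, seed) gives byte-identical CSVs.

A green test on synthetic data therefore establishes that the *pipeline
arithmetic* is correct — retrieval, counting, aggregation — not that real
EHR extractions are clean; messy codings, duplicate registrations and
free-text fields are out of scope.

## FAIR graph schema

One star per patient: subject IRI `{base}patient/{center}/{patient_id}`,
one predicate per column, typed literals (`xsd:date`, `xsd:boolean`,
`xsd:integer`, `xsd:decimal`) and concept IRIs for enumerated values.
Terminology anchoring is annotation-based: predicates and value concepts
carry a `terminologyCode` literal (SNOMED CT identifiers in the default
mapping — placeholders, editable in `data/default_mapping.json`), rather
than using the codes as predicates, keeping graphs readable while
preserving the semantic hook. Missing data is an absent triple. One
dataset-level provenance triple records the center. The round-trip
`flat_view(triplify(t)) == t` (up to record order) is enforced by tests;
triple counts obey `records × (1 + non-missing mapped cells)` over the
patient-subject triples, with dataset-level annotation triples counted
separately.

Because no RDF library is available in the target environment, the package
carries a minimal RDF core: ground graphs (no blank nodes, so isomorphism
is set equality), Turtle and N-Triples writers that emit
one-statement-per-line standards-conformant documents, and parsers for
that profile (plus `;`/`,` lists in Turtle). The SPARQL engine implements
the SELECT fragment the shipped queries need — basic graph patterns,
`OPTIONAL`, `FILTER` with comparisons and boolean connectives — evaluated
as an index-driven nested-loop join, linear in cohort size for star
queries. Malformed queries raise with a character position; queries over
unknown predicates return zero rows.

## Station boundary and privacy

Stations expose exactly two capabilities to the orchestrator:
`accept_train` and `return_payload`; the graph and row-level query results
are reachable only by code running inside the station (the dispatched
local algorithm). Every payload is audited against a closed-world schema —
exactly the six aggregate fields, correct types, `numerator ≤ denominator`,
ratio consistent — and any extra field (the channel record-level data
would need) rejects the run. Suppression (`min_cell_size`) defaults to 0
so small-center counts (7 and 4) stay reproducible; when enabled, both
counts and the ratio are replaced by an explicit suppressed marker.
Transport is in-process: the production deployment's containers, message
broker and token auth are infrastructure, not method, and are out of
scope.

## Numerical and degenerate-input choices

- Ratios are exact float divisions of exact integer counts; no tolerance
  enters the pipeline itself.
- Empty cohort → denominator 0, ratio undefined (`None`), a warning, not
  an exception; undefined centers are skipped by mean/plots with a log
  note; an all-undefined federation is an error.
- Tie-break: a neoadjuvant date equal to the surgery date is the first
  therapy date (min of the two).
- Truncated normal/log-normal sampling is by rejection (cap 1000 tries,
  then a configuration error naming the field).
- Plots embed no timestamps (SVG date metadata stripped, hash salt
  pinned), so identical inputs give identical bytes.

## Known limitations

- No case-mix adjustment and no funnel control limits — mean lines only,
  matching the reproduced dashboard.
- The SPARQL subset excludes aggregates, property paths, UNION and
  subqueries; the indicator logic, not the query, does the counting.
- Synthetic data only; no ETL from real EHR systems.
- Terminology codes are unvalidated placeholders; governance-approved
  codes must be supplied per deployment.
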