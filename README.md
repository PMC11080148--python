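# fedqi — federated surgical quality indicators over FAIR data stations

National clinical audits (such as the Dutch ColoRectal Audit) compute
hospital quality indicators by collecting patient-level data centrally —
a slow, privacy-sensitive process. `fedqi` demonstrates the federated
alternative for colorectal-cancer surgery: each hospital FAIRifies its
patient table into an RDF graph behind a query-only *station*, an analysis
*train* (SPARQL retrieval query + indicator algorithm) travels to each
station, and only aggregate numerator/denominator payloads travel back to
be combined and plotted. No patient-level value ever crosses the station
boundary, and an explicit closed-schema audit rejects any payload that
tries.

It is aimed at researchers and registry engineers prototyping
privacy-preserving quality measurement; a built-in synthetic-EHR generator
stands in for hospital data so the whole pipeline is runnable and testable
on a laptop.

## The indicators

For a center *c* with cohort size (denominator) `N_c` and event count
(numerator) `O_c`, each indicator is the crude proportion `p_c = O_c / N_c`:

- **Waiting time (2b)** — cohort: resections of one tumor localization,
  primary carcinoma diagnosed locally (not referred); event: strictly fewer
  than 35 whole days (< 5 weeks) between the date of diagnosis and the
  *first therapy date*, the earlier of neoadjuvant-therapy start and
  surgery.
- **Complications (8)** — cohort: rectum resections (not referred); event:
  any postoperative complication. Case-mix variables (age, BMI, Charlson
  score, ASA class, preoperative tumor complications) are retrieved with
  the cohort but no risk adjustment is applied.

The master step combines per-center results: the cross-center mean
`p̄ = (1/K) Σ p_c` (unweighted by default; pooled `ΣO_c / ΣN_c` available),
each center's **expected events** `E_c = p̄ · N_c`, and its **rate of the
mean** `p_c / p̄`. The two dashboard-style figures plot percentage vs
cohort size (with a green mean line) and rate-of-mean vs expected events
(with a blue reference line at the mean).

## Worked example

```bash
fedqi demo --outdir demo/ --seed 1
```

generates the two synthetic centers (4699 and 40 patients, quota mode),
FAIRifies them to Turtle, hosts one station each, dispatches both trains,
and prints:

```
qi2b center1: 546/546 = 1.000
qi2b center2: 7/10 = 0.700
qi2b mean ratio: 0.850
qi8 center1: 2144/4153 = 0.516
qi8 center2: 4/7 = 0.571
qi8 mean ratio: 0.544
```

Reading: every one of center 1's 546 colon-cohort patients started therapy
within 5 weeks (100%) versus 7 of 10 at center 2 (70%), mean line at 85%;
the rectum complication rate is 0.516 at center 1 and 0.571 at center 2.
`demo/` then holds the per-center CSVs and Turtle graphs, `results.json`,
and the two comparison figures (`qi2b.png/svg`, `qi8.png/svg`).

The steps are also available individually:

```bash
fedqi generate --config cfg.json --out center.csv
fedqi fairify  --in center.csv --mapping mapping.json --out station.ttl
fedqi run      --stations s1.ttl --stations s2.ttl --train train.json --out results.json
fedqi plot     --in results.json --outdir figs/
```

and as library functions (`generate_center`, `triplify`, `host_station`,
`run_federated`, `plot_qi2b`, `plot_qi8`, …).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete two-center pipeline from scratch — synthetic cohort
generation, triplification, station hosting, train dispatch for both
indicators, aggregation and figure rendering — and writes its JSON output
to the given path.

## Layout

- `src/fedqi/synthetic_ehr.py` — cohort generator (Bernoulli + exact-quota
  modes), CSV I/O
- `src/fedqi/fair_model.py` — triplification, ontology mapping, Turtle /
  N-Triples serialization, inverse flat view
- `src/fedqi/station.py` — query-only FAIR stations with suppression policy
- `src/fedqi/indicators.py` — the two indicator computations
- `src/fedqi/federated.py` — trains, local/master split, payload audit
- `src/fedqi/reporting.py` — the two comparison plots
- `src/fedqi/data/` — default mapping (placeholder terminology codes),
  demo configs, JSON Schemas, shipped SPARQL queries

See `docs/methods.md` for the modelling choices, parameters and known
limitations.
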