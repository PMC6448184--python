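# provlink

Link state licensure rosters to national (NPPES-public-use-file-style)
provider records to produce accurate, de-duplicated provider-directory
records. The pipeline filters national records by provider-type taxonomy
code set and by location, classifies candidate pairs into seven
name/address match types, scores each matched entity (last name, first
name, city, street) over a multi-year snapshot window with recency-decayed
points, thresholds the total, resolves candidates one-to-one, and merges
the winning pairs into a directory CSV.

A synthetic cohort generator with injectable error channels (misspellings,
name changes, moves, inaccurate taxonomies, middle-name-as-first,
unmatched roster residue) and a recall/precision evaluation harness make
the whole system testable with no external data.

## CLI

Three subcommands mirror the three workflows:

```bash
# 1. generate a synthetic cohort (roster + 5 national snapshots + truth)
provlink simulate -n 500 --seed 7 --out cohort/ \
    --p-misspelling 0.02 --p-name-change 0.02

# 2. run the linkage pipeline
provlink link --licensure cohort/licensure.csv \
    --nppes 2013=cohort/nppes_2013.csv --nppes 2014=cohort/nppes_2014.csv \
    --nppes 2015=cohort/nppes_2015.csv --nppes 2016=cohort/nppes_2016.csv \
    --nppes 2017=cohort/nppes_2017.csv \
    --provider-type certified_nurse_midwife --out run/

# 3. evaluate against ground truth
provlink evaluate --predicted run/directory.csv \
    --truth cohort/truth.tsv --out eval/
```

Exit codes: 0 success, 1 runtime failure, 2 invalid input/configuration.
Each `link` run writes `directory.csv`, a per-stage `run_report.jsonl`
(every stage conserves `in == out + dropped`), `rejects.csv` (quarantined
national rows), `ambiguous.csv` (exact-tie candidates, excluded rather
than guessed) and `effective_config.json`.

## Key defaults

* Scoring window 2013–2017 (5 snapshots); 5 points for a most-recent-year
  entity match, minus one point per year older, floored at 0.
* Acceptance threshold **12** — this is a package default, not a published
  value; configurable via `--threshold` or `scoring.threshold`.
* Exact string comparison by default; `--fuzzy` enables
  misspelling-tolerant matching (Levenshtein ≤ 2 for keys of length ≥ 5,
  ≤ 1 otherwise) with deletion-neighbourhood blocking that provably never
  loses a pair the classifier would accept.
* Location filter keeps records whose practice OR mailing address is in
  {CT, MA, NY, RI, FL}.
* Taxonomy sets per provider type ship in
  `src/provlink/resources/taxonomy.yaml` (editable).

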