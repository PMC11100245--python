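# faersig

Disproportionality signal mining for FAERS-style spontaneous-reporting
data: parse quarterly `$`-delimited ASCII packages, deduplicate report
versions, profile a target-drug cohort, build drug–event 2×2 tables at
PT or SOC level, and score them with ROR, PRR, chi-squared, the Bayesian
information component (IC) and the observed/expected reporting ratio
(EBGM), each with confidence bounds and the standard screening
thresholds (a ≥ 3 with CI lower bounds > 1, IC025 > 0, EBGM05 > 2).

Two companions make the pipeline testable without any download:

* `faersig.synthetic` — a generative model that emits the exact file
  dialect with configurable drug/event vocabularies, designated
  signal pairs at a chosen reporting-rate ratio, duplicate case
  versions and deleted-case lists;
* `faersig.reconstruct` — recovers the unpublished global pair-level
  denominators (T, N) of a published PT-level signal table from three
  printed rows, then re-predicts every other printed statistic from its
  (case count, PRR) alone.

## Counting unit

Cell counts are distinct **(report, event-label) pairs**, not raw
reports: a report with three distinct PTs contributes three pairs, and
`a + b` is the target drug's total pair count. Reports in the cohort
never contribute to the comparator cells c/d, even when they also list
other suspect drugs.

## Command line

```
faersig simulate --config config.yaml --outdir sim/         # synthetic quarter
faersig run      --config config.yaml --outdir out/         # full pipeline
faersig validate-reference --out report.csv                 # reproduce shipped reference rows
```

`faersig run` writes `profile.csv` (cohort descriptives), `signals_pt.csv`
/ `signals_soc.csv` (full precision, plus `*_2dp.csv` two-decimal views),
`dedup_summary.csv` and `run.log`. A config names either real quarter
directories (`DEMO.txt` … `THER.txt`) or a `synthetic:` block; see
`faersig/pipeline.py` for the schema and `tests/test_pipeline_cli.py`
for a worked example. Flags `--level`, `--min-a`, `--yates`, `--rule`,
`--seed` override config keys.

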