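# pvsignal

Disproportionality analysis of FAERS-style spontaneous adverse-event
reports: ingest the quarterly ASCII tables, deduplicate case versions,
build drug–event 2×2 contingency tables, and score every event with the
four standard pharmacovigilance detectors — ROR, PRR (with χ²), the
BCPNN information component, and the MGPS empirical-Bayes geometric mean
— plus a combined positivity rule. A seeded synthetic-data generator
with planted signals provides ground truth for end-to-end validation.

## What it computes

For a target drug (primary-suspect reports) versus all other reports,
and for each adverse-event term (MedDRA-style PT, optionally aggregated
to SOC), the pipeline builds the 2×2 table

|                | event Y | other events |
|----------------|---------|--------------|
| target drug    | a       | b            |
| all other drugs| c       | d            |

and reports:

- **ROR** `(a·d)/(b·c)` with a 95 % Wald interval on the log scale;
- **PRR** `[a/(a+b)] / [c/(c+d)]` with its Wald interval, plus the
  Pearson χ² (Yates-corrected by default);
- **IC / IC025** — the closed-form BCPNN information component and its
  two-standard-deviation lower bound;
- **EBGM / EBGM05** — DuMouchel's empirical-Bayes geometric mean under a
  two-gamma mixture prior fitted by maximum likelihood over all
  (drug, event) cells of the database, and its posterior 5th percentile.

A term is flagged **positive** when all of `a ≥ 3`, `ROR ≥ 3`,
`PRR ≥ 2`, `EBGM05 > 2` and `IC025 > 0` hold (each threshold is
configurable; terms with non-evaluable statistics are never flagged).

Descriptive outputs accompany the signal tables: a baseline
characteristics table (sex, age bucket, reporter, country, route,
outcomes; percentages rounded half-up to two decimals), annual report
counts, the time-to-onset distribution (median, quartiles, binned
counts) and indication tallies.

## Worked example

Generate a 2 000-case synthetic dataset with one planted signal
(drug `DRUG01` causes `PT_003` at eight times its background rate),
then run the full pipeline on it:

```bash
pvsignal simulate --out demo/data --n-cases 2000 --background-rate 0.05 \
    --seed 7 --plant DRUG01:PT_003:8
cat > demo/config.yaml <<'YAML'
input_dir: demo/data
target: DRUG01
output_dir: demo/out
pt_soc_map_path: demo/data/pt_soc_map.txt
YAML
pvsignal validate demo/config.yaml
pvsignal run demo/config.yaml
```

which prints

```
wrote 6 tables to demo/data
config OK
2000 cases analysed; 220 in target cohort; outputs in demo/out
```

and the top of `demo/out/pt_signals_full.tsv` (columns abridged) shows
the planted pair flagged and the null pairs quiet:

```
label    a   b    c    d     expected   ror_lo    prr_lo    ic        ebgm      signal    reasons
PT_003   98  433  152  4087  27.830189  4.633751  4.059528  1.772835  3.521084  positive
PT_012   22  509  143  4096  18.367925  0.782941  0.791220  0.238268  0.985376  negative  ebgm05;ic025;prr;ror
PT_019   22  509  134  4105  17.366038  0.835721  0.842635  0.314452  0.985424  negative  ebgm05;ic025;prr;ror
```

The same run also writes `soc_signals.tsv`, `table1.tsv`,
`annual_counts.tsv`, `tto.tsv`, `indications.tsv` and `run_log.txt`.
Re-running an identical config on identical inputs is byte-identical.

Real FAERS quarters work the same way: place the `$`-delimited
`DEMO.txt`, `DRUG.txt`, `REAC.txt`, `THER.txt`, `OUTC.txt`, `INDI.txt`
in a directory and point `input_dir` at it (a synonym file maps brand
names onto one canonical substance; a PT→SOC file enables SOC-level
tables).

## Package layout

- `pvsignal.faers_ingest` — `$`-delimited table parsing, date/age
  harmonization, case linking, version deduplication
- `pvsignal.synthetic_faers` — seeded generator with planted signals and
  a hand-written 20-row fixture with fully documented expected values
- `pvsignal.cohort_builder` — drug-name normalization, target/background
  cohort split, 2×2 table construction at PT or SOC level
- `pvsignal.dpa_core` — ROR, PRR, χ², BCPNN, MGPS/EBGM, positivity rule
- `pvsignal.descriptives` — baseline tables, annual counts,
  time-to-onset, indications
- `pvsignal.pipeline` / `pvsignal.cli` — YAML-configured orchestration
  and the `pvsignal` command (`simulate`, `run`, `stats`, `validate`)
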