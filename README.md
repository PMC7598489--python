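# bmitraj

Tools for longitudinal infant BMI-trajectory analysis on scheduled health
check-up data (seven exams at median ages 5, 11, 21, 33, 45, 57 and 69
months):

* **`bmitraj.synth`** — synthetic-cohort simulator: per-child piecewise
  quadratic BMI curves (infancy peak → nadir → rebound) over Jenss–Bayley
  height growth, with measurement noise, missing exams, corrupted records
  and a per-child ground-truth table for recovery testing.
* **`bmitraj.qc`** — record validity filters (height ≥ 25 cm, weight ≥
  birth weight, strict increase vs the last valid exam), the 0.5–5.0 kg
  birth-weight inclusion window, the ≥5-valid-exams rule and a full
  exclusion report.
* **`bmitraj.ar`** — BMI-nadir detection (earliest-tie argmin over valid
  exams, pluggable identifiability rule requiring a valid exam VII) and
  adiposity-rebound timing classes: very early (exams I–V), early (exam
  VI), moderate-to-late (exam VII); prevalence tables with cumulatives.
* **`bmitraj.subgroup`** — birth-weight classes (VLBW ≤ 1.5 kg < LBW ≤
  2.5 kg < non-LBW ≤ 5.0 kg), rapid weight gain in the first 5 months
  (gain ≥ 5.1 kg, threshold configurable/derivable), and BMI status at
  exam VI from 5th/85th/95th percentile thresholds (within-cohort,
  sex-stratified, or an external table).
* **`bmitraj.stats`** — contingency tables, Pearson χ² and likelihood-ratio
  tests, crude and covariate-adjusted odds ratios (hand-rolled IRLS
  logistic regression, Wald CIs), 13-level BMI percentile curve sets and
  per-exam Welch t-tests between sexes.
* **`bmitraj.cli` / `bmitraj.pipeline`** — YAML-configured end-to-end
  driver with a count-chained run report and SHA-256 output manifest
  (seeded runs are byte-identical).

## CLI

```sh
# simulate a cohort (subjects.csv / exams.csv / truth.csv)
bmitraj synth --n 5000 --seed 1 --out sim/

# quality control -> clean cohort + qc_report
bmitraj qc --subjects sim/subjects.csv --exams sim/exams.csv --out qc/

# nadir detection and AR-timing prevalence
bmitraj ar --clean-cohort qc/ --out ar/ --tie earliest

# subgroups, cross-tabulations, tests, ORs, percentile curves
bmitraj stats --clean-cohort qc/ --classified ar/ar_classification.csv --out stats/

# or everything from one config
bmitraj run --config config.yaml --out out/
```

A minimal `config.yaml`:

```yaml
seed: 1
simulate:
  n_subjects: 5000
  p_miss: 0.05
  p_shrink: 0.03
  p_bw_out: 0.01
```

All file formats are flat UTF-8 CSVs (one row per exam); units are kg, cm
and months.  Malformed rows are routed to `rejected_rows.csv` with line
numbers, never silently dropped.

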