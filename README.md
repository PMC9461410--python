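# vaxwatch

Detects physiological reactions to vaccination from consumer-smartwatch
data and compares them with questionnaire self-reports. The pipeline
covers:

- **Synthetic cohorts** (`vaxwatch.synthetic`) — raw device streams (heart
  rate every 15 s, stress 1–100 every 3 min) with per-participant circadian
  baselines, a severity-scaled post-vaccination elevation peaking near
  24 h, random intercepts, charging gaps, and probabilistic daily symptom
  reporting. Fixed seed ⇒ byte-identical output; per-participant seed
  streams, so growing a cohort never reshuffles existing members.
- **Questionnaire analysis** (`vaxwatch.questionnaire`) — last-entry-per-day
  deduplication, mild/severe symptom tiering (with the feeling-hot /
  fever-above-38.9 °C branch), baseline symptom subtraction, per-symptom
  proportions with Beta(k, n−k) confidence intervals, and stratified
  cross-tabulations.
- **Wearable preprocessing** (`vaxwatch.preprocessing`) — wall-clock hourly
  averaging, linear interpolation of missing runs shorter than 5 h,
  centered 5 h moving average, and post-minus-baseline differencing matched
  by day-of-week and hour-of-day against the 7-day baseline week.
- **Inclusion rules** (`vaxwatch.inclusion`) — the three participation
  criteria with auditable exclusion reason codes.
- **Difference statistics** (`vaxwatch.diffstats`) — severity-stratified
  hourly mean-difference curves with 95% CIs, 72 h window means, Welch's
  t-tests between strata, and peak / return-to-baseline detection.
- **Panel regression** (`vaxwatch.panel`) — participant-hour panels over
  ±168 h (interpolated, unsmoothed) and a maximum-likelihood
  random-intercept regression with a lagged dependent variable, a
  post-vaccination indicator (0–72 h, with a 24–72 h sensitivity refit),
  demographic fixed effects, between/within/overall R², the
  random-effect variance share, and Bonferroni-corrected one-sided testing
  of the indicator.

## CLI

```sh
vaxwatch run --out out/ --seed 7 --n 50          # full pipeline on a simulated cohort
vaxwatch simulate --out data/ --seed 7 --n 50    # just the CSV triplet
vaxwatch classify --roster data/roster.csv --questionnaires data/questionnaire.csv --out out/
vaxwatch preprocess --wearable data/wearable.csv --roster data/roster.csv --out out/
vaxwatch analyze --diffs out/diffs.csv --tiers out/tiers.csv --out out/
vaxwatch panel --hourly out/hourly.csv --roster data/roster.csv --tiers out/tiers.csv \
    --channel hr --window 0-72 --out out/
```

`run` writes every stage artifact (tiers, proportions, hourly series,
matched diffs, inclusion decisions, stratified curves, window means, Welch
tests, all four panel fits) plus `report.json` / `report.txt`. Exit codes:
0 success, 1 validation error, 2 computation error. A YAML `--config`
can override any simulation or analysis constant (post window, gap limit,
smoothing window, fever threshold, alpha, number of comparisons).

Input CSV schemas (written by `simulate`, validated before any run):

| file | columns |
|---|---|
| roster | participant_id, age, sex, underlying_condition, dose, vaccination_time, true_severity |
| wearable | participant_id, channel, timestamp, value |
| questionnaire | participant_id, timestamp, symptoms (semicolon-joined), temperature_c |

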