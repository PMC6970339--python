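# uaprogress

Scoring, simulation, and time-series forecasting tools for substance-use
treatment programs that monitor patients with scheduled urinalyses.

Mandatory treatment programs for stimulant and cannabis use disorders test
patients on a protocol-driven schedule: biweekly urinalysis on entry
("high-demand" phase), a switch to monthly testing after four negative
samples ("low-demand" phase), and a return to biweekly testing after any
positive result. `uaprogress` turns the resulting long-format record tables
into quantitative progress indicators and forecasts, for clinicians and
biostatisticians running or evaluating such programs.

## The model

Each test occasion scores **+1** (negative), **−1** (positive), or **0**
(missed). Per patient, the cumulative score over occasions is a "progress
bar": rising under abstinence, dipping on relapse. Per program week *i*
across the group,

```
score_i          = Σ per-test scores in week i
n_i              = number of patients who took a urinalysis in week i
adjusted_score_i = score_i / n_i            ∈ [−1, 1], missing when n_i = 0
```

The weekly adjusted-score series is split at the phase cut-off week
(default 27 of a 52-week program) and each segment is analysed with an
ARIMA(p, d, q) pipeline: augmented Dickey–Fuller stationarity testing,
AIC-grid order selection (or caller-fixed orders), maximum-likelihood
fitting, Box–Pierce residual diagnostics (Q = T·Σρ̂²), and forecasting with
confidence intervals. The package also ships a protocol-faithful synthetic
cohort simulator (state machine with stabilization, relapse resets,
missed-appointment schedule drift, and dropout) and the study-flow
eligibility filters (≥ 4-visit engagement, 26-week recency, completion).

## Worked example

Simulate a 312-patient cohort, score it, and run the two-phase analysis:

```sh
$ uaprogress simulate --seed 42 --n-patients 312 --out records.csv
INFO uaprogress: simulate: 312 patients, 6952 records, seed=42 -> records.csv

$ uaprogress score --records records.csv --out weekly.csv
INFO uaprogress: score: 312 patients, 52 weeks -> weekly.csv

$ head -5 weekly.csv
week,score,n,adjusted_score
1,0,0,
2,93,259,0.3590733590733591
3,19,41,0.4634146341463415
4,108,218,0.4954128440366973
```

Week 1 is empty (the first scheduled test is at week 2) and week 2 is the
biggest testing week: 259 of 312 patients attended, and the group netted
+93 — an adjusted score of 0.36, i.e. negatives outnumbered positives
roughly 2:1 among tests taken. Odd weeks have small `n` early on (only
patients whose schedules have drifted through missed appointments test on
odd weeks).

```sh
$ uaprogress analyze --weekly weekly.csv --out analysis.json
INFO uaprogress: analyze high_demand: order=(0,0,0) aic=-35.29 portmanteau p=0.851
INFO uaprogress: analyze low_demand: order=(0,1,1) aic=-45.16 portmanteau p=0.848
```

For each segment the report (`analysis.json`) carries the ADF test, the
selected order and coefficients, AIC, the Box–Pierce statistic with its
p-value (here 0.85 — no evidence of residual autocorrelation, so the fits
are adequate for forecasting), and 8-week-ahead forecasts with 95%
intervals. Fixed orders can be supplied instead of the grid search, e.g.
`--orders 3,4,7 2,2,3` (heavily parameterized orders on 26-point segments
trigger a small-sample warning).

The other subcommands: `uaprogress filter --rule engagement|recency|completion`
(eligibility filtering with a JSON report), `uaprogress summarize`
(descriptive baseline table with one-decimal percentages), and
`uaprogress run --config examples/paper_orders.yaml --seed 42 --out-dir out/`
(the full pipeline; byte-identical outputs under a fixed seed). Everything
is also available as a library — see `uaprogress.scoring`,
`uaprogress.simulate`, `uaprogress.cohort`, `uaprogress.timeseries`.

## Documentation

The model, simulator calibration, numerical choices, and known limitations
are documented in [`docs/methods.md`](docs/methods.md).
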