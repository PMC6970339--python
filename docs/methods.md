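# Methods

## The scoring model

`uaprogress` implements a progress-indicator scoring system for substance-use
treatment programs that monitor patients with scheduled urinalyses. Each test
occasion has a trinary outcome and a score:

| outcome  | meaning                          | score |
|----------|----------------------------------|-------|
| negative | no drug metabolites detected     | +1    |
| positive | metabolites detected (relapse)   | -1    |
| missed   | scheduled test not attended      | 0     |

A patient's **progress bar** is the cumulative sum of their scores over test
occasions: monotonically rising under sustained abstinence, dipping on each
positive, flat through missed tests. At the group level, for program week
*i*:

- `score_i` = sum of all patients' per-test scores in week *i*;
- `n_i` = number of patients who actually took a urinalysis in week *i*
  (a missed test is *not taken*, so it contributes to neither the numerator —
  its score is 0 — nor the denominator);
- `adjusted_score_i = score_i / n_i`, which lies in [-1, 1] and is undefined
  (missing) when `n_i = 0`.

Weeks are patient-relative: week 1 is each patient's first program week, so
cohorts are aligned on time-in-program rather than calendar time. This is the
only alignment under which a full-program group curve spans weeks 1–52 for
every completer.

### Missing weeks

The downstream time-series stage needs a complete weekly series. Weeks with
`n_i = 0` are filled by a configurable policy: `zero` (default — conservative,
fabricates no signal, and is logged per filled week) or `interpolate` (linear
between the nearest observed weeks, flat-extended at the edges; requires at
least one observed week).

## Cohort filters

Three eligibility filters mirror a typical mandatory-treatment study flow.
An "outpatient visit" is operationalized as an attended test occasion
(result ≠ missed), since visits and urinalyses are coupled in this protocol;
users with separate visit data can apply their own filter upstream.

- **Engagement**: retain patients with ≥ `min_visits` (default 4) attended
  occasions.
- **Recency**: retain patients whose last attended week is within `max_gap`
  (default 26) weeks of the study end; a patient who never attended has no
  "most recent visit" and is excluded by convention.
- **Completion**: retain patients with ≥ 1 attended occasion in each program
  half (split at week 27 by default) whose last attended occasion is within
  26 weeks of the program end. Completion has no universal formal definition;
  this operationalization is a declared design choice of the package.

Every filter conserves patients (input = retained + excluded) and is
idempotent. Descriptive summaries report boolean attributes as
`count (percent)` with percentages rounded half-away-from-zero to one
decimal, and numeric attributes as mean ± sd.

## The protocol simulator

The synthetic-cohort generator emulates a two-phase testing protocol as a
per-patient state machine:

- **High-demand phase** (program entry): urinalysis every 2 weeks, first test
  at week 2. Each negative increments a stabilization counter; a positive in
  either phase resets the counter to zero and returns the patient to the
  biweekly schedule (i.e. a relapse restarts the full requirement — the
  strictest reading, configurable via `stabilization_threshold`).
- **Stabilization**: accumulating 4 negatives since the last positive
  switches the patient to the low-demand phase.
- **Low-demand phase**: urinalysis every 4 weeks ("monthly" on the integer
  week grid).
- **Missed appointments** delay the next test by exactly 1 week instead of a
  full interval (`missed_delay`, configurable). This is the minimal mechanism
  that produces the characteristic parity drift of biweekly schedules:
  perfectly attending patients test only on even program weeks, and each miss
  flips a patient's week parity, so the odd-week share of tests rises toward
  1/2 over the program (with damped oscillation once it saturates, since the
  share tracks the probability that a patient's accumulated miss count is
  odd).
- **Dropout** is per-occasion Bernoulli with no re-entry.

Group psychotherapy sessions are schedule context only; they do not alter the
testing schedule and are not simulated.

### Default generative parameters

The defaults describe a moderately adherent stimulant-use cohort:

| parameter | default | rationale |
|---|---|---|
| `n_patients` | 312 | completer-cohort scale |
| `p_positive_high` | 0.30 | per-test relapse probability early in treatment |
| `p_positive_low` | 0.15 | reduced relapse risk after stabilization |
| `p_missed` | 0.20 | per-occasion no-show probability |
| `p_dropout_per_occasion` | 0.005 | rare permanent dropout |

With per-test negative probability 0.7 and reset-on-positive, the expected
number of attended tests to accumulate 4 negatives is
`(0.7^-4 - 1)/0.3 ≈ 10.5`, i.e. ≈ 13 scheduled occasions after accounting for
misses — putting stabilization near the middle of a 52-week program, in line
with the roughly-six-months transition time such protocols report. The
realized mean is lower (~20 weeks under the defaults) because patients who
have not stabilized by week 52 are right-censored and because misses cost 1
week rather than 2.

Randomness uses one master `numpy` `SeedSequence`; each patient receives a
spawned substream, so cohorts are reproducible under a fixed seed and a
patient's trajectory is independent of cohort size and simulation order.

### What the simulator does and does not emulate

It reproduces the protocol's *structure*: schedule alternation, stabilization
and relapse resets, schedule drift from misses, dropout, and 52-week span.
It does not model covariate-dependent relapse risk, pharmacology,
within-patient autocorrelation of outcomes (outcomes are i.i.d. given phase),
re-arrest/re-entry dynamics, or calendar effects. Passing tests therefore
demonstrate that the pipeline is computationally correct and that protocol
mechanics alone generate the qualitative signatures (even/odd parity drift,
phase-dependent trends); they do not validate clinical effect sizes on real
cohorts.

## Time-series stage

The filled adjusted-score series is split at the phase cut-off week (default
27, so a 52-week program yields two 26-point segments: weeks 1–26 and 27–52)
and each segment is analysed separately:

1. **ADF test** (constant-only regression) for a unit root; rejection at
   α = 0.05 is reported as stationarity. The automatic lag rule is
   ⌊(T−1)^(1/3)⌋ with fixed lags (no information-criterion lag search), which
   keeps Monte-Carlo calibration runs deterministic and fast. Constant
   series raise a degenerate-series error.
2. **Order selection** (when orders are not fixed by the caller): `d` is the
   smallest value in 0..max_d whose d-times differenced series rejects a unit
   root; then an exhaustive grid over (p, q) is fitted and the AIC minimizer
   wins, ties broken by smaller p+q, then smaller p. If no `d` yields
   stationarity or no candidate converges, selection fails loudly rather than
   returning a default.
3. **ARIMA fit** by maximum likelihood (statsmodels state-space
   implementation, `maxiter=200`). Models with d = 0 include an intercept;
   differencing absorbs the level otherwise. Residuals exclude the first
   `d` diffuse values. Non-convergence raises an error carrying the
   optimizer diagnostics. Repeated fits on identical input are
   deterministic.
4. **Portmanteau diagnostics**: Box-Pierce `Q = T · Σ_{k≤m} ρ̂_k²` referred to
   χ²(m − n_params), with Ljung-Box available as an option (it dominates in
   small samples). The default lag count is `min(10, ⌊T/5⌋)`, raised to
   `n_params + 1` when the fitted order uses that many lag coefficients —
   otherwise the degrees of freedom would be non-positive and no p-value
   would exist (this arises for heavily parameterized orders such as (3,4,7)
   on a 26-point segment).
5. **Forecasting**: point forecasts with symmetric confidence intervals at
   the configured level (default 95%); interval widths are non-decreasing in
   horizon for integrated models.

A fit whose order leaves fewer than `3 × (p + q + 1)` effective points emits
a small-sample warning: such fits are returned, but their coefficients are
fragile. The orders (3,4,7)/(2,2,3) shipped in `examples/paper_orders.yaml`
are a documented example configuration of exactly this kind, not defaults:
d = 4 on a 26-point segment leaves 22 points for 10 lag coefficients. The
package's default is automatic AIC-grid selection with `max_p = max_q = 5`,
`max_d = 2`.

The per-segment report exposes the ADF result, the order and coefficients,
AIC/log-likelihood, the portmanteau statistic/df/p-value, and the forecasts;
it deliberately makes no single "fit for prediction" ruling, since coefficient
significance, portmanteau outcome, and stationarity are distinct questions.
α = 0.05 throughout.

## Numerical choices and degenerate inputs

- Adjusted scores are exact floating-point divisions of small integers;
  equality tests compare to 1e-12 absolute tolerance or exactly.
- Percentage rounding is half-away-from-zero via `decimal`, not banker's
  rounding.
- Constant segments, series shorter than the requested order/lags, zero
  denominators, probabilities outside [0, 1], and unknown result tokens all
  raise typed errors naming the offending input; analysis-stage errors are
  re-raised with the failing segment named.
- The pipeline is byte-deterministic under a fixed seed (one master
  `SeedSequence`; no wall-clock or hash-order dependence).

## Problem sizes used in validation

Validation runs use 1,000 random datasets (≤ 200 records each) for the
scoring oracle; 100 replicates × 3 coefficients of AR(1) length 500 for
parameter recovery; 1,000 white-noise series (T = 500, 10 lags) for
Box-Pierce size; 200 replicates each of white noise and random walks
(T = 500) for ADF power/size; and simulated cohorts of 312–800 patients for
protocol properties. These sizes give Monte-Carlo standard errors well below
the asserted margins.

## Known limitations

- The completer definition and the visit/urinalysis coupling are declared
  operationalizations; studies with separate attendance data should filter
  upstream.
- Order selection on 26-point segments is genuinely unstable; the AIC grid
  is a reasonable default, not a recovery guarantee at that length.
- The simulator's i.i.d.-given-phase outcome model understates real
  within-patient persistence of abstinence/relapse runs.
- Box-Pierce is the primary portmanteau statistic for fidelity to common
  practice in this literature; Ljung-Box is preferable statistically at
  these segment lengths and is one flag away.
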