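# keytype

Keystroke dynamics — the millisecond timing of press and release events
during everyday smartphone typing — is a candidate passive digital
biomarker for neurological disease. In multiple sclerosis (MS), typing
engages exactly the two domains that deteriorate most visibly between
clinic visits: upper-limb fine motor control and information processing
speed. `keytype` implements the full analysis chain for studies that pair
continuous keystroke logging with quarterly clinical testing: it derives
timing features from raw press/release logs, aggregates them into two
composite keystroke clusters around each clinical visit, and quantifies
their longitudinal association with the Nine-Hole Peg Test (NHPT, upper
limb; higher = worse) and the Symbol Digit Modalities Test (SDMT,
processing speed; higher = better) using random-intercept linear mixed
models. It is written for biostatisticians and digital-biomarker
researchers working with this kind of dense passive monitoring data.

## What it computes

**Features** (per typing session, all in seconds). For alphanumeric keys:
hold time HT = release − press of one key; press-press latency PPL and
release-release latency RRL between consecutive keys; flight time
FT = press(k+1) − release(k), which may be negative under rollover typing.
For backspace bursts: precorrection slowing (pause before the burst),
correction duration (first press to last release), postcorrection slowing
(pause after). For punctuation: the after-punctuation pause.

**Clusters.** Each feature is summarised per day as (mean + median)/2 of
its samples, on days with ≥ 50 keystroke events. Candidate features are
screened per concept group by pairwise correlation (r > 0.50) and by
equal contribution to the first principal component; the surviving
fine-motor score cluster FMSC = {PPL, RRL, FT} is averaged over ±14 days
around each visit, the cognition score cluster CSC = {preCS, postCS, APP}
over ±7 days.

**Models.** For outcome Y (NHPT or SDMT) and cluster score X at visit j
of subject i, the overall association is

    Y_ij = β₀ + β₁ X_ij + covariates + u_i + ε_ij ,   u_i ~ N(0, σ²_u)

and the hybrid model separates stable differences between people from
change within a person by person-mean centering, X̄_i = mean_j X_ij and
d_ij = X_ij − X̄_i:

    Y_ij = β₀ + β_between X̄_i + β_within d_ij + covariates + u_i + ε_ij .

The SDMT model adds a crossed random intercept over measurement occasion
to absorb practice effects. Fits are REML (via statsmodels MixedLM) with
Wald 95% CIs; the report includes explained variance relative to the
intercept-only model, the 10% change-in-estimate covariate rule, and
effects rescaled per 1 SD of the cluster.

Because studies of this kind rarely deposit raw keystroke data, the
package ships a synthetic cohort generator (`keytype.synthetic_cohort`)
with known ground truth — latent motor/cognitive latencies per subject
and visit, event streams, clinical scores linked through the hybrid
model, an SDMT practice effect, and mid-study visit missingness — so the
entire pipeline is testable end to end. See `docs/methods.md`.

## Worked example

```python
from keytype.synthetic_cohort import CohortConfig, simulate_cohort
from keytype.pipeline import PipelineParams, analyze

cohort = simulate_cohort(CohortConfig(n_subjects=40, events_per_day_mean=150,
                                      events_per_day_sd=60,
                                      typing_days="windows_only"), seed=7)
report = analyze(cohort.events, cohort.visits, PipelineParams(seed=7))
```

On this 40-subject cohort the data-driven screens recover the validated
memberships — FMSC = {PPL, RRL, FT}, CSC = {preCS, postCS, APP} — and the
hybrid models print:

```
nhpt: beta_between=17.25 (95% CI 10.92 to 23.57), beta_within=6.19 (95% CI 2.49 to 9.90)
  explained variance (hybrid): 38.3%  per-SD effects: between 2.43, within 0.87
sdmt: beta_between=-15.05 (95% CI -24.22 to -5.88), beta_within=1.51 (95% CI -4.94 to 7.96)
  explained variance (hybrid): 15.7%  per-SD effects: between -5.54, within 0.55
```

Read: a subject whose fine-motor cluster is 1 s slower than another's is
expected to be ~17 s slower on the NHPT (β_between); within a subject, a
1 s slowing between visits predicts ~6 s slowing (β_within). The
generating values here were 15.9 and 6.9 — both inside the CIs. Per 1 SD
of cluster latency the effects are a 2.4 s between-subject and 0.9 s
within-subject NHPT difference. The cohort is small, so the SDMT
within-subject effect (truth −0.4) is estimated with a wide CI.

The same pipeline runs from the shell on CSV inputs:

```bash
keytype simulate --seed 7 --out cohort/
keytype run --events cohort/events.csv --visits cohort/visits.csv --out report/
```

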