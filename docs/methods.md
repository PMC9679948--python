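# Methods

This note documents the modelling and numerical choices in `keytype`: the
feature and aggregation definitions, the mixed-model specification, the
synthetic cohort generator and its calibration, and what the test suite
does and does not establish about real data.

## Sessionization and feature definitions

Latencies are only meaningful inside a continuous bout of typing, so each
subject's event stream is split into sessions wherever the gap between
consecutive events exceeds `max_gap_s` (default 5 s, configurable). No
feature sample ever spans a session boundary; without this, a pause of
hours would enter the daily latency averages. Press and release events
are paired into key instances FIFO per `(session, key_token)`, which
equals stack order for non-overlapping instances of one key and remains
well defined under rollover. Unmatched presses are kept (press-based
latencies still use them); releases without a press, or preceding it, are
discarded and counted.

Definitions, for consecutive alphanumeric instances k, k+1 with no other
key class between them: HT(k) = release(k) − press(k);
PPL = press(k+1) − press(k); RRL = release(k+1) − release(k);
FT = press(k+1) − release(k). Negative FT (rollover) is retained —
clamping would bias the latency distributions the clusters average. A
maximal run of backspaces is one correction burst: preCS runs from the
release of the last preceding non-backspace key to the first backspace
press; CD spans first press to last release of the burst (a single
backspace's CD is its hold time); postCS runs from the last backspace
release to the next non-backspace press. APP is the punctuation release
to the next press of any class. Samples are dated to the UTC calendar day
of their first contributing event; negative values of the
nonnegative-by-definition features (possible only in pathological
streams) are discarded with a tally. Space and return are classified
`other` and therefore break PPL/RRL/FT adjacency; this keeps the timing
features purely alphanumeric, and the classification table is
configurable.

## Aggregation

The daily summary of a feature is (mean + median)/2 of the day's samples:
the two summaries are strongly collinear, and averaging them keeps a
single interpretable value on the seconds scale. Days with fewer than 50
raw press+release events are removed as insufficient data (the threshold
counts events, not feature samples). Daily values of a cluster's member
features are averaged (unweighted, over the members available that day)
into a daily cluster value, and daily cluster values within ±14 days
(FMSC) or ±7 days (CSC) of a visit — inclusive of the visit day — are
averaged into the visit's cluster score, with the number of contributing
days reported. This order (features → day, then days → window) weights
days equally; the alternative order (per-feature window means, then
features) is available behind `order="features_first"` for sensitivity
analysis, and differs only when member features have unequal day
coverage.

## Cluster screening

Candidates are grouped by concept: timing features {PPL, RRL, HT, FT}
for fine motor function, error/paralinguistic features
{preCS, CD, postCS, APP} for cognition. Within a group, membership
requires (a) every pairwise Pearson r strictly above 0.50 on the pooled
subject-day matrix (the largest such subset is retained, ties broken by
mean pairwise correlation), and (b) "equal contribution" to the first
principal component of the column-standardized candidate matrix,
operationalized as |loading| ≥ 0.7 × max |loading| with majority loading
sign. Both thresholds are configurable; "contributes equally" has no
standard formalisation, and the 0.7 relative-loading rule tolerates mild
imbalance while rejecting decoupled features. PCA is computed on the
correlation matrix (standardized columns) because the features have
heterogeneous scales; a covariance-matrix PCA would let the
largest-variance feature dominate. Memberships can be pinned by
configuration to the validated sets {PPL, RRL, FT} and
{preCS, postCS, APP}, which reproduces the published clusters on any
dataset and is what replicate studies use so that every replicate
estimates the same model.

## Mixed models

NHPT is the mean of four trial times, with visit averages above 40 s set
missing as outliers (counted and logged). The overall association model
is a linear mixed model with a subject random intercept, REML-estimated;
the hybrid model replaces the predictor with its person mean X̄_i
(computed over the modeled visits only) and the within-subject deviation
d_ij = X_ij − X̄_i, whose subject sums are zero by construction. Grand-mean
centering of X̄_i would change only the intercept and is omitted. The SDMT
model adds a crossed random intercept over measurement occasion
(M0…M12), implemented as a variance component: a per-day random
intercept is not supported by one observation per subject-day, and the
occasion effect captures exactly the occasion-common practice effect the
term exists to absorb; a fixed linear days-since-baseline term is the
sensitivity alternative. Covariates: age and sex for NHPT; age, sex and
education (unordered three-level factor) for SDMT. Missing rows are
dropped per observation (mixed models use all available rows). Wald 95%
CIs; optimizer falls back across lbfgs/bfgs/powell/nm/cg and raises on
genuine non-convergence. Explained variance is
100·(V₀ − V)/V₀ where V is the sum of all random-effect variances plus
the residual variance and V₀ the same total in the intercept-only model;
negative values are allowed with a warning. Covariates are flagged
relevant when the cluster coefficient changes by ≥ 10% upon adjustment.
Rounding happens only at the reporting layer (per-SD effects: one
decimal, two when |value| < 1).

## Synthetic cohort

The generator emulates a one-year observational MS cohort: 102 subjects,
visits at days 0/91/182/273/365, clinical-visit missingness
(0, 9, 25, 43, 13)% per occasion reflecting mid-study disruption, daily
typing adherence ~0.91 (Beta-distributed across subjects), and log-normal
per-day event counts (mean 250). Latent states are a per-subject
fine-motor latency (log-normal across subjects, mean 0.43 s, SD 0.16 s)
and cognitive latency (mean 0.94 s, SD 0.40 s plus an education shift
that creates genuine confounding for the SDMT model), with independent
per-visit Gaussian deviations (within-subject SDs 0.06 s and 0.12 s).
The cohort gives no within-subject variance decomposition to copy, so
the within SDs are stated assumptions sized so that within-subject
effects are estimable but clearly smaller than between-subject spread;
they are config fields. Clinical scores follow the hybrid linkage
exactly — NHPT: 14 + 15.9·m̄_i + 6.9·(m_ij − m̄_i) + subject intercept
(SD 2.5) + residual (SD 1.2), emitted as four trials; SDMT:
65 − 11.2·c̄_i − 0.4·(c_ij − c̄_i) − 0.15·(age − 46.4) + education effects
+ 1.5·occasion + occasion noise + subject intercept (SD 9) + residual
(SD 4), rounded to integer points. Scores are generated *after* visit
missingness, with person means over the retained visits, so the
configured coefficients coincide exactly with the hybrid-model estimand
under missingness.

### Calibration of the event streams

Per-sample latencies are log-normal (positive support, right skew, as
typing latencies are) with a *constant coefficient of variation*. For a
log-normal with mean M and CV c, the median is M/√(1+c²), so the daily
summary (mean+median)/2 has expectation κ(c)·M with
κ = (1 + 1/√(1+c²))/2 — linear in M. The generator inverts this: gaps
are drawn with mean (m_day + h_day/3)/κ, where h_day is the day's hold
time, so that the expected extracted daily FMSC value — the mean of the
PPL, RRL and FT daily summaries, in which hold time enters FT — equals
the latent m_day exactly; cognitive pauses use mean c_day/κ. This makes
the generator's coefficients the true estimands of the full pipeline,
which is what allows unbiased end-to-end parameter recovery. Two
constraints follow: hold-time noise must be small relative to gap
variability (its effect on the RRL/FT medians is second order), and the
sample CVs (0.28 motor, 0.25 cognitive) must keep the latency tails
below the 5 s session gap for all plausible latents — pauses beyond the
gap are truncated by sessionization, which would otherwise attenuate
high-latency subjects specifically. HT and CD carry no subject-level
disease signal (hold times vary by subject and day independently), which
is what makes the correlation/PCA screens drop them, as intended.

### What the generator does not emulate

No linguistic structure or autocorrelated typing rhythm; no relapse
dynamics or time trends in the latents (within-subject variation is pure
per-visit deviation; config fields exist for trends); sequential typing
only by default (a rollover probability flag exercises negative flight
times); independent per-visit clinical missingness rather than the mixed
independent/dropout pattern of a real pandemic-era study (a monotone
dropout hazard is available). Passing tests therefore certify the
pipeline's correctness and the estimator's statistical behaviour under a
faithful data-generating model — not robustness to autocorrelation,
informative missingness, or device heterogeneity in real cohorts.

## Problem sizes in the test suite

Pipeline-level tests run on a 24-subject cohort with ~120 events per
active day, with typing restricted to the visit windows (days outside
the ±14-day windows contribute nothing to window scores). The parameter
recovery study uses 200 replicates of the full 102-subject cohort at 150
events per day — reduced relative to real phone usage, chosen so the
added measurement attenuation stays an order of magnitude below the
Monte-Carlo resolution of the study — and asserts that each recovered
hybrid coefficient's mean sits within 2 Monte-Carlo SEs of its
generating value and that nominal 95% CIs cover the truth in ≥ 90% of
replicates. The acceptance script reports means over 40 replicates at
the same conditions.

## Known limitations

- The correlation screen's largest-qualifying-subset search is
  exhaustive over the 4-feature concept groups; it is not meant for
  large candidate sets.
- Education enters the SDMT model as an unordered factor; with very
  small cohorts a level can be absent and the corresponding contrast is
  then dropped by design-matrix construction.
- The occasion variance component treats occasions as exchangeable;
  a strongly nonlinear practice trajectory is absorbed only on average.
- Timezone handling is UTC throughout; per-subject local-time day
  boundaries would require a timezone column not currently modelled.
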