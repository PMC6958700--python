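# Methods

This note records the models, operational definitions and design choices
behind `bestdiary`, in the spirit of a statistical methods appendix.

## The instrument

Six ordinal items: breathlessness, fatigue, sputum volume and cough score
0–4; sputum colour 0–5 (5 = blood stained, the only haemoptysis encoding);
cold/flu symptoms take values {0, 1, 2, 5} — levels 3 and 4 are not defined
on the card and are rejected by validation (an opt-in lenient mode maps
them to 2 with a warning). Per-item maxima sum to 26. Scores are integers;
dates are ISO-8601 calendar dates at daily resolution. Sputum volume
categories use lower-inclusive boundaries (exactly 5 ml is already
"teaspoon to an egg-cup"); the published equivalences give only the
landmark volumes, so the boundary assignment is this package's choice.

## Baselines and event definitions

* **Baseline** *B*: median of observed daily totals over the 7 calendar
  days preceding the reference day, requiring ≥ 4 observed days; a sparse
  window slides back day-by-day up to 21 days, and references within the
  first study week use the first 7 diary days. Estimates that never reach
  4 observations are flagged unusable and excluded downstream.
* **Reported (treated) events** are anchored on the recorded
  antibiotic-start day. Onset is the earliest day within a 14-day lookback
  (the standard antibiotic course length) that starts a run of totals
  strictly above *B* persisting to treatment; the event ends on the first
  post-treatment day with total ≤ *B* (ties resolve to the earlier day),
  capped at 42 days (flagged truncated). Duration is measured from
  treatment start, matching how recovery is reported clinically; the
  prodrome (onset time) is treatment minus onset.
* **Unreported events**: a maximal run of ≥ 2 consecutive *observed*
  calendar days with totals ≥ *B* + 3, where *B* is re-estimated at the
  run's first day. The 48-hour requirement is operationalised as two
  consecutive observed days; a missing day breaks a run (conservative — no
  interpolation). The event ends on the first later day with total ≤ *B*;
  events closer than 7 days merge into one (refractory window). Days from
  7 days before a reported event's onset through its end are censored.
  Duration is measured from the first qualifying day (the rule has no
  treatment anchor).
* **Worsened domains**: an item counts as worsened when it exceeds its own
  baseline-window median on ≥ 2 consecutive days within the event; ≥ 3
  worsened domains meets the consensus exacerbation definition.
* **Stable days** exclude a 7-day buffer before each event onset through
  the event end; within-subject SD and CV (100·SD/mean, sample SD, n−1)
  are computed over stable days only, requiring ≥ 8 of them.

All thresholds (3 points, 2 days, 7-day refractory, 4-of-7 baseline
observations, 14-day lookback, 42-day cap, buffers) are exposed as
function/config parameters with these defaults.

## Synthetic cohort model

Each patient *i* has a latent baseline *B*ᵢ ~ N(7.1, 2.2²), clipped to
[1, 16]. The daily latent total is

  *S*ᵢₜ = *B*ᵢ + Σ event offsets + εᵢₜ,  εᵢₜ ~ N(0, σᵢ²),

rounded half-up and clamped to [0, 26], then decomposed into six valid item
scores (below). Days are dropped independently with probability 0.03
(roughly the adherence seen in diary studies where most patients complete
≥ 3 months).

**Noise scale.** σᵢ = CVᵢ·*B*ᵢ/100 with CVᵢ = 100·σ₀/*B*ᵢ capped at 97.8%,
σ₀ = 1.15 points. Two observations motivate this: (i) on a 26-point integer
scale a stable patient's day-to-day movement is on the order of one point,
and 1.15 is the value implied by the low end of the published CV range
(16.1%) at the cohort mean baseline 7.1; (ii) the published unreported
exacerbation yield (~1 rule-triggered event per patient per 6 months, mean
duration 10 d) is only consistent with day-to-day noise that rarely
sustains 3-point excursions for 48 h — multi-point daily SDs would trip the
rule weekly. The wide published CV *range* is therefore treated as a
denominator effect: low-baseline patients have high CVs, not intrinsically
wilder symptoms. The generator does not force every patient's CV above the
published minimum (that minimum is an order statistic of a 19-patient
cohort, not a floor).

**Event arrivals** are Poisson per kind (defaults 1.5 reported and 1.2
unreported per patient-year), placed uniformly with ≥ 14 clear days between
event spans; crowded draws are resampled a bounded number of times before
erroring with advice to lengthen follow-up.

**Reported event template** (per event: lag L ~ N(4.8, 3.5) days clipped to
[1, 10]; peak change P ~ N(9.1, 2.5) clipped to the published range
[5, 14]; duration D ~ N(15.3, 5.7) clipped to the published range
[5, 28]): a convex rise over the prodrome reaching P on the treatment day,
a sharp drop (to 0.65·P) the day after, then a decay through a shallow
tail that stays ~2 points above baseline until recovery completes at day
D, where the offset returns to zero. The sharp peak keeps the
maximum-over-window statistic close to the nominal peak under noise; the
elevated tail makes "first day back at baseline" land at the nominal
duration rather than days early. With zero noise the measured onset, peak,
and duration reproduce the planted values exactly (after rounding). The
linear-ish prodrome yields a mean pre-treatment rise of ~3.6–4.0 points,
consistent with the published +4 onset change.

**Unreported event template** (change C ~ N(4.7, 1.5) clipped to the
published [3, 8]; duration D ~ N(10, 3.8) clipped to [4, 20]): starts at
+3 (the detection threshold), rises quadratically to C at ~D/3, decays
steeply, then lingers ~2.2 points above baseline before returning to zero
at day D — so the qualifying run begins on day one of the event and the
measured duration is exact in the noise-free limit.

**Item decomposition.** The integer total is allocated across the six item
ladders greedily in a fixed order (cough and sputum first, systemic
symptoms last), moving each item at most two ladder steps per day from its
previous value (temporal smoothness), with cold/flu leaving zero only while
an event is active and decaying afterwards. When no smooth allocation can
reach the target (only possible at extreme totals) the step and cold/flu
constraints are relaxed so the allocated sum always equals the clamped
rounded total.

**Anchors.** A one-factor Gaussian copula: each anchor loads on the
baseline factor with its configured correlation (CAT 0.61, SGRQ total 0.61,
SGRQ symptom 0.52, LCQ −0.52, 6MWT −0.46), marginals clipped to instrument
ranges (CAT [0, 40], SGRQ [0, 100], LCQ [3, 21], 6MWT ≥ 0). CAT
(19.1, 6.1), SGRQ (41.5, 17.0) and 6MWT (439, 104) marginals are
published; LCQ 14 (SD 3) and SGRQ-symptom 55 (SD 18) are assumptions, noted
as such. The one-factor structure is positive semi-definite by
construction; the assembled matrix is still eigenvalue-checked so custom
configurations fail before sampling. `config_with_planted_anchor_slope`
adjusts an anchor's SD to plant a chosen regression slope
(slope = r·σ_BEST/σ_anchor) for calibration experiments.

**Seeding.** Patient *i*'s stream is `default_rng([seed, i])`: cohorts are
reproducible and patients order-independent.

## Psychometrics

Convergent validity is ordinary least squares of the baseline diary score
on each anchor (scipy's `linregress`), Pearson r, and the two-sided t-test
p-value with n − 2 df; missing values are dropped pairwise, zero-variance
inputs are flagged not-computable, p-values are floored at 10⁻¹⁵ and
reported raw (no multiplicity correction). The anchor-based MCID converts
through the slope of that regression (diary regressed on anchor), the
direction that reproduces the published 3.5 / 4.0 / 4.95-point
conversions. The half-SD method halves the sample SD (n − 1) of
per-patient baseline scores — "scores for all participants" is read as
baseline scores, switchable to other summaries by passing a different
vector. The onset method averages (pre-treatment mean − baseline) over
reported events.

Cutoff performance uses episodes as the unit of analysis: sensitivity is
the share of treated events with peak change ≥ c; specificity the share of
stable 14-day windows (non-overlapping, change = max of the second week
minus the leading week's median) with change < c. The unit of analysis is
a design choice exposed in the report.

## Numerical choices and degenerate inputs

Half-up rounding (not banker's) keeps the latent-to-integer map monotone
and deterministic. Medians of even-sized windows may be half-integers;
comparisons use ≤/≥ as stated above, ties resolving toward the earlier
day. Flat pre-treatment series yield onset time 0 and are flagged
atypical; events that never return to baseline are truncated at the cap
and excluded from duration summaries for reported events. Diaries shorter
than 14 days cannot support unreported-event detection and are rejected.

## What the generator does and does not emulate

Emulated: published baseline level and spread, prodrome/peak/recovery
kinetics of treated events, magnitude and duration of unreported events,
anchor correlations, the day-to-day variability range, missing diary days.
Not emulated: item-level natural history beyond smooth allocation,
autocorrelated symptom drift, hospitalised severe exacerbations, treatment
response heterogeneity, or informative missingness (dropout after
exacerbations). Passing recovery tests on this generator therefore shows
the pipeline measures what the definitions say on data of this structure —
not that real diaries satisfy the Gaussian-noise assumption.

A consequence worth stating plainly: on noisy cohorts the *detected*
unreported-event statistics are not the planted nominals. The rule also
admits occasional two-day noise runs (short, ~+3.5–4 point events), and
misses ~a third of the mildest planted events (change < 4), so the
detected mean change runs ~0.2–0.4 points above and the detected mean
duration ~1–1.5 days below the planted 4.7 / 10 d, with the balance
depending on the noise seed. The same selection effects operate in any
real application of the rule; the package reports what the rule finds, not
the latent truth.

## Problem sizes

Recovery experiments use 500 patients × 180 days for event kinetics (the
published design is ~21 patients × 6 months; 500 gives stable means while
keeping runs to seconds) and 1000 patients for correlation/slope recovery.
The brute-force detector-equivalence suite uses 1000 random diaries of
14–60 days.

## Known limitations

Exact reproduction of the published cohort's descriptive statistics is not
possible (no deposited data); the package reproduces them as
parameter-recovery experiments on the calibrated generator. The published
LCQ p-value appears twice with conflicting values (0.0015 vs 0.015); the
package computes its own p-values and takes no side. Event rates in the
default configuration (1.5/1.2 per patient-year) are deliberately modest;
users matching a specific cohort should set them from observed counts.
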