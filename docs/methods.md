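# Methods

## The alerting algorithm

Each serum creatinine (SCr) result, in μmol/L on a calendar date, is
compared against two baselines drawn from the same patient's history:

* **short window** — the *lowest* SCr in the 0–7 days preceding the index
  result;
* **long window** — the *median* SCr in the 8–365 days preceding it
  (even counts take the mean of the two central values; the common
  convention, since the source algorithm does not state one).

A reference value ratio (RVR) is the index value divided by a baseline.
The higher of the two available RVRs drives staging:

| stage | criterion |
|---|---|
| AKI 1 (low RVR) | higher RVR < 1.5 **and** SCr rise > 26 μmol/L within the preceding 48 h |
| AKI 1 (high RVR) | 1.5 ≤ higher RVR < 2 |
| AKI 2 | 2 ≤ higher RVR < 3 |
| AKI 3 | higher RVR ≥ 3, **or** higher RVR ≥ 1.5 and SCr ≥ 354 μmol/L |

Ratio thresholds are inclusive on their lower bound and exclusive above;
the rise criterion is strict. When only one window holds data, the higher
RVR is that window's ratio. A result with no prior inside any window can
never alert.

### Date granularity

Laboratory timestamps are unreliable in routinely collected data, so the
package operates on whole days with an explicit integer `seq` ordering
results within one patient-day. The 48-h rise rule is implemented as a
**two-day window** (`rise_window_days`, configurable), which can slightly
overestimate incidence; a timestamp-resolution mode is deliberately out of
scope. All windows include both endpoints in whole days; "0 days" means
earlier results on the index date itself, which are eligible for the short
and rise windows but never the long one. Duplicate `(date, seq)` keys are
rejected rather than averaged so evaluation stays reproducible.

### Observation vs look-back

Alerts are only emitted for results inside the configured observation
interval (closed on both ends); earlier results serve purely as baselines,
mirroring a design with a 2014 observation year and a 2013 look-back. No
re-alert suppression is applied: the source algorithm is designed to alert
repeatedly through an episode, so one episode commonly yields a run of
alerts (grouping alerts into episodes is out of scope).

### Data quality

Values outside an open plausibility band of (5, 3000) μmol/L — unit
confusion, sign errors, zero placeholders — are quarantined before
evaluation and counted in the quality log; the bounds are configurable.

## Cohort selection

Practice-level biochemical testing rates are computed as tests per
registered patient per 365-day year over the study period (the scale is
irrelevant to fencing, which is shift/scale-equivariant). A designated
*anchor* subset of practices — in the original setting, those in the
laboratory cities, generalised here to a boolean flag — defines the
reference distribution. The inclusion threshold is the Tukey lower fence,
Q1 − 1.5 × IQR with linearly interpolated quartiles, and every practice
(anchors included) below it is excluded; a rate exactly on the fence is
retained, since only a strict shortfall counts as "falling below".

Patients are retained when aged ≥ 18 in whole years (from birth year) at
the observation start and continuously registered with a surviving
practice for the entire study period. Every excluded patient carries
exactly one reason, assigned in the fixed order age → registration →
practice.

## Alert classification

Admission spells are normalised first: open discharges are closed at the
study end and overlapping or same-day-abutting spells merged. Typing then
follows a strict precedence:

1. test date equals an admission date → **CA identified on admission**
   (the injury originated beforehand, so it is community-acquired);
2. admission day < test date ≤ discharge day → **HA** (discharge-day
   tests are in-spell);
3. otherwise, an admission within the next 7 days (inclusive; earliest
   such admission linked) → **CA admitted within 7 days**;
4. otherwise **CA not admitted**.

A consequence worth knowing: in-spell re-tests after a community-triggered
admission are typed HA, which matches the observation that repeated
inpatient biochemistry inflates HA alert counts relative to episodes.

The first-alert cross-section takes each patient's chronologically first
alert (same-day ties by `seq`); its row count always equals the number of
distinct alerted patients.

## Synthetic data generator

The generator emulates the *structure* of a linked regional EHR, not any
real population's absolute counts (the original source database is not
public). Per patient it draws:

* an age band (nine bands, 18–24 … 95+) with weights matching a regional
  adult age mix, and gender with a 48.7% male share;
* a stable baseline SCr, lognormal with gender-specific medians of
  80 (male) / 65 (female) μmol/L and log-scale 0.18;
* community test dates as a Poisson process whose intensity rises with age
  band — 0.23 up to 1.20 tests/person-year at 85–94, dipping to 0.93 at
  95+ — calibrated so the share of patients with ≥ 2 results over the
  two-year period climbs from roughly 8% in young adults to roughly
  two-thirds in the oldest admitted bands, reproducing the published
  age gradient qualitatively;
* repeat-test noise, multiplicative lognormal with CV 0.07 (typical
  combined assay plus biological variability); values are rounded to
  whole μmol/L as laboratories report them;
* AKI episodes at 0.008 episodes/person-year of observation — chosen to
  land near the reported ~0.8% of a cohort alerting in a year — each a
  linear ramp of the baseline multiplier up to a peak ratio over 1–3 days
  and back over 5–14 days. Peak ratios are drawn from a severity mixture
  over {1.2–1.5, 1.5–2, 2–3, ≥3} with weights 0.25/0.40/0.22/0.13 (no
  published stage breakdown exists; this is a one-off plausibility
  choice). 35% of episodes are hospital-onset (an admission spell starts
  at onset with near-daily in-spell testing); community episodes get
  sparse draws through the episode, a guaranteed primary-care baseline
  test 30–180 days before onset, and are admitted with probability 0.55
  after a 0–7-day lag weighted toward short lags;
* 15% of practices are simulated as deficient testers (rate × 0.1) to
  exercise the fence, and 5% of patients have incomplete registration to
  exercise eligibility. Deficient practices are drawn from non-anchors
  only: anchors model the city practices whose regular laboratory use
  defines the reference distribution, so simulating them as deficient
  would contradict what the anchor flag means.

Episodes are injected only into cohort-eligible patients so that
ground-truth recovery is well defined. Every episode is recorded in
`truth.csv` with an `expected_alertable` flag established by an
**independent brute-force evaluation** of the actually written test dates
and values (plain loops inside the generator, sharing no code with the
detection module): the flag is true exactly when some in-episode,
in-observation test satisfies the staging criteria given the data as
sampled. Episodes whose tests land short of the thresholds — a mild peak
between rounding and noise, or no usable baseline — are labelled not
alertable rather than being nudged to detectability.

Randomness uses one explicit seed with deterministic per-patient
substreams (`SeedSequence(seed, spawn_key=(1, i))`), so identical configs
give byte-identical files and enlarging the population never perturbs
existing patients.

What the generator does **not** model: aetiology or pharmacology of AKI,
coded diagnoses, mortality, seasonal testing patterns, inter-practice
case-mix differences beyond the rate multiplier, and timestamp-level
ordering. Passing tests on synthetic data therefore demonstrate the
pipeline's correctness and invariances, not the real-world performance of
the alerting criteria.

## Reports

The demographic report gives cohort / gender / age-band rows with the
percentage of patients holding 0–1 vs 2+ SCr results, alerted-patient
counts and alert counts; percentages are row-relative. Result availability
is counted over the whole study period by default (look-back results
contribute to detectability), switchable to the observation year via
`scr_count_window` — the underlying definition is ambiguous in routine
practice, so it is an explicit flag rather than a buried choice. The
alert-type report gives first-alert and all-alert counts by the four CA/HA
types with column-relative percentages and a CA subtotal. All percentages
are stored at full precision and rounded to one decimal only when
rendered, so rounding footnotes never contaminate stored outputs.

## Numerical and scale choices

* Quartiles: NumPy's linear interpolation; the fence identity
  (Q1 − fence)/IQR = 1.5 holds under any convention and is tested
  directly.
* Testing-rate denominator: 365-day years; leap-day drift is irrelevant
  at fence scale.
* Exhaustive staging tests probe ±1e-9 neighbourhoods of every threshold
  (1.5, 2, 3, 354, 26) to pin the inequalities' strictness.
* Test-suite problem sizes: oracle equivalence uses 1,000 random series of
  up to 50 results; recovery and false-alert checks use 10,000 synthetic
  patients; the demographic-gradient check uses 6,000 patients with
  uniform band weights and strictly increasing band rates; the fence
  check uses 20 seeds of 1,000 patients. These sizes give stable
  pass/fail behaviour at desk scale.
* Degenerate inputs: empty cohorts produce empty (zero-count) reports
  with a warning; a practice table with fewer than four anchors makes the
  fence undefined and is an error; zero-list-size practices are dropped
  from the rate table with a warning.

## Known limitations

* No episode-level grouping of serialized alerts; counts are alert counts.
* The two-day rise proxy can overestimate incidence relative to true 48-h
  logic.
* Age is computed from birth year only, so eligibility at the 18-year
  boundary is accurate to the calendar year.
* The generator's admission model is intentionally simple (single lag,
  uniform length of stay) — sufficient for classification structure, not
  for modelling utilisation.
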