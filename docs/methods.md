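# Methods

## The problem

Primary-care electronic medical records (EMRs) are increasingly reused for
research, surveillance and quality measurement, but a field that a
physician never fills in cannot support any of those uses. `emrqual`
operationalises a pragmatic completeness assessment for family-practice
EMR extracts: it measures, per physician, what fraction of patients have
each core field populated, tracks how those fractions evolve with
physician and patient time on the EMR, and flags physicians whose rates
fall below fixed or peer-derived benchmarks.

## Measures

The unit of documented care is the **documented visit**: an office-visit
billing and a progress note for the same patient and physician on the same
calendar day. From it derive:

- **Initiation date** — the earliest day on which a physician's record
  shows at least 10 same-day bill/note pairs (pairs, not distinct
  patients). This marks the operational start of EMR use; a cumulative
  reading (running total of pairs reaching 10) is available as a mode
  flag, and the threshold is configurable.
- **Active patient** — a rostered patient with at least one documented
  visit with their physician inside the one-year window under study.
- **Patient first-EMR date** — the patient's earliest documented visit
  with any physician; patients without one cannot be assigned a tenure.

Field completeness for one physician over a one-year window is
numerator/denominator, where the denominator is the set of active patients
(event fields) or all rostered patients (CPP fields), and a patient enters
the numerator when:

| field | predicate |
| --- | --- |
| visit_documentation | every in-window office-visit billing has a same-day note |
| blood_pressure / weight | ≥ 1 structured measurement of that kind in-window |
| lab_test | ≥ 1 *structured* (electronic-feed) lab result in-window; scanned reports never count |
| prescription / referral / consult_letter | ≥ 1 entry in-window |
| cpp_* | the snapshot category is populated; medical history = past health **or** problem list, since clinicians use the two fields interchangeably |

Visit documentation has two defensible readings. The canonical measure
here is per-patient (all of a patient's billed office visits documented),
which fits the "share of active patients having the measure" framing of
every other field; a per-visit rate (documented visit-days / billed
visit-days) is computed and emitted alongside under
`visit_documentation_per_visit`, because it is the more direct description
of encounter-level documentation behaviour.

A rate with a zero denominator is *undefined*, never 0; undefined rates
are excluded from aggregation and counted in the run metadata.

## Time on EMR

All windows are half-open `[start, end)` at day granularity, and "one
year" is an anniversary year (same month/day next year; a Feb 29 start
rolls forward to Mar 1). Anniversary windows tile a multi-year record
exactly and do not drift the way 365-day windows do.

- **Physician time**: year *k* since initiation is
  `[initiation + (k−1) years, initiation + k years)`. A physician
  contributes to year *k* only when that window ends on or before the
  extraction date (a full year of data), so eligible sets shrink as *k*
  grows and are always nested.
- **Patient time (tenure)**: time from the first-EMR date to extraction,
  binned `<1`, `1-2`, `2-3`, `>3` years as half-open intervals
  `[0,1), [1,2), [2,3), [3,∞)` — exactly 3 years falls in `>3`, so the
  four printed labels partition the binned population. Tenure analyses
  evaluate the final year before extraction; event-field denominators are
  confined to active patients, CPP fields use all binned rostered
  patients.

## Aggregation

The physician is the unit of analysis: stratum summaries are unweighted
means of physician-level rates with a normal-approximation 95% CI,
`mean ± 1.96·sd/√n` (sample sd, zero width at n = 1), clamped to [0, 1].
Patient-level binomial CIs would ignore clustering within physicians and
be anti-conservative; a panel-size-weighted mean (with an effective-n CI)
is available behind a flag for users who want a patient-centric summary.
Calibration is checked empirically: across 1000 simulated cohorts of 50
physician rates the CI covers the true mean ~94–95% of the time.

## Benchmarks

- Fixed 95%: visit documentation and allergies (most safety-critical).
- Fixed 80%: the remaining practice-style-independent fields
  (blood pressure, weight, and the other CPP categories).
- Mean − 1 SD: the practice-style-dependent fields (labs, prescriptions,
  referrals, consultation letters), where a low rate may be legitimate
  style and only outliers suggest the physician is doing the task on
  paper.

Conventions, each an explicit and logged option: sample (n−1) standard
deviation; strict inequality, so a physician exactly at a benchmark meets
it; the mean − 1 SD threshold is computed within the stratum being
reported, not pooled across strata; thresholds floor at 0. Frequency
distributions of physician rates (5-point bins, top bin closed) accompany
every benchmark so outliers can be seen, not just counted.

## Synthetic EMR generator

Real rostered-practice extracts cannot be shared, so the generator
produces structurally faithful datasets with known ground truth. Year
probabilities follow `p(k) = clamp(p0 + jump·[k≥2] + slope·(k−1), 0,
ceiling)` — a distinguished year-1→2 jump because adoption data show the
steepest gains between the first and second year of use.

Per physician: a start date within the configured spread, a go-live burst
of ≥ 10 same-day bill/note pairs (the initiation-detection target), and a
Poisson-sized panel (mean 50). Per patient: a start year uniform over the
physician's years on EMR, office visits as Poisson counts per year (mean
4) each billed and noted with the year's documentation probability, one
at-least-one Bernoulli draw per field per patient-year (matching the
granularity at which the measures are evaluated), occasional non-office
billings and scanned labs as negative controls, and a CPP snapshot drawn
once with tenure-bin-dependent category probabilities. All events are
dated strictly before the extraction date so half-open windows never drop
boundary events. Randomness is a hierarchical physician → patient stream
off one seed: adding a physician never perturbs another's draws, and a
fixed seed reproduces the dataset byte for byte.

Default schedules echo the completeness levels reported for Ontario
family practices: visit documentation 0.69 rising to a 0.88 ceiling,
prescriptions the most complete event field (0.70 base), labs and
consultation letters flat over physician time, weight recording poorest,
and family history / risk factors the weakest CPP categories.

What the generator does **not** emulate: visit seasonality and
clustering, roster churn and transfers, correlated field behaviour within
a patient or physician (draws are independent given the schedule),
free-text content, and measurement values. Passing recovery tests
therefore demonstrates that the pipeline measures what the data contain —
not that real EMR data meet any particular completeness level.

## Validation problem sizes

Oracle-equivalence checks run the engine against brute-force enumeration
on 200 random fixtures of up to 10³ events. Parameter recovery uses 100
replicates of 40 physicians × ~50 patients × 5 years with a 0.2
year-1→2 jump on the prescription field: the scheduled probability falls
inside the stratum CI in ≥ 90% of replicates and the jump is recovered as
a positive difference in all of them. CI calibration uses 1000 replicates
of 50 physician rates. These sizes give stable statistics while keeping
the full suite fast enough to run routinely.

## Known limitations

- Rostering is treated as current-at-extraction with a single active
  roster per patient; historical de-rostering is out of scope.
- The CPP snapshot is untimestamped, so CPP completeness cannot be
  localised in time — only cross-sectioned by patient tenure.
- Referral and consult entries are counted by presence alone; no linkage
  to a specialist identity is attempted.
- Billing records carry only an office-visit flag, not a fee-code
  taxonomy.
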