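# Methods

## The Average Medication Score

The AMS condenses a patient's medication use between two follow-up
visits into one number. Each formulary drug has a *reference unit dose*
`u` and a *unit score* `s` (points per unit dose), ranked by
pharmacological class and dose–effect relationship: irrigation fluids
0.1, topical/inhaled corticosteroids 0.5–1, symptomatic relief 2,
leukotriene antagonists 2.5–3.5, oral corticosteroids 20–25, up to
intravenous corticosteroids (150–250) and adrenaline (1000). A course
with dose-per-administration `d`, frequency `f` per day and `p` days of
use inside a window of `F` follow-up days contributes

    (d / u) · f · p · s / F

and the patient total is the sum over courses.

Three readings of this formula were genuinely open and are fixed here as
package conventions:

- **Operator grouping.** The product is divided by the follow-up days as
  a whole: `((d/u)·f·p·s)/F`. This is the only grouping that is
  dimensionless in dose, increases with dose, frequency and days of use,
  and makes persistent daily use window-length invariant (a drug taken
  at one unit dose daily all window contributes exactly `f·s`, whether
  the follow-up is monthly or quarterly).
- **"Total dose"** is read as the dose per administration; the total
  over the window is then `d·f·p`. Reading it as an already-accumulated
  total would double-count frequency and period.
- **Window semantics.** Windows are half-open `[start, end)` and a
  course's period is clipped to its overlap with the window, so
  timelines built from consecutive visits never double-count a day, and
  splitting a course into contiguous sub-courses leaves scores
  unchanged. Follow-up days are calendar days between visits, not a
  nominal cycle length.

### Unit-score policy

Scores scale linearly with dose from the reference point
(`score(d) = s·d/u`): the budesonide anchor pair 80 μg → 0.5 and
100 μg → 0.625 fixes the interpolation rule. Fixed-dose combinations
are scored additively over dose-scaled components, which reproduces all
published combination values (Symbicort 80/4.5 → 1.5, 160/4.5 → 2,
320/9 → 4, Seretide 500/50 → 6). One policy row pins Seretide 250/50 at
2 points although component arithmetic gives 4; the fixture stores both
(`override_unit_score=2`), the additive convention is the default, and
the override is available per entry for deployments that want the
literal row values.

Ranged class scores ("2.5–3.5", "20–25") must become one number per
drug: values pinned by published worked examples are used where they
exist (methylprednisolone 4 mg tablet → 25, prednisone 5 mg → 20), and
documented midpoints otherwise (montelukast 10 mg → 3.0). Mass doses
are canonicalized to micrograms; counted units (tablets, puffs,
applications) form a single separate family, and converting between
mass and counts is an error.

The packaged fixture holds 112 drugs (24 rhinitis, 51 asthma,
37 dermatitis). Only a fraction are individually dosed in the published
policy; the remainder are plausibly named entries carrying their policy
row's class-level score, flagged `placeholder=True` so downstream users
can exclude them. A second fixture, the standard-element registry,
lists the platform's 533 data elements (210 common + 323 specific) by
module; element names beyond those published are systematic
placeholders that preserve countability without inventing semantics.

### Dermatitis variant

For atopic dermatitis the score of dermatitis-category drugs is
multiplied by the lesion area as a percentage of body surface, measured
in patient palms (1 palm ≈ 1%, capped at 100). The percent number is
the multiplier and 1% is the identity — the only reading under which
the "standard" lesion area leaves the base formula unchanged. The area
applied to a window is the latest one recorded at a visit inside that
window; if none is recorded the coefficient is 1. Whether systemic
drugs should also carry the coefficient is unspecified upstream; it is
applied to dermatitis-category courses only.

## Record schema and validation

Records use ISO-8601 dates on disk and calendar dates in memory. Ages
are completed years at a reference date (default: enrolment), matching
integer-valued published medians. Parsing (types, enum membership) and
clinical validation (birth before enrolment, non-decreasing cumulative
injection dose within a vial series, lesion area only with an AD
diagnosis, FEV1 ≤ FVC) are deliberately separated: imperfect exports
load fine and validation returns a report rather than raising, so a
registry manager can triage rather than crash. CSV interchange is
UTF-8, comma-separated, RFC-4180 quoted, with nested lists as
JSON-encoded cells; this keeps round-trips byte-exact.

## Cohort summaries

Percentages are rounded half-up at one decimal, the convention that
reproduces every recomputable published cell (62.4% male of
14,871/23,847, 40.9% rhinitis-only of 9,753/23,847, 59.5% aged 6–17,
...); rounded partitions therefore need not total exactly 100.
Quartiles use linear interpolation on order statistics (the common
"type 7" convention) — the source states none, and a fixed published
convention beats an unstated one. Diagnosis sets map onto the seven
published combination classes (AR, AS, AR+AS, AS+AD, AR+AD, AR+AS+AD,
other); AD-only falls into "other". Ages below 3 (absent from the
published bands) are counted in the 3–5 band so partitions stay
exhaustive. Nonattendance is flagged when the gap since the last
injection strictly exceeds interval + grace; injection intervals per
phase are configuration (defaults: weekly escalation for the first 15
injections, four-weekly maintenance) because no intervals are published
and clinics differ.

## Synthetic cohort generator

The generator emulates the *marginal* structure of the 23,847-patient
registry demographics: sex 62.4/37.6, five age bands with 59.5% mass at
6–17 (uniform age within band, ≥65 capped at 90), the seven diagnosis
classes led by rhinitis-only at 40.9%, enrolment years 2015–2023, and
per-patient volumes matching the registry ratios (≈23.5 injections and
≈6.6 visits per patient). All probability vectors are the printed
counts normalized to sum to one. Where nothing is printed, defaults
were chosen once as clinically typical and are stated here: visit
intervals of 42 ± 10 days, weekly escalation injections with rising
doses then 28-day maintenance at 300 allergen units, a ~10-drug
medication menu spanning the score range from saline (0.1) to
adrenaline (1000) with diagnosis-gated use probabilities, 10% dropout,
and spirometry (FVC ~ N(3.2, 0.8) L, FEV1/FVC ~ U(0.6, 0.95)) for
asthmatics.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: joint dependence of age × disease × year
(only marginals are printed; independence is assumed), per-hospital
clustering, longitudinal efficacy trends (no AMS trajectories are
published to calibrate against), realistic adverse-event epidemiology,
and seasonal exacerbation structure. Tests against generated cohorts
demonstrate the *mechanics* (validity, determinism, marginal recovery,
pipeline behaviour), not clinical realism.

Each patient draws from a PRNG substream keyed by (seed, patient
index), so identical configurations are byte-reproducible across
platforms and appending patients never reshuffles existing ones.

## Numerical choices

Scoring is pure floating-point arithmetic; tests compare at absolute
tolerance 1e-9. Degenerate inputs are defined rather than special-cased
wherever a natural value exists: zero dose or zero period scores 0,
fewer than two visits yields an empty timeline, an empty record set
summarizes to zeros, a patient with no injections gets an adherence
entry (reason "no injections") rather than an exception. Same-day
consecutive visits define no window and are skipped in timelines.
Problem sizes in the test suite — 1,000 randomized oracle cases for the
engine and 10⁴-patient cohorts with 3σ binomial bounds for marginal
recovery — were chosen so the binomial standard error (≈0.5 points on a
62.4% proportion) sits well inside the ±1.5-point check bands while the
whole suite stays fast.

## Known limitations

The formulary's placeholder entries carry class-level scores, not
verified per-drug references; deployments should replace them with
local formularies (any CSV with the documented columns loads). The AMS
is a burden index, not an outcome model: no efficacy judgement,
dose-adjustment advice or symptom-score integration is computed. The
lesion-area coefficient uses the latest in-window measurement rather
than a time-weighted average, which overweights late measurements in
long windows.
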