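# Methods

## Study calendar and arms

The program is 78 weeks: phase I (1–26, loss), phase II (27–52,
maintenance), phase III (53–78, follow-up). Weeks are anchored per
participant at the enrollment date rather than a shared calendar — a
rolling cohort. Adjudication therefore runs on each participant's own
week boundaries, while the Monday incentive message is placed on the
unique Monday inside each 7-day participant week, which reconciles
rolling weeks with calendar-Monday messaging. A withdrawn participant
is inactive on the withdrawal date itself.

Weights are kilograms internally; the wire format for cellular-scale
payloads is JSON-lines with grams and epoch-millisecond UTC timestamps.
That dialect is fixed by this package (device vendors do not publish
one), and a 20–300 kg plausibility gate removes non-human artifacts
(untared scales, objects on the platform) before screening proper.

## Weight screening

The screen is a chained relative-deviation rule: a measurement is
rejected iff its deviation from the reference exceeds the threshold
*strictly* (default 3%; "more than 3%" is the rule, so exactly 3%
passes). The reference starts at the enrollment baseline, advances to
each accepted weight, and is never moved by a rejection. The rule is
symmetric in direction — the trial protocol does not distinguish gains
from losses. Coordinator resets replace the reference from their date
forward (local calendar date when a timezone is supplied) and are
themselves exempt from screening.

Two properties worth noting:

- The chained rule is **not monotone in the threshold**: widening the
  band can accept an intermediate weight, move the reference, and
  reject a later measurement that the narrower band accepted.
  Monotonicity holds per measurement, and the test suite asserts it
  there; the chained behavior is pinned by a brute-force re-walk oracle
  over random streams instead.
- Daily representatives are the **mean of the day's accepted weights**
  (not first or min), damping the close-succession re-weighs
  participants are asked to do when a first reading looks wrong.

The repeated-rejection flag defaults to 3 consecutive rejections;
protocols describe "patterns of repeated rejections" without a number,
so `k` is a parameter.

## Incentive adjudication

Per phase I/II week and incentivized participant, two booleans:

- **Diet:** ≥ `diet_days_required_per_week` (default 5) days with at
  least one entry totalling ≥ `min_kcal_per_logging_day` (default
  500 kcal). The calorie floor filters token entries.
- **Weight, phase I:** ≥ 2 accepted weigh-in days and a weekly mean
  strictly below the lowest prior weekly mean (baseline-seeded). The
  ratchet prevents oscillation gaming — losing the same kilogram twice
  pays once. The alternative rule (beat only the prior week) is
  available as `ratchet_phase1=False`.
- **Weight, phase II:** ≥ 1 accepted weigh-in day and a weekly mean
  within ±2% of the anchor, the lowest phase-I weekly mean. A missing
  anchor (no accepted phase-I weights) defers the week to manual review
  with amount 0 rather than auto-denying.

Payment: COMBINED full/partial/zero for 2/1/0 criteria; single-criterion
arms full or zero; CONTROL and phase III always zero. Amounts are
configuration currency units (placeholder defaults 1.0 / 0.5) — the
magnitudes are a protocol decision, not a property of the algorithm.
Manual overrides require a nonempty note, append to an immutable audit
trail, and can never pay a control participant. These exact numeric
defaults (logging days, calorie floor, weigh-in counts, band width) are
deliberate placeholders exposed in `IncentiveConfig` and the YAML study
config, since published platform descriptions confirm the rule *shapes*
but deployments set the values.

## Messaging

Cadence: 2 motivational messages (Tuesday, Friday) every week 1–78 for
everyone; 1 incentive-status message (Monday → Tuesday on holidays) in
phase I/II weeks for incentivized arms. Only the incentive message
shifts for holidays. The holiday calendar is injected configuration,
defaulting to observed US federal holidays computed internally.

Send times are uniform draws in [08:00, 11:00) local wall time, seeded
per (seed, participant, week, message type) so schedules are
reproducible, order-independent, and distinct seeds vary only times —
never dates or counts. Constructing wall time directly in the
enrollment timezone keeps the window correct across daylight-saving
transitions; the enrollment zone is authoritative forever (no travel
adjustment).

Delivery is a per-message state machine (QUEUED → ACCEPTED_BY_CARRIER →
DELIVERED, or → FAILED with reason). The `attempted` denominator counts
unique messages, not retries; carrier acceptance is sticky so a
post-acceptance failure still counts in the delivery-rate numerator.
Retries re-queue up to 3 attempts, never for opt-outs (consent) or
landlines (hardware). Incentive bodies are digit- and currency-free
templates: numerals and dollar signs trigger carrier spam filters.

## Simulator

The simulator emulates the *operating regime* the platform must
survive, not physiology or incentive-responsiveness:

| parameter | default | rationale |
|---|---|---|
| weigh-in days/week | 2 (phase I), 1 (phase II/III) | instructed cadence |
| repeat-weigh probability | 0.2/weighing day | yields ~1.2 weigh-ins per weighing day |
| errant weight probability | 0.05 | ~5% rejection in mature remote-weighing deployments |
| errant deviation | U(8%, 15%), random sign | well outside the 3% band, inside plausibility |
| measurement noise | σ = 0.4 kg | scale repeatability; ≪ 3% of body weight |
| true loss | 0.35 kg/week in phase I, then plateau | modest, realistic loss curve |
| logging start / half-life | 0.85, 90 days | adherence decline concentrating around day 90 |
| kcal per logging day | N(1900, 350²) truncated at 0 | adult intake |
| delivery failure | 0.006 | sub-1% carrier failure |
| withdrawal hazard | 0.002/week | rare dropout |

Baselines are N(95, 14²) kg truncated at 60; participants enroll in
weekly waves of 25 from a fixed start date, cycling through the four
arms; site (and thereby timezone, Chicago/New York) is a fair coin.
Everything derives from one seed; two runs with the same configuration
are byte-identical on disk.

What passing tests show: the pipeline's bookkeeping — screening,
adjudication, scheduling, accounting — is correct under a realistic
volume and error mix, and injected parameters (errant rate, delivery
failure rate) are recovered by the reported statistics within binomial
error. What they do not show: anything about real human behavior,
incentive efficacy, or the empirical adherence of any actual cohort.
The latent weight model is intentionally simple (piecewise-linear +
Gaussian noise) because the platform, not physiology, is under test.

Scenario injections reproduce documented field failures
deterministically: a household member's ~20%-off weight block (must be
rejected), a week-long carrier gap (weight criterion must fail), a spam
wave failing a week's incentive messages (retry must requeue them), and
a diet-API cutover with a logging gap and source switch.

## Reporting conventions

Percentages print at one decimal with half-up rounding (`Decimal`, not
float `round`, avoiding banker's rounding). "Weighing day" = a
participant-day with ≥ 1 transmission, accepted or rejected, since
re-weighs after an unreasonable first reading are part of the behavior
being measured. Weigh-ins per weighing day are averaged within
participant first, then across participants (SD likewise); the pooled
alternative is a flag. Peak-day ties break to the earliest date. Empty
inputs summarize to zeros rather than erroring.

## Problem sizes

The test suite and the acceptance script run the simulator at 6–200
participants and 4–78 weeks; the parameter-recovery checks use 200
participants × 26 weeks (≈ 18,000 weights, ≈ 28,000 messages), sizes at
which binomial standard errors are small enough to separate the
injected rates from neighboring values while the whole suite stays
fast.

## Known limitations

- No live device/SMS/EHR integrations; the interchange formats stand in
  for vendor APIs.
- The screening chain assumes the baseline is trustworthy; a bad
  enrollment baseline requires a manual reset to recover.
- Message receipt events are applied in timestamp order; out-of-order
  carrier webhooks with equal timestamps tie-break by message ID.
- The simulator draws weigh-in days independently per day; real
  adherence is autocorrelated (streaks and lapses), so day-level gap
  statistics are thinner-tailed than in the field.
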