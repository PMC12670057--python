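# trialops

Operations engine for remote weight-monitoring trials that pay
contingency-management incentives: cellular-scale data ingestion,
automated anomalous-weight screening, weekly per-arm incentive
adjudication across trial phases, holiday-aware SMS scheduling with
delivery accounting, operational reporting, and a synthetic-cohort
simulator so the whole pipeline runs without participant data.

## Who this is for

Teams running (or rehearsing) digital weight-loss trials in which
participants weigh on cellular scales, log meals in a phone app, and
receive weekly financial incentives contingent on adherence. The
package implements the *platform* — the data plumbing, screening rules,
payment algorithm, and messaging cadence — not the trial's efficacy
analysis.

## The model

A 78-week program in three 26-week phases, with study weeks anchored at
each participant's enrollment date:

- **Phase I (weeks 1–26, weight loss).** Weekly weight criterion: at
  least 2 accepted weigh-in days and a weekly mean weight strictly below
  the participant's lowest weekly mean to date (a ratchet, seeded from
  baseline `w0`).
- **Phase II (weeks 27–52, maintenance).** At least 1 accepted weigh-in
  day and a weekly mean inside the band `a·(1 ± δ)`, where the anchor
  `a` is the lowest phase-I weekly mean and `δ = 0.02` by default.
- **Phase III (weeks 53–78).** Motivational messages continue; no
  incentives.

**Weight screening.** Each transmitted weight `w` is screened against
the reference `r` (the last accepted weight, initially baseline):
rejected iff `|w − r| / r > 0.03`, strictly. Rejected weights never
update the reference and are invisible to adjudication. Coordinators
may reset the reference to a verified weight from a given date forward.

**Diet criterion.** ≥ 5 days/week with a log entry totalling
≥ 500 kcal (both configurable).

**Arms.** COMBINED pays full for both criteria and partial for exactly
one; DIET_ONLY and WEIGHT_ONLY pay full on their single criterion;
CONTROL is never paid.

**Messaging.** Two motivational texts per week (Tuesday, Friday) for
all 78 weeks; one incentive-status text each phase I/II week on Monday,
shifted to Tuesday when Monday is a holiday (US federal calendar by
default). Send times are drawn uniformly in 08:00–11:00 in the
participant's enrollment timezone. Delivery rate = carrier-accepted /
attempted; success rate = delivered / accepted. Failed messages retry
up to 3 attempts, except opt-outs and landlines.

## Worked example

```sh
trialops report --seed 1 --participants 12 --weeks 10
```

```
Operations summary
==================
messages_total                     330
delivery_rate                      0.996969696969697
success_rate                       1.0
weights_total                      282
weights_accepted                   265
acceptance_pct                     94.0
mean_weighins_per_weighing_day     1.2363348711103288
sd_weighins_per_weighing_day       0.10446101006080671
diet_days_total                    563
incentives_total                   90
incentives_auto                    90
auto_pct                           100.0
incentives_manual                  0
manual_pct                         0.0
messages by weekday and type:
            Mon    Tue    Wed    Thu    Fri    Sat    Sun
    INCE     72     18      0      0      0      0      0
    MOTI      0    120      0      0    120      0      0
    MANU      0      0      0      0      0      0      0
```

Reading it: 12 simulated participants over 10 weeks received 330 texts
(the 18 Tuesday incentive messages are Monday-holiday shifts — New
Year's Day observed and Martin Luther King Jr. Day fall in this
window). 94.0% of transmitted weights passed the >3% screen; the rest
were errant transmissions the simulator injected at 5%. Participants
averaged 1.24 weigh-ins per weighing day (close-succession re-weighs),
and all 90 phase-I incentive decisions were processed automatically.

The CLI also exposes `simulate`, `ingest`, `screen`, `incentives`, and
`schedule`; all file formats are plain CSV/JSON-lines and are
round-trippable through the library (`trialops simulate --out-dir d`
writes roster, scale, diet, and receipt fixtures that `ingest` reads
back verbatim).

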