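"""Weekly contingency-management incentive adjudication.

Each phase I/II week, every active participant in an incentivized arm is
adjudicated against up to two criteria:

* dietary self-monitoring — at least ``diet_days_required_per_week`` days
  with at least one log entry totalling at least
  ``min_kcal_per_logging_day`` kcal; and
* weight — enough accepted weigh-in days for the phase, plus in phase I
  a new all-time weekly low (a ratchet rule, so oscillating around a
  plateau cannot be gamed for repeated rewards) or in phase II a weekly
  representative within a symmetric maintenance band around the
  end-of-phase-I anchor weight.

The COMBINED arm earns a full amount when both criteria are met and a
partial amount when exactly one is; single-criterion arms earn full or
nothing on their own criterion; CONTROL and all phase III weeks earn
zero.  Decisions default to automatic processing; edge cases are marked
MANUAL with a documented note and a preserved audit trail.

Only ACCEPTED weights ever enter adjudication — rejected measurements
are invisible to every criterion.
"""

from __future__ import annotations

import datetime as dt
import statistics
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from trialops.ingestion import DietDay
from trialops.screening import WeightRecord, collapse_daily
from trialops.trial_core import (
    Arm,
    Participant,
    Phase,
    StudyWeek,
    build_calendar,
    is_active,
    map_week_to_phase,
)


class ProcessingMode(str, Enum):
    AUTO = "AUTO"
    MANUAL = "MANUAL"


class AdjudicationDeferred(Exception):
    """A week that cannot be auto-adjudicated (e.g. no phase-I anchor)."""


@dataclass(frozen=True)
class IncentiveConfig:
    """Tunable rules of the weekly incentive algorithm.

    Amounts are study-configuration currency units with placeholder
    defaults (1.0 full / 0.5 partial); real deployments set them from
    the protocol.  ``weighins_required`` maps phase to the number of
    accepted weigh-in days needed that week.
    """

    diet_days_required_per_week: int = 5
    min_kcal_per_logging_day: float = 500.0
    weighins_required_phase1: int = 2
    weighins_required_phase2: int = 1
    maintenance_band_fraction: float = 0.02
    amount_full: float = 1.0
    amount_partial: float = 0.5
    ratchet_phase1: bool = True  # alternative: decrease vs immediately prior week

    def __post_init__(self) -> None:
        if not 0 < self.maintenance_band_fraction < 1:
            raise ValueError("maintenance_band_fraction must be in (0, 1)")
        if self.amount_full < 0 or self.amount_partial < 0:
            raise ValueError("amounts must be nonnegative")
        if self.amount_partial >= self.amount_full:
            raise ValueError("amount_partial must be less than amount_full")

    def weighins_required(self, phase: Phase) -> int:
        return (
            self.weighins_required_phase1
            if phase is Phase.I
            else self.weighins_required_phase2
        )


@dataclass(frozen=True)
class IncentiveDecision:
    """One participant-week adjudication.

    ``diet_criterion_met`` / ``weight_criterion_met`` are None when the
    criterion does not apply to the arm.  ``audit`` preserves the full
    history of (mode, amount, note) entries; the live fields reflect the
    latest entry.
    """

    participant_id: str
    week_index: int
    arm: Arm
    diet_criterion_met: bool | None
    weight_criterion_met: bool | None
    amount: float
    processing_mode: ProcessingMode = ProcessingMode.AUTO
    note: str = ""
    audit: tuple[tuple[str, float, str], ...] = ()


def evaluate_diet_criterion(
    diet_days: Iterable[DietDay], config: IncentiveConfig
) -> bool:
    """True iff enough days this week have a qualifying dietary log.

    A day qualifies when it has at least one entry and its total is at
    least the calorie minimum (filters token entries).
    """
    qualifying = sum(
        1
        for d in diet_days
        if d.n_entries >= 1 and d.total_kcal >= config.min_kcal_per_logging_day
    )
    return qualifying >= config.diet_days_required_per_week


def weekly_representative(daily: Mapping[dt.date, float]) -> float | None:
    """Weekly representative weight: mean of the daily representatives."""
    if not daily:
        return None
    return statistics.fmean(daily.values())


def evaluate_weight_criterion_phase1(
    this_week: Mapping[dt.date, float],
    prior_weekly_representatives: Sequence[float],
    config: IncentiveConfig,
) -> bool:
    """Phase I weight criterion.

    Requires (a) at least the phase-I number of accepted weigh-in days
    and (b) the weekly representative strictly below the lowest prior
    weekly representative (the ratchet; callers seed the history with
    the baseline weight so week 1 must beat baseline).  With
    ``ratchet_phase1`` off, only the immediately prior representative
    must be beaten.
    """
    if len(this_week) < config.weighins_required(Phase.I):
        return False
    rep = weekly_representative(this_week)
    if rep is None or not prior_weekly_representatives:
        return False
    target = (
        min(prior_weekly_representatives)
        if config.ratchet_phase1
        else prior_weekly_representatives[-1]
    )
    return rep < target


def evaluate_weight_criterion_phase2(
    this_week: Mapping[dt.date, float],
    anchor_kg: float | None,
    config: IncentiveConfig,
) -> bool:
    """Phase II maintenance criterion.

    Requires the phase-II weigh-in count and a weekly representative
    within anchor x (1 +/- maintenance_band_fraction).  A missing anchor
    (no accepted phase-I weights) defers adjudication to manual review.
    """
    if anchor_kg is None:
        raise AdjudicationDeferred("no phase-I anchor weight; route to manual review")
    if len(this_week) < config.weighins_required(Phase.II):
        return False
    rep = weekly_representative(this_week)
    if rep is None:
        return False
    band = config.maintenance_band_fraction
    return anchor_kg * (1 - band) <= rep <= anchor_kg * (1 + band)


def decide_week(
    participant: Participant,
    week_index: int,
    diet_met: bool | None,
    weight_met: bool | None,
    config: IncentiveConfig,
) -> IncentiveDecision:
    """Combine per-criterion results into the week's decision.

    CONTROL and phase III always pay zero.  DIET_ONLY / WEIGHT_ONLY pay
    the full amount on their single criterion.  COMBINED pays full for
    both, partial for exactly one.
    """
    phase = map_week_to_phase(week_index)
    arm = participant.arm

    if arm is Arm.CONTROL or phase is Phase.III:
        return IncentiveDecision(
            participant_id=participant.participant_id,
            week_index=week_index,
            arm=arm,
            diet_criterion_met=None,
            weight_criterion_met=None,
            amount=0.0,
            audit=(("AUTO", 0.0, ""),),
        )

    if arm is Arm.DIET_ONLY:
        weight_met = None
        amount = config.amount_full if diet_met else 0.0
    elif arm is Arm.WEIGHT_ONLY:
        diet_met = None
        amount = config.amount_full if weight_met else 0.0
    else:  # COMBINED
        n_met = int(bool(diet_met)) + int(bool(weight_met))
        amount = {0: 0.0, 1: config.amount_partial, 2: config.amount_full}[n_met]

    return IncentiveDecision(
        participant_id=participant.participant_id,
        week_index=week_index,
        arm=arm,
        diet_criterion_met=diet_met,
        weight_criterion_met=weight_met,
        amount=amount,
        audit=(("AUTO", amount, ""),),
    )


def mark_manual(
    decision: IncentiveDecision,
    note: str,
    amount_override: float | None = None,
) -> IncentiveDecision:
    """Convert a decision to MANUAL with a documented note.

    The original audit entry is preserved and the override appended.
    Manual adjudication must be documented (empty note refused) and can
    never pay a CONTROL participant.
    """
    if not note.strip():
        raise ValueError("manual adjudication requires a nonempty note")
    amount = decision.amount if amount_override is None else amount_override
    if decision.arm is Arm.CONTROL and amount != 0:
        raise ValueError("control-arm participants cannot be paid")
    return replace(
        decision,
        processing_mode=ProcessingMode.MANUAL,
        note=note,
        amount=amount,
        audit=decision.audit + (("MANUAL", amount, note),),
    )


def _weekly_dailies(
    records: Sequence[WeightRecord],
    calendar: Sequence[StudyWeek],
    tz: str | None,
) -> dict[int, dict[dt.date, float]]:
    """Daily accepted representatives grouped by study-week index."""
    daily = collapse_daily(records, tz=tz)
    out: dict[int, dict[dt.date, float]] = {}
    for wk in calendar:
        week_days = {
            day: w for day, w in daily.items() if wk.start_date <= day <= wk.end_date
        }
        if week_days:
            out[wk.week_index] = week_days
    return out


def adjudicate_participant(
    participant: Participant,
    weight_records: Sequence[WeightRecord],
    diet_days: Sequence[DietDay],
    config: IncentiveConfig,
    through_week: int,
) -> list[IncentiveDecision]:
    """Adjudicate weeks 1..through_week (phase I/II only) for one participant.

    The phase-I weekly-low history is seeded with the baseline weight;
    the phase-II anchor is the lowest phase-I weekly representative.
    Weeks that cannot be auto-adjudicated are emitted as MANUAL with
    amount 0 pending coordinator review.
    """
    calendar = build_calendar(participant.enrollment_date)
    weekly = _weekly_dailies(weight_records, calendar, participant.timezone)
    diet_by_week: dict[int, list[DietDay]] = {}
    for d in diet_days:
        for wk in calendar:
            if wk.start_date <= d.date <= wk.end_date:
                diet_by_week.setdefault(wk.week_index, []).append(d)
                break

    history: list[float] = [participant.baseline_weight_kg]
    anchor: float | None = None
    decisions: list[IncentiveDecision] = []
    for wk in calendar:
        if wk.week_index > through_week:
            break
        this_week = weekly.get(wk.week_index, {})
        rep = weekly_representative(this_week)
        if wk.phase is Phase.III:
            break
        if not is_active(participant, wk.end_date):
            # withdrawn before the week completed: no decision
            if rep is not None and wk.phase is Phase.I:
                history.append(rep)
            continue

        diet_met = evaluate_diet_criterion(diet_by_week.get(wk.week_index, []), config)
        if wk.phase is Phase.I:
            weight_met = evaluate_weight_criterion_phase1(this_week, history, config)
            decisions.append(
                decide_week(participant, wk.week_index, diet_met, weight_met, config)
            )
            if rep is not None:
                history.append(rep)
        else:  # Phase II
            if anchor is None:
                phase1_reps = history[1:]  # exclude the baseline seed
                anchor = min(phase1_reps) if phase1_reps else None
            try:
                weight_met = evaluate_weight_criterion_phase2(this_week, anchor, config)
                decisions.append(
                    decide_week(participant, wk.week_index, diet_met, weight_met, config)
                )
            except AdjudicationDeferred as exc:
                auto = decide_week(participant, wk.week_index, diet_met, False, config)
                decisions.append(mark_manual(replace(auto, amount=0.0), str(exc)))
    return decisions


@dataclass(frozen=True)
class PaymentQueueEntry:
    participant_id: str
    week_index: int
    amount: float


def run_weekly_batch(
    participants: Sequence[Participant],
    weight_records: Mapping[str, Sequence[WeightRecord]],
    diet_days: Mapping[str, Sequence[DietDay]],
    week_ending: dt.date,
    config: IncentiveConfig,
) -> tuple[list[IncentiveDecision], list[PaymentQueueEntry]]:
    """Adjudicate the most recent completed week for every participant.

    Study weeks are anchored per participant, so the same calendar date
    falls in different week indices for different participants; each
    participant's latest week ending on or before ``week_ending`` is
    adjudicated.  Control-arm, withdrawn, and phase-III participants
    produce no decision.  Deterministic given inputs; the payment queue
    is sorted by participant ID.
    """
    decisions: list[IncentiveDecision] = []
    for p in sorted(participants, key=lambda q: q.participant_id):
        if not p.arm.incentivized:
            continue
        calendar = build_calendar(p.enrollment_date)
        completed = [wk for wk in calendar if wk.end_date <= week_ending]
        if not completed:
            continue
        wk = completed[-1]
        if wk.phase is Phase.III or not is_active(p, wk.end_date):
            continue
        all_decisions = adjudicate_participant(
            p,
            weight_records.get(p.participant_id, ()),
            diet_days.get(p.participant_id, ()),
            config,
            through_week=wk.week_index,
        )
        decisions.extend(d for d in all_decisions if d.week_index == wk.week_index)
    queue = [
        PaymentQueueEntry(d.participant_id, d.week_index, d.amount)
        for d in sorted(decisions, key=lambda d: d.participant_id)
        if d.amount > 0
    ]
    return decisions, queue
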