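"""Message scheduling, delivery accounting, and retry logic.

Cadence: every participant receives two motivational texts per week
(Tuesday and Friday) for all 78 weeks; participants in incentivized arms
additionally receive one incentive-status text on Monday of each phase
I/II week, shifted to Tuesday when Monday is a holiday.  Send times are
drawn uniformly in the 08:00-11:00 local-time window, in the timezone
recorded at enrollment (authoritative forever — no adjustment for
travel), which keeps the window correct across daylight-saving
transitions.

Delivery is tracked as a small state machine per message:
QUEUED -> ACCEPTED_BY_CARRIER -> DELIVERED, or -> FAILED with a reason.
The delivery rate is messages accepted by the downstream carrier divided
by messages attempted; the success rate is messages with a positive
delivery receipt divided by accepted messages.  Failed messages are
retried up to a cap, except opt-outs and landlines, which are final.

Incentive bodies are templated without digits or currency symbols: spam
filters flag dollar amounts, and removing numerals restores delivery.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np

from trialops.incentives import IncentiveDecision
from trialops.trial_core import (
    Arm,
    Participant,
    Phase,
    StudyWeek,
    build_calendar,
    is_active,
    map_week_to_phase,
)


class MessageType(str, Enum):
    INCENTIVE = "INCENTIVE"
    MOTIVATIONAL = "MOTIVATIONAL"
    MANUAL = "MANUAL"


class MessageStatus(str, Enum):
    QUEUED = "QUEUED"
    ACCEPTED_BY_CARRIER = "ACCEPTED_BY_CARRIER"
    DELIVERED = "DELIVERED"
    FAILED = "FAILED"


class FailureReason(str, Enum):
    SPAM_FLAGGED = "SPAM_FLAGGED"
    OPTED_OUT = "OPTED_OUT"
    UNREACHABLE = "UNREACHABLE"
    LANDLINE = "LANDLINE"
    OTHER = "OTHER"


class CarrierEvent(str, Enum):
    ACCEPT = "ACCEPT"
    DELIVERY_RECEIPT = "DELIVERY_RECEIPT"
    FAIL = "FAIL"


class StateError(RuntimeError):
    """Illegal delivery-state transition."""


@dataclass(frozen=True)
class Message:
    """One scheduled or sent text message."""

    message_id: str
    participant_id: str
    mtype: MessageType
    scheduled_local: dt.datetime  # timezone-aware, participant-local
    body: str
    status: MessageStatus = MessageStatus.QUEUED
    sent_utc: dt.datetime | None = None
    failure_reason: FailureReason | None = None
    attempt: int = 1
    carrier_accepted: bool = False  # sticky: survives a later failure


@dataclass(frozen=True)
class DeliveryStats:
    attempted: int
    accepted: int
    delivered: int
    delivery_rate: float
    success_rate: float


# ---------------------------------------------------------------------------
# Holidays

def _nth_weekday(year: int, month: int, weekday: int, n: int) -> dt.date:
    d = dt.date(year, month, 1)
    offset = (weekday - d.weekday()) % 7
    return d + dt.timedelta(days=offset + 7 * (n - 1))


def _last_weekday(year: int, month: int, weekday: int) -> dt.date:
    if month == 12:
        d = dt.date(year, 12, 31)
    else:
        d = dt.date(year, month + 1, 1) - dt.timedelta(days=1)
    return d - dt.timedelta(days=(d.weekday() - weekday) % 7)


def _observed(d: dt.date) -> dt.date:
    # Federal observance: Saturday holidays observed Friday, Sunday observed Monday.
    if d.weekday() == 5:
        return d - dt.timedelta(days=1)
    if d.weekday() == 6:
        return d + dt.timedelta(days=1)
    return d


def us_federal_holidays(year: int) -> set[dt.date]:
    """Observed US federal holidays for one year (default holiday calendar)."""
    mon, thu = 0, 3
    fixed = [
        dt.date(year, 1, 1),    # New Year's Day
        dt.date(year, 6, 19),   # Juneteenth
        dt.date(year, 7, 4),    # Independence Day
        dt.date(year, 11, 11),  # Veterans Day
        dt.date(year, 12, 25),  # Christmas Day
    ]
    floating = [
        _nth_weekday(year, 1, mon, 3),    # Martin Luther King Jr. Day
        _nth_weekday(year, 2, mon, 3),    # Washington's Birthday
        _last_weekday(year, 5, mon),      # Memorial Day
        _nth_weekday(year, 9, mon, 1),    # Labor Day
        _nth_weekday(year, 10, mon, 2),   # Columbus Day
        _nth_weekday(year, 11, thu, 4),   # Thanksgiving
    ]
    return {_observed(d) for d in fixed} | set(floating)


def holidays_for_range(start: dt.date, end: dt.date) -> set[dt.date]:
    days: set[dt.date] = set()
    for year in range(start.year, end.year + 1):
        days |= us_federal_holidays(year)
    return {d for d in days if start <= d <= end}


# ---------------------------------------------------------------------------
# Scheduling

SEND_WINDOW_START_H = 8
SEND_WINDOW_END_H = 11

_TYPE_CODE = {MessageType.INCENTIVE: 0, MessageType.MOTIVATIONAL: 1, MessageType.MANUAL: 2}


def _stable_pid_int(participant_id: str) -> int:
    # Deterministic across processes (unlike hash()); keeps RNG streams
    # independent of roster ordering.
    h = 0
    for ch in participant_id:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def _send_time(
    seed: int, participant_id: str, week_index: int, mtype: MessageType, date: dt.date, tz: str
) -> dt.datetime:
    """Uniform draw in [08:00, 11:00) local wall time, reproducible per
    (seed, participant, week, type) and invariant to scheduling order."""
    rng = np.random.default_rng(
        [seed, _stable_pid_int(participant_id), week_index, _TYPE_CODE[mtype]]
    )
    seconds = int(rng.integers(0, (SEND_WINDOW_END_H - SEND_WINDOW_START_H) * 3600))
    naive = dt.datetime.combine(date, dt.time(SEND_WINDOW_START_H)) + dt.timedelta(
        seconds=seconds
    )
    return naive.replace(tzinfo=ZoneInfo(tz))


def _weekday_in_week(week: StudyWeek, weekday: int) -> dt.date:
    """The unique date of the given weekday within a 7-day study week."""
    offset = (weekday - week.start_date.weekday()) % 7
    return week.start_date + dt.timedelta(days=offset)


MOTIVATIONAL_BODY = "Keep going strong this week. Small healthy choices add up."


def schedule_week(
    participants: Sequence[Participant],
    week_index: int,
    holidays: set[dt.date] | None = None,
    rng_seed: int = 0,
    decisions: Mapping[str, IncentiveDecision] | None = None,
) -> list[Message]:
    """Schedule one study week of messages for each active participant.

    Every week gets two motivational messages (Tuesday, Friday).  Phase
    I/II weeks add one incentive-status message for incentivized arms on
    Monday, or Tuesday when Monday is a holiday (default calendar: US
    federal).  Send times are seeded uniform draws in the local-morning
    window; distinct seeds vary only times, never dates or counts.
    """
    phase = map_week_to_phase(week_index)
    out: list[Message] = []
    for p in participants:
        calendar = build_calendar(p.enrollment_date)
        week = calendar[week_index - 1]
        hol = (
            holidays
            if holidays is not None
            else holidays_for_range(week.start_date, week.end_date + dt.timedelta(days=7))
        )

        plan: list[tuple[MessageType, dt.date]] = []
        if p.arm.incentivized and phase in (Phase.I, Phase.II):
            monday = _weekday_in_week(week, 0)
            send_date = monday + dt.timedelta(days=1) if monday in hol else monday
            plan.append((MessageType.INCENTIVE, send_date))
        plan.append((MessageType.MOTIVATIONAL, _weekday_in_week(week, 1)))
        plan.append((MessageType.MOTIVATIONAL, _weekday_in_week(week, 4)))

        for mtype, date in plan:
            if not is_active(p, date):
                continue
            if mtype is MessageType.INCENTIVE:
                decision = (decisions or {}).get(p.participant_id)
                body = (
                    compose_incentive_body(decision)
                    if decision is not None
                    else "Your weekly incentive update is ready. Check your study card."
                )
            else:
                body = MOTIVATIONAL_BODY
            out.append(
                Message(
                    message_id=f"{p.participant_id}-w{week_index:02d}-{mtype.value[:3]}-{date.isoformat()}",
                    participant_id=p.participant_id,
                    mtype=mtype,
                    scheduled_local=_send_time(
                        rng_seed, p.participant_id, week_index, mtype, date, p.timezone
                    ),
                    body=body,
                )
            )
    return out


_FULL_BODY = "Great work this week. You earned your full reward."
_PARTIAL_BODY = "Nice progress. You met one goal this week and earned a partial reward."
_NONE_BODY = "You did not earn a reward this week. A fresh week starts now."


def compose_incentive_body(decision: IncentiveDecision) -> str:
    """Template the incentive-status text for a decision.

    Deterministic per (arm, criteria pattern); bodies contain no digits
    and no currency symbols, a spam-mitigation profile.  Control-arm
    decisions are refused — control receives no incentive messages.
    """
    if decision.arm is Arm.CONTROL:
        raise ValueError("control-arm participants receive no incentive messages")
    met = [m for m in (decision.diet_criterion_met, decision.weight_criterion_met) if m is not None]
    n_met = sum(bool(m) for m in met)
    if decision.arm is Arm.COMBINED:
        body = {0: _NONE_BODY, 1: _PARTIAL_BODY, 2: _FULL_BODY}[n_met]
    else:
        body = _FULL_BODY if n_met >= 1 else _NONE_BODY
    return body


# ---------------------------------------------------------------------------
# Delivery state machine

def record_receipt(
    message: Message,
    event: CarrierEvent,
    reason: FailureReason | None = None,
    event_time_utc: dt.datetime | None = None,
) -> Message:
    """Apply a carrier event to a message, returning the updated message.

    Legal transitions: QUEUED --ACCEPT--> ACCEPTED_BY_CARRIER
    --DELIVERY_RECEIPT--> DELIVERED; FAIL is legal from QUEUED or
    ACCEPTED_BY_CARRIER and requires a reason.  Anything else raises
    StateError (DELIVERED and FAILED are terminal).
    """
    s = message.status
    if event is CarrierEvent.ACCEPT:
        if s is not MessageStatus.QUEUED:
            raise StateError(f"cannot ACCEPT from {s.value}")
        return replace(
            message,
            status=MessageStatus.ACCEPTED_BY_CARRIER,
            carrier_accepted=True,
            sent_utc=event_time_utc or message.sent_utc,
        )
    if event is CarrierEvent.DELIVERY_RECEIPT:
        if s is not MessageStatus.ACCEPTED_BY_CARRIER:
            raise StateError(f"cannot record delivery receipt from {s.value}")
        return replace(message, status=MessageStatus.DELIVERED)
    if event is CarrierEvent.FAIL:
        if s not in (MessageStatus.QUEUED, MessageStatus.ACCEPTED_BY_CARRIER):
            raise StateError(f"cannot FAIL from {s.value}")
        if reason is None:
            raise ValueError("FAIL event requires a failure reason")
        return replace(message, status=MessageStatus.FAILED, failure_reason=reason)
    raise ValueError(f"unknown carrier event {event!r}")


_NEVER_RETRY = {FailureReason.OPTED_OUT, FailureReason.LANDLINE}


def retry_failed(messages: Iterable[Message], max_attempts: int = 3) -> list[Message]:
    """Requeue retryable failures with an incremented attempt counter.

    Opt-outs and landlines are never retried (consent and hardware are
    not transient); retries stop at ``max_attempts`` per message.
    """
    out: list[Message] = []
    for m in messages:
        if (
            m.status is MessageStatus.FAILED
            and m.failure_reason not in _NEVER_RETRY
            and m.attempt < max_attempts
        ):
            out.append(
                replace(
                    m,
                    status=MessageStatus.QUEUED,
                    failure_reason=None,
                    attempt=m.attempt + 1,
                )
            )
        else:
            out.append(m)
    return out


def compute_delivery_stats(messages: Iterable[Message]) -> DeliveryStats:
    """Delivery accounting over unique messages (retries do not inflate
    the attempted count).

    delivery_rate = accepted / attempted; success_rate = delivered /
    accepted; both 0 when the denominator is 0.
    """
    attempted = accepted = delivered = 0
    for m in messages:
        attempted += 1
        if m.carrier_accepted or m.status in (
            MessageStatus.ACCEPTED_BY_CARRIER,
            MessageStatus.DELIVERED,
        ):
            accepted += 1
        if m.status is MessageStatus.DELIVERED:
            delivered += 1
    return DeliveryStats(
        attempted=attempted,
        accepted=accepted,
        delivered=delivered,
        delivery_rate=accepted / attempted if attempted else 0.0,
        success_rate=delivered / accepted if accepted else 0.0,
    )
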