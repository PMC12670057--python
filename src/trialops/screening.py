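"""Automated anomalous-weight screening and manual reference resets.

Study-provided scales produce errant transmissions — a household member
stepping on, an untared platform — so each incoming weight is screened
against the participant's *reference weight*: the most recent accepted
measurement (seeded from the enrollment baseline).  A measurement whose
relative deviation from the reference exceeds the threshold (default
strictly more than 3%) is labeled REJECTED; rejected weights never
update the reference and are excluded from all incentive adjudication.

When a rejected streak reflects a genuine change (a long gap off the
scale, a verified new weight), coordinators issue a *reference reset*
that replaces the reference from its date forward; resets themselves are
exempt from screening.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union
from zoneinfo import ZoneInfo

from trialops.ingestion import BoundMeasurement

DEFAULT_THRESHOLD = 0.03


class ScreeningStatus(str, Enum):
    ACCEPTED = "ACCEPTED"
    REJECTED = "REJECTED"


class InvalidReferenceError(ValueError):
    """Raised when screening against a nonpositive reference weight."""


class OrderingError(ValueError):
    """Raised when a stream is not sorted by timestamp."""


@dataclass(frozen=True)
class WeightRecord:
    """One screened scale measurement."""

    participant_id: str
    timestamp_utc: dt.datetime
    weight_kg: float
    status: ScreeningStatus
    reference_weight_kg: float
    reason: str | None = None


@dataclass(frozen=True)
class ReferenceReset:
    """A coordinator-verified reference replacement, applied from its date on."""

    participant_id: str
    date: dt.date
    verified_weight_kg: float
    operator_note: str = ""

    def __post_init__(self) -> None:
        if self.verified_weight_kg <= 0:
            raise ValueError("verified_weight_kg must be positive")


def screen_weight(
    weight_kg: float, reference_kg: float, threshold: float = DEFAULT_THRESHOLD
) -> ScreeningStatus:
    """Screen one weight against a reference.

    REJECTED iff |weight - reference| / reference strictly exceeds the
    threshold; a deviation of exactly the threshold is accepted.  The
    rule is symmetric in direction.
    """
    if reference_kg <= 0:
        raise InvalidReferenceError(f"reference must be positive, got {reference_kg}")
    deviation = abs(weight_kg - reference_kg) / reference_kg
    if deviation > threshold:
        return ScreeningStatus.REJECTED
    return ScreeningStatus.ACCEPTED


def screen_stream(
    measurements: Sequence[BoundMeasurement],
    baseline_kg: float,
    resets: Sequence[ReferenceReset] = (),
    threshold: float = DEFAULT_THRESHOLD,
    tz: str | None = None,
) -> list[WeightRecord]:
    """Screen one participant's time-ordered measurements.

    The first reference is the enrollment baseline; each ACCEPTED weight
    becomes the new reference; REJECTED weights never update it.  A
    reset dated on or before a measurement's calendar date (local if
    ``tz`` is given, else UTC) replaces the reference from that point
    forward.  Input must be sorted by timestamp.
    """
    if baseline_kg <= 0:
        raise InvalidReferenceError(f"baseline must be positive, got {baseline_kg}")
    for a, b in zip(measurements, measurements[1:]):
        if b.timestamp_utc < a.timestamp_utc:
            raise OrderingError("measurements must be sorted by timestamp")

    zone = ZoneInfo(tz) if tz else dt.timezone.utc
    pending = sorted(resets, key=lambda r: r.date)
    reset_i = 0
    reference = baseline_kg
    out: list[WeightRecord] = []
    for m in measurements:
        local_date = m.timestamp_utc.astimezone(zone).date()
        while reset_i < len(pending) and pending[reset_i].date <= local_date:
            reference = pending[reset_i].verified_weight_kg
            reset_i += 1
        status = screen_weight(m.weight_kg, reference, threshold)
        reason = None
        if status is ScreeningStatus.REJECTED:
            deviation = abs(m.weight_kg - reference) / reference
            reason = f"deviation {deviation:.1%} from reference exceeds {threshold:.0%}"
        out.append(
            WeightRecord(
                participant_id=m.participant_id,
                timestamp_utc=m.timestamp_utc,
                weight_kg=m.weight_kg,
                status=status,
                reference_weight_kg=reference,
                reason=reason,
            )
        )
        if status is ScreeningStatus.ACCEPTED:
            reference = m.weight_kg
    return out


def flag_repeat_rejections(records: Iterable[WeightRecord], k: int = 3) -> list[str]:
    """Participants with >= k consecutive REJECTED records.

    Streaks are per participant in record order; an acceptance resets
    the streak.  Flagged participants are routed to coordinator review.
    """
    streaks: dict[str, int] = {}
    flagged: dict[str, None] = {}
    for r in records:
        if r.status is ScreeningStatus.REJECTED:
            streaks[r.participant_id] = streaks.get(r.participant_id, 0) + 1
            if streaks[r.participant_id] >= k:
                flagged[r.participant_id] = None
        else:
            streaks[r.participant_id] = 0
    return list(flagged)


def collapse_daily(
    records: Iterable[WeightRecord], tz: str | None = None
) -> dict[dt.date, float]:
    """Per-calendar-date representative weight: the mean of that day's
    ACCEPTED weights.  Days with only rejected records have no value.
    Dates are local when ``tz`` is given (else UTC) — close-succession
    re-weighs on one day collapse to a single damped value.
    """
    zone = ZoneInfo(tz) if tz else dt.timezone.utc
    by_day: dict[dt.date, list[float]] = {}
    for r in records:
        if r.status is not ScreeningStatus.ACCEPTED:
            continue
        day = r.timestamp_utc.astimezone(zone).date()
        by_day.setdefault(day, []).append(r.weight_kg)
    return {day: sum(ws) / len(ws) for day, ws in sorted(by_day.items())}


SCREENING_COLUMNS = [
    "participant_id",
    "timestamp",
    "weight_kg",
    "status",
    "reference_weight_kg",
    "reason",
]


def write_screening_report(
    records: Iterable[WeightRecord], sink: Union[str, Path, TextIO]
) -> None:
    """Write screened records to the screening-report CSV."""
    if isinstance(sink, (str, Path)):
        handle: TextIO = open(sink, "w", newline="", encoding="utf-8")
        close = True
    else:
        handle, close = sink, False
    try:
        writer = csv.writer(handle)
        writer.writerow(SCREENING_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.timestamp_utc.isoformat(),
                    f"{r.weight_kg:.3f}",
                    r.status.value,
                    f"{r.reference_weight_kg:.3f}",
                    r.reason or "",
                ]
            )
    finally:
        if close:
            handle.close()


def read_resets(source: Union[str, Path, TextIO]) -> list[ReferenceReset]:
    """Read the resets CSV: participant_id, date, verified_weight_kg, operator_note."""
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source, "r", newline="", encoding="utf-8")
        close = True
    else:
        handle, close = source, False
    try:
        return [
            ReferenceReset(
                participant_id=row["participant_id"].strip(),
                date=dt.date.fromisoformat(row["date"].strip()),
                verified_weight_kg=float(row["verified_weight_kg"]),
                operator_note=(row.get("operator_note") or "").strip(),
            )
            for row in csv.DictReader(handle)
        ]
    finally:
        if close:
            handle.close()
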