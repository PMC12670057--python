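"""Study calendar, arms, phases, and the participant registry.

A trial runs for 78 weeks split into three 26-week phases: phase I
(active weight loss), phase II (weight maintenance), and phase III
(unincentivized follow-up).  Weeks are anchored per participant at their
enrollment date — a rolling cohort — so week 1 always begins on the day a
participant enrolls.  Participants are randomized to one of four arms at
one of two sites, and each receives a cellular scale whose device
identifier (IMEI role) is bound to their participant ID at enrollment.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

PROGRAM_WEEKS = 78
PHASE_LENGTH_WEEKS = 26


class Site(str, Enum):
    """Enrollment site."""

    WI = "WI"
    NC = "NC"


class Arm(str, Enum):
    """Randomized study arm.

    COMBINED receives incentives for both dietary self-monitoring and
    weight loss (partial credit when exactly one criterion is met);
    DIET_ONLY and WEIGHT_ONLY are incentivized on a single criterion;
    CONTROL receives no financial incentives.
    """

    COMBINED = "COMBINED"
    DIET_ONLY = "DIET_ONLY"
    WEIGHT_ONLY = "WEIGHT_ONLY"
    CONTROL = "CONTROL"

    @property
    def incentivized(self) -> bool:
        return self is not Arm.CONTROL


INCENTIVIZED_ARMS = (Arm.COMBINED, Arm.DIET_ONLY, Arm.WEIGHT_ONLY)


class Phase(str, Enum):
    I = "I"
    II = "II"
    III = "III"


class InvalidWeekError(ValueError):
    """Raised for week indices outside 1..78."""


@dataclass(frozen=True)
class Participant:
    """One enrollment record.

    Weights are kilograms internally; ingestion converts device units.
    The timezone recorded at enrollment is authoritative for the whole
    study (no adjustment for travel).
    """

    participant_id: str
    site: Site
    arm: Arm
    timezone: str
    baseline_weight_kg: float
    enrollment_date: dt.date
    scale_device_id: str
    withdrawal_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.baseline_weight_kg <= 0:
            raise ValueError(
                f"baseline_weight_kg must be positive, got {self.baseline_weight_kg}"
            )
        if (
            self.withdrawal_date is not None
            and self.withdrawal_date < self.enrollment_date
        ):
            raise ValueError("withdrawal_date precedes enrollment_date")


@dataclass(frozen=True)
class StudyWeek:
    """One 7-day study week on a participant's personal calendar."""

    week_index: int
    phase: Phase
    start_date: dt.date
    end_date: dt.date


def map_week_to_phase(week_index: int) -> Phase:
    """Map a study week index (1..78) to its phase.

    Weeks 1-26 are phase I, 27-52 phase II, 53-78 phase III.
    """
    if not 1 <= week_index <= PROGRAM_WEEKS:
        raise InvalidWeekError(f"week_index must be in 1..{PROGRAM_WEEKS}, got {week_index}")
    if week_index <= PHASE_LENGTH_WEEKS:
        return Phase.I
    if week_index <= 2 * PHASE_LENGTH_WEEKS:
        return Phase.II
    return Phase.III


def build_calendar(enrollment_date: dt.date) -> list[StudyWeek]:
    """Build the 78 consecutive 7-day study weeks anchored at enrollment.

    Week 1 starts on ``enrollment_date``; weeks are contiguous and cover
    exactly 546 days.
    """
    weeks = []
    for w in range(1, PROGRAM_WEEKS + 1):
        start = enrollment_date + dt.timedelta(days=7 * (w - 1))
        end = start + dt.timedelta(days=6)
        weeks.append(StudyWeek(w, map_week_to_phase(w), start, end))
    return weeks


def week_containing(calendar: Sequence[StudyWeek], on: dt.date) -> StudyWeek | None:
    """Return the study week containing ``on``, or None if outside the program."""
    for wk in calendar:
        if wk.start_date <= on <= wk.end_date:
            return wk
    return None


def is_active(participant: Participant, on: dt.date) -> bool:
    """Whether a participant is active on a given date.

    Inactive before enrollment and on/after the withdrawal date itself
    (withdrawal is exclusive of services that day).
    """
    if on < participant.enrollment_date:
        return False
    if participant.withdrawal_date is not None and on >= participant.withdrawal_date:
        return False
    return True


ROSTER_COLUMNS = [
    "participant_id",
    "site",
    "arm",
    "timezone",
    "baseline_weight_kg",
    "enrollment_date",
    "scale_device_id",
    "withdrawal_date",
]


def _open_maybe(source: Union[str, Path, TextIO]) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", newline="", encoding="utf-8")
    return source


def load_roster(source: Union[str, Path, TextIO]) -> list[Participant]:
    """Load the enrollment roster CSV.

    Columns: participant_id, site, arm, timezone, baseline_weight_kg,
    enrollment_date (ISO 8601), scale_device_id, withdrawal_date
    (optional, may be blank).  Scale device IDs must be unique across
    active participants; duplicates are a hard error.
    """
    handle = _open_maybe(source)
    close = isinstance(source, (str, Path))
    try:
        reader = csv.DictReader(handle)
        participants = []
        for row in reader:
            wd = (row.get("withdrawal_date") or "").strip()
            participants.append(
                Participant(
                    participant_id=row["participant_id"].strip(),
                    site=Site(row["site"].strip()),
                    arm=Arm(row["arm"].strip()),
                    timezone=row["timezone"].strip(),
                    baseline_weight_kg=float(row["baseline_weight_kg"]),
                    enrollment_date=dt.date.fromisoformat(row["enrollment_date"].strip()),
                    scale_device_id=row["scale_device_id"].strip(),
                    withdrawal_date=dt.date.fromisoformat(wd) if wd else None,
                )
            )
    finally:
        if close:
            handle.close()

    seen: dict[str, str] = {}
    for p in participants:
        if p.withdrawal_date is not None:
            continue
        if p.scale_device_id in seen:
            raise ValueError(
                f"scale_device_id {p.scale_device_id!r} bound to both "
                f"{seen[p.scale_device_id]!r} and {p.participant_id!r}"
            )
        seen[p.scale_device_id] = p.participant_id
    return participants


def write_roster(participants: Iterable[Participant], sink: Union[str, Path, TextIO]) -> None:
    """Write participants back to the roster CSV format."""
    handle: TextIO
    if isinstance(sink, (str, Path)):
        handle = open(sink, "w", newline="", encoding="utf-8")
        close = True
    else:
        handle, close = sink, False
    try:
        writer = csv.writer(handle)
        writer.writerow(ROSTER_COLUMNS)
        for p in participants:
            writer.writerow(
                [
                    p.participant_id,
                    p.site.value,
                    p.arm.value,
                    p.timezone,
                    f"{p.baseline_weight_kg:.1f}",
                    p.enrollment_date.isoformat(),
                    p.scale_device_id,
                    p.withdrawal_date.isoformat() if p.withdrawal_date else "",
                ]
            )
    finally:
        if close:
            handle.close()
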