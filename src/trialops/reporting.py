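"""Operational summary statistics and staff-facing reports.

Computes the headline operations numbers a trial team tracks — message
counts by weekday and type, delivery and success rates, weight
acceptance, weigh-ins per weighing day, dietary-log volume, and the
automatic/manual incentive-processing split — and renders them as text,
CSV, or JSON.  Percentages are printed at one decimal with half-up
rounding.
"""

from __future__ import annotations

import datetime as dt
import io
import json
import statistics
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from trialops.incentives import IncentiveDecision, ProcessingMode
from trialops.ingestion import DietDay
from trialops.messaging import Message, compute_delivery_stats
from trialops.screening import ScreeningStatus, WeightRecord

WEEKDAYS = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at the given precision (presentation rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int) -> float:
    """Percentage at one decimal, half-up; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, 1)


@dataclass(frozen=True)
class OpsSummary:
    messages_total: int
    messages_by_weekday_and_type: dict[str, dict[str, int]]
    delivery_rate: float
    success_rate: float
    weights_total: int
    weights_accepted: int
    acceptance_pct: float
    mean_weighins_per_weighing_day: float
    sd_weighins_per_weighing_day: float
    diet_days_total: int
    incentives_total: int
    incentives_auto: int
    auto_pct: float
    incentives_manual: int
    manual_pct: float


def _weighin_stats(
    weight_records: Iterable[WeightRecord], per_participant: bool
) -> tuple[float, float]:
    """Mean/SD of weigh-ins per weighing day.

    A weighing day is a participant-day with at least one transmission,
    accepted or rejected (close-succession re-weighs count).  Default:
    compute each participant's own weigh-ins-per-weighing-day, then
    average across participants; ``per_participant=False`` pools all
    participant-days instead.
    """
    per_day: dict[tuple[str, dt.date], int] = {}
    for r in weight_records:
        key = (r.participant_id, r.timestamp_utc.date())
        per_day[key] = per_day.get(key, 0) + 1
    if not per_day:
        return 0.0, 0.0
    if per_participant:
        by_pid: dict[str, list[int]] = {}
        for (pid, _), n in per_day.items():
            by_pid.setdefault(pid, []).append(n)
        values = [statistics.fmean(v) for v in by_pid.values()]
    else:
        values = [float(n) for n in per_day.values()]
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return mean, sd


def summarize(
    weight_records: Sequence[WeightRecord] = (),
    messages: Sequence[Message] = (),
    diet_days: Sequence[DietDay] = (),
    decisions: Sequence[IncentiveDecision] = (),
    per_participant_weighins: bool = True,
) -> OpsSummary:
    """Compute the operational summary over raw records.

    Empty inputs yield a summary of zeros.  Weekday tallies use each
    message's scheduled local date.
    """
    table: dict[str, dict[str, int]] = {
        d: {t: 0 for t in ("INCENTIVE", "MOTIVATIONAL", "MANUAL")} for d in WEEKDAYS
    }
    for m in messages:
        day = WEEKDAYS[m.scheduled_local.date().weekday()]
        table[day][m.mtype.value] += 1
    stats = compute_delivery_stats(messages)

    weights_total = len(weight_records)
    weights_accepted = sum(
        1 for r in weight_records if r.status is ScreeningStatus.ACCEPTED
    )
    mean_w, sd_w = _weighin_stats(weight_records, per_participant_weighins)

    incentives_total = len(decisions)
    incentives_auto = sum(
        1 for d in decisions if d.processing_mode is ProcessingMode.AUTO
    )
    incentives_manual = incentives_total - incentives_auto

    return OpsSummary(
        messages_total=len(messages),
        messages_by_weekday_and_type=table,
        delivery_rate=stats.delivery_rate,
        success_rate=stats.success_rate,
        weights_total=weights_total,
        weights_accepted=weights_accepted,
        acceptance_pct=pct(weights_accepted, weights_total),
        mean_weighins_per_weighing_day=mean_w,
        sd_weighins_per_weighing_day=sd_w,
        diet_days_total=len(diet_days),
        incentives_total=incentives_total,
        incentives_auto=incentives_auto,
        auto_pct=pct(incentives_auto, incentives_total),
        incentives_manual=incentives_manual,
        manual_pct=pct(incentives_manual, incentives_total),
    )


def peak_day(dates: Iterable[dt.date]) -> tuple[dt.date, int] | None:
    """Date with the most events; ties broken by earliest date.

    Returns None for empty input.
    """
    counts: dict[dt.date, int] = {}
    for d in dates:
        counts[d] = counts.get(d, 0) + 1
    if not counts:
        return None
    best = min(counts, key=lambda d: (-counts[d], d))
    return best, counts[best]


_INT_FIELDS = {
    "messages_total",
    "weights_total",
    "weights_accepted",
    "diet_days_total",
    "incentives_total",
    "incentives_auto",
    "incentives_manual",
}


class UsageError(ValueError):
    """Unknown report format."""


def render_report(summary: OpsSummary, format: str = "text") -> str:
    """Render a summary as 'text', 'csv', or 'json'.

    CSV and JSON renderings round-trip losslessly through
    :func:`parse_report`.
    """
    if format == "json":
        return json.dumps(asdict(summary), indent=2, sort_keys=True)
    if format == "csv":
        buf = io.StringIO()
        buf.write("key,value\n")
        for k, v in asdict(summary).items():
            if k == "messages_by_weekday_and_type":
                for day, types in v.items():
                    for t, n in types.items():
                        buf.write(f"messages_by_weekday_and_type.{day}.{t},{n}\n")
            else:
                buf.write(f"{k},{v!r}\n")
        return buf.getvalue()
    if format == "text":
        lines = ["Operations summary", "=================="]
        d = asdict(summary)
        table = d.pop("messages_by_weekday_and_type")
        for k, v in d.items():
            lines.append(f"{k:34s} {v}")
        lines.append("messages by weekday and type:")
        lines.append("  " + " ".join(f"{day:>6s}" for day in [""] + WEEKDAYS))
        for t in ("INCENTIVE", "MOTIVATIONAL", "MANUAL"):
            row = [f"{table[day][t]:>6d}" for day in WEEKDAYS]
            lines.append(f"  {t[:4]:>6s} " + " ".join(row))
        return "\n".join(lines) + "\n"
    raise UsageError(f"unknown report format {format!r}")


def parse_report(document: str, format: str) -> OpsSummary:
    """Parse a csv/json rendering back to an OpsSummary."""
    if format == "json":
        d = json.loads(document)
        return OpsSummary(**d)
    if format == "csv":
        table: dict[str, dict[str, int]] = {
            d: {t: 0 for t in ("INCENTIVE", "MOTIVATIONAL", "MANUAL")} for d in WEEKDAYS
        }
        fields: dict[str, object] = {"messages_by_weekday_and_type": table}
        for line in document.strip().splitlines()[1:]:
            key, value = line.split(",", 1)
            if key.startswith("messages_by_weekday_and_type."):
                _, day, t = key.split(".")
                table[day][t] = int(value)
            elif key in _INT_FIELDS:
                fields[key] = int(value)
            else:
                fields[key] = float(value)
        return OpsSummary(**fields)  # type: ignore[arg-type]
    raise UsageError(f"unknown report format {format!r}")
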