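"""Synthetic-cohort simulator.

Generates rosters and behavior streams with the statistical structure
the platform must handle — adherence that decays over time, errant
scale transmissions, close-succession re-weighs, delivery failures,
occasional withdrawals — so every other module is exercisable without
trial data.  The latent weight model is intentionally simple (linear
loss during phase I plus Gaussian measurement noise, plateau
afterwards): the platform, not human physiology, is under test.

Outputs are written in exactly the ingestion formats (roster CSV, scale
JSON-lines, diet CSV, receipt-event CSV), so simulator fixtures double
as format documentation.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence
from zoneinfo import ZoneInfo

import numpy as np

from trialops.ingestion import DietDay, DietSource, RawScalePayload, write_diet_log, write_scale_stream
from trialops.messaging import (
    CarrierEvent,
    FailureReason,
    Message,
    MessageType,
    schedule_week,
)
from trialops.trial_core import (
    Arm,
    Participant,
    Phase,
    Site,
    map_week_to_phase,
    write_roster,
)

_SITE_TZ = {Site.WI: "America/Chicago", Site.NC: "America/New_York"}
_ARM_CYCLE = [Arm.COMBINED, Arm.DIET_ONLY, Arm.WEIGHT_ONLY, Arm.CONTROL]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the behavioral simulator.

    Defaults emulate the operating regime a large remote-monitoring
    weight-loss trial reports qualitatively: roughly two weigh-in days a
    week while losing, one while maintaining, about five percent errant
    transmissions well outside the screening band, dietary logging that
    starts high and halves by around day 90, and a message-delivery
    failure rate under one percent.
    """

    n_participants: int = 40
    site_weights: tuple[float, float] = (0.5, 0.5)  # (WI, NC)
    seed: int = 0
    n_weeks: int = 78
    weighin_rate_phase1: float = 2.0   # expected weigh-in days/week
    weighin_rate_phase2: float = 1.0
    repeat_weigh_prob: float = 0.2     # second same-day measurement (re-weigh)
    errant_weight_prob: float = 0.05
    errant_deviation_range: tuple[float, float] = (0.08, 0.15)
    logging_start_prob: float = 0.85
    logging_decay_halflife_days: float = 90.0
    kcal_mean: float = 1900.0
    kcal_sd: float = 350.0
    delivery_failure_prob: float = 0.006
    withdrawal_hazard_per_week: float = 0.002
    trueloss_kg_per_week_phase1: float = 0.35
    weight_noise_sd_kg: float = 0.4
    baseline_weight_mean_kg: float = 95.0
    baseline_weight_sd_kg: float = 14.0
    enrollment_start: dt.date = dt.date(2021, 1, 4)
    wave_size: int = 25                # participants enrolled per weekly wave

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in (
            "errant_weight_prob",
            "logging_start_prob",
            "delivery_failure_prob",
            "withdrawal_hazard_per_week",
            "repeat_weigh_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.errant_deviation_range
        if not 0 < lo <= hi:
            raise ValueError("errant_deviation_range must be a positive interval")
        if not 1 <= self.n_weeks <= 78:
            raise ValueError("n_weeks must be in 1..78")


@dataclass(frozen=True)
class ReceiptEvent:
    """One carrier event for the receipt stream."""

    message_id: str
    event: CarrierEvent
    event_time_utc: dt.datetime
    reason: FailureReason | None = None


@dataclass
class SimulatedCohort:
    """Everything one simulation run produces."""

    config: SimConfig
    participants: list[Participant]
    scale_payloads: list[RawScalePayload]
    diet_days: list[DietDay]
    messages: list[Message]
    receipts: list[ReceiptEvent]


class Scenario(str, Enum):
    """Deterministic perturbations mirroring field failure modes."""

    HOUSEHOLD_MEMBER = "HOUSEHOLD_MEMBER"
    CARRIER_GAP = "CARRIER_GAP"
    SPAM_WAVE = "SPAM_WAVE"
    API_CUTOVER = "API_CUTOVER"


def _simulate_participant_weights(
    p: Participant, cfg: SimConfig, rng: np.random.Generator
) -> list[RawScalePayload]:
    tz = ZoneInfo(p.timezone)
    payloads: list[RawScalePayload] = []
    true0 = p.baseline_weight_kg
    n_days = 7 * cfg.n_weeks
    end = p.withdrawal_date or (p.enrollment_date + dt.timedelta(days=n_days))
    for day in range(n_days):
        date = p.enrollment_date + dt.timedelta(days=day)
        if date >= end:
            break
        week = day // 7 + 1
        phase = map_week_to_phase(week)
        rate = cfg.weighin_rate_phase1 if phase is Phase.I else cfg.weighin_rate_phase2
        if rng.random() >= rate / 7.0:
            continue
        # latent trajectory: linear loss through phase I, plateau after
        weeks_losing = min(day / 7.0, 26.0)
        true_w = true0 - cfg.trueloss_kg_per_week_phase1 * weeks_losing
        n_meas = 2 if rng.random() < cfg.repeat_weigh_prob else 1
        base_seconds = int(rng.integers(6 * 3600, 9 * 3600))
        for j in range(n_meas):
            measured = true_w + rng.normal(0.0, cfg.weight_noise_sd_kg)
            if rng.random() < cfg.errant_weight_prob:
                dev = rng.uniform(*cfg.errant_deviation_range)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                measured = true_w * (1.0 + sign * dev)
            local = dt.datetime.combine(date, dt.time(0), tzinfo=tz) + dt.timedelta(
                seconds=base_seconds + j * 120
            )
            ts_ms = int(local.astimezone(dt.timezone.utc).timestamp() * 1000)
            payloads.append(
                RawScalePayload(
                    device_id=p.scale_device_id,
                    timestamp_utc=ts_ms,
                    weight_g=int(round(measured * 1000)),
                )
            )
    return payloads


def _simulate_participant_diet(
    p: Participant, cfg: SimConfig, rng: np.random.Generator
) -> list[DietDay]:
    days: list[DietDay] = []
    n_days = 7 * cfg.n_weeks
    end = p.withdrawal_date or (p.enrollment_date + dt.timedelta(days=n_days))
    for day in range(n_days):
        date = p.enrollment_date + dt.timedelta(days=day)
        if date >= end:
            break
        prob = cfg.logging_start_prob * 0.5 ** (day / cfg.logging_decay_halflife_days)
        if rng.random() >= prob:
            continue
        kcal = max(0.0, rng.normal(cfg.kcal_mean, cfg.kcal_sd))
        n_entries = 1 + int(rng.poisson(2))
        days.append(
            DietDay(
                participant_id=p.participant_id,
                date=date,
                total_kcal=round(kcal, 1),
                n_entries=n_entries,
                source=DietSource.MFP_VIA_FITBIT,
            )
        )
    return days


_FAIL_REASONS = [
    FailureReason.SPAM_FLAGGED,
    FailureReason.UNREACHABLE,
    FailureReason.OTHER,
]


def _simulate_receipts(
    messages: Sequence[Message], cfg: SimConfig, rng: np.random.Generator
) -> list[ReceiptEvent]:
    events: list[ReceiptEvent] = []
    for m in messages:
        t0 = m.scheduled_local.astimezone(dt.timezone.utc)
        if rng.random() < cfg.delivery_failure_prob:
            reason = _FAIL_REASONS[int(rng.integers(0, len(_FAIL_REASONS)))]
            events.append(ReceiptEvent(m.message_id, CarrierEvent.FAIL, t0, reason))
        else:
            events.append(
                ReceiptEvent(m.message_id, CarrierEvent.ACCEPT, t0 + dt.timedelta(seconds=2))
            )
            events.append(
                ReceiptEvent(
                    m.message_id,
                    CarrierEvent.DELIVERY_RECEIPT,
                    t0 + dt.timedelta(seconds=8),
                )
            )
    return events


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one full synthetic cohort.

    Participants enroll in weekly waves, cycle through the four arms,
    and draw baselines from a truncated normal.  Weigh-in days are
    Bernoulli at the phase rate; errant weights are injected at
    ``errant_weight_prob`` with a multiplicative deviation from the
    configured range; daily logging follows an exponentially decaying
    Bernoulli; messages are scheduled for every simulated week and
    receipts fail at ``delivery_failure_prob``.
    """
    rng = np.random.default_rng(config.seed)
    participants: list[Participant] = []
    for i in range(config.n_participants):
        site = Site.WI if rng.random() < config.site_weights[0] / sum(config.site_weights) else Site.NC
        enrollment = config.enrollment_start + dt.timedelta(days=7 * (i // config.wave_size))
        baseline = max(60.0, rng.normal(config.baseline_weight_mean_kg, config.baseline_weight_sd_kg))
        withdrawal = None
        if config.withdrawal_hazard_per_week > 0:
            for w in range(1, config.n_weeks + 1):
                if rng.random() < config.withdrawal_hazard_per_week:
                    withdrawal = enrollment + dt.timedelta(days=7 * w)
                    break
        participants.append(
            Participant(
                participant_id=f"P{i + 1:04d}",
                site=site,
                arm=_ARM_CYCLE[i % 4],
                timezone=_SITE_TZ[site],
                baseline_weight_kg=round(baseline, 1),
                enrollment_date=enrollment,
                scale_device_id=f"IMEI{i + 1:06d}",
                withdrawal_date=withdrawal,
            )
        )

    payloads: list[RawScalePayload] = []
    diet: list[DietDay] = []
    for p in participants:
        payloads.extend(_simulate_participant_weights(p, config, rng))
        diet.extend(_simulate_participant_diet(p, config, rng))
    payloads.sort(key=lambda q: (q.timestamp_utc, q.device_id))

    messages: list[Message] = []
    for week in range(1, config.n_weeks + 1):
        messages.extend(
            schedule_week(participants, week, holidays=None, rng_seed=config.seed)
        )
    messages.sort(key=lambda m: (m.scheduled_local.astimezone(dt.timezone.utc), m.message_id))
    receipts = _simulate_receipts(messages, config, rng)

    return SimulatedCohort(config, participants, payloads, diet, messages, receipts)


def inject_scenario(cohort: SimulatedCohort, scenario: Scenario) -> SimulatedCohort:
    """Apply a deterministic field-failure perturbation to a cohort.

    HOUSEHOLD_MEMBER: a mid-stream block of the first participant's
    weights shifted ~20% (someone else on the scale).  CARRIER_GAP: the
    first participant's payloads in study week 3 dropped (scale out of
    carrier range).  SPAM_WAVE: every incentive message of week 2 fails
    with a spam flag.  API_CUTOVER: a one-week dietary gap at the study
    midpoint, after which logs arrive via the direct-device source.
    """
    c = cohort
    if scenario is Scenario.HOUSEHOLD_MEMBER:
        pid_device = c.participants[0].scale_device_id
        idx = [i for i, q in enumerate(c.scale_payloads) if q.device_id == pid_device]
        block = idx[len(idx) // 2 : len(idx) // 2 + 5]
        payloads = list(c.scale_payloads)
        for i in block:
            q = payloads[i]
            payloads[i] = replace(q, weight_g=int(round(q.weight_g * 0.8)))
        return replace_cohort(c, scale_payloads=payloads)
    if scenario is Scenario.CARRIER_GAP:
        p = c.participants[0]
        start = p.enrollment_date + dt.timedelta(days=14)
        end = start + dt.timedelta(days=7)
        keep = [
            q
            for q in c.scale_payloads
            if not (
                q.device_id == p.scale_device_id
                and start <= q.datetime_utc.date() < end
            )
        ]
        return replace_cohort(c, scale_payloads=keep)
    if scenario is Scenario.SPAM_WAVE:
        wave_ids = {
            m.message_id
            for m in c.messages
            if m.mtype is MessageType.INCENTIVE and "-w02-" in m.message_id
        }
        receipts: list[ReceiptEvent] = []
        failed: set[str] = set()
        for ev in c.receipts:
            if ev.message_id in wave_ids:
                if ev.message_id not in failed:
                    failed.add(ev.message_id)
                    receipts.append(
                        ReceiptEvent(
                            ev.message_id,
                            CarrierEvent.FAIL,
                            ev.event_time_utc,
                            FailureReason.SPAM_FLAGGED,
                        )
                    )
            else:
                receipts.append(ev)
        return replace_cohort(c, receipts=receipts)
    if scenario is Scenario.API_CUTOVER:
        cut = c.config.enrollment_start + dt.timedelta(days=7 * (c.config.n_weeks // 2))
        gap_end = cut + dt.timedelta(days=7)
        diet: list[DietDay] = []
        for d in c.diet_days:
            if cut <= d.date < gap_end:
                continue
            if d.date >= gap_end:
                d = DietDay(d.participant_id, d.date, d.total_kcal, d.n_entries, DietSource.FITBIT_DIRECT)
            diet.append(d)
        return replace_cohort(c, diet_days=diet)
    raise ValueError(f"unknown scenario {scenario!r}")


def replace_cohort(cohort: SimulatedCohort, **changes) -> SimulatedCohort:
    fields = dict(
        config=cohort.config,
        participants=cohort.participants,
        scale_payloads=cohort.scale_payloads,
        diet_days=cohort.diet_days,
        messages=cohort.messages,
        receipts=cohort.receipts,
    )
    fields.update(changes)
    return SimulatedCohort(**fields)


RECEIPT_COLUMNS = ["message_id", "event", "event_time_utc", "reason"]


def write_receipts(receipts: Sequence[ReceiptEvent], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RECEIPT_COLUMNS)
        for ev in receipts:
            w.writerow(
                [
                    ev.message_id,
                    ev.event.value,
                    ev.event_time_utc.isoformat(),
                    ev.reason.value if ev.reason else "",
                ]
            )


def read_receipts(path) -> list[ReceiptEvent]:
    with open(path, "r", newline="", encoding="utf-8") as fh:
        out = []
        for row in csv.DictReader(fh):
            out.append(
                ReceiptEvent(
                    message_id=row["message_id"],
                    event=CarrierEvent(row["event"]),
                    event_time_utc=dt.datetime.fromisoformat(row["event_time_utc"]),
                    reason=FailureReason(row["reason"]) if row.get("reason") else None,
                )
            )
        return out


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Write the cohort in the ingestion interchange formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": out / "roster.csv",
        "scale": out / "scale.jsonl",
        "diet": out / "diet.csv",
        "receipts": out / "receipts.csv",
    }
    write_roster(cohort.participants, paths["roster"])
    write_scale_stream(cohort.scale_payloads, paths["scale"])
    write_diet_log(cohort.diet_days, paths["diet"])
    write_receipts(cohort.receipts, paths["receipts"])
    return paths
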