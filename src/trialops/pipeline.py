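"""End-to-end glue: simulate or load streams, screen, adjudicate, report.

This module chains the per-module operations into the weekly production
flow: bind scale payloads to participants, run chained screening per
participant, adjudicate every completed phase I/II week, apply carrier
receipt events to the scheduled messages, and summarize operations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

from trialops.incentives import (
    IncentiveConfig,
    IncentiveDecision,
    adjudicate_participant,
)
from trialops.ingestion import DietDay, RawScalePayload, bind_stream
from trialops.messaging import CarrierEvent, Message, record_receipt
from trialops.reporting import OpsSummary, summarize
from trialops.screening import ReferenceReset, WeightRecord, screen_stream
from trialops.simulator import ReceiptEvent, SimulatedCohort
from trialops.trial_core import Participant, Phase, build_calendar, map_week_to_phase


@dataclass
class PipelineResult:
    weight_records: list[WeightRecord]
    unbound_payloads: list[RawScalePayload]
    decisions: list[IncentiveDecision]
    messages: list[Message]
    summary: OpsSummary


def screen_cohort(
    participants: Sequence[Participant],
    payloads: Sequence[RawScalePayload],
    resets: Sequence[ReferenceReset] = (),
) -> tuple[list[WeightRecord], list[RawScalePayload]]:
    """Bind and screen a whole scale stream, participant by participant."""
    bound, unbound = bind_stream(payloads, participants)
    by_pid: dict[str, list] = {}
    for m in bound:
        by_pid.setdefault(m.participant_id, []).append(m)
    resets_by_pid: dict[str, list[ReferenceReset]] = {}
    for r in resets:
        resets_by_pid.setdefault(r.participant_id, []).append(r)
    p_index = {p.participant_id: p for p in participants}
    records: list[WeightRecord] = []
    for pid in sorted(by_pid):
        p = p_index[pid]
        records.extend(
            screen_stream(
                sorted(by_pid[pid], key=lambda m: m.timestamp_utc),
                baseline_kg=p.baseline_weight_kg,
                resets=resets_by_pid.get(pid, ()),
                tz=p.timezone,
            )
        )
    return records, unbound


def apply_receipts(
    messages: Sequence[Message], receipts: Sequence[ReceiptEvent]
) -> list[Message]:
    """Fold carrier events into message states, in event order."""
    by_id = {m.message_id: m for m in messages}
    for ev in sorted(receipts, key=lambda e: (e.event_time_utc, e.message_id)):
        m = by_id.get(ev.message_id)
        if m is None:
            continue
        by_id[ev.message_id] = record_receipt(
            m, ev.event, reason=ev.reason, event_time_utc=ev.event_time_utc
        )
    return [by_id[m.message_id] for m in messages]


def adjudicate_cohort(
    participants: Sequence[Participant],
    weight_records: Sequence[WeightRecord],
    diet_days: Sequence[DietDay],
    config: IncentiveConfig,
    through_week: int | None = None,
    n_weeks: int | None = None,
) -> list[IncentiveDecision]:
    """All phase I/II decisions for every incentivized participant.

    ``through_week`` caps the adjudicated weeks (default: every
    completed phase I/II week in the simulated window ``n_weeks``).
    """
    records_by_pid: dict[str, list[WeightRecord]] = {}
    for r in weight_records:
        records_by_pid.setdefault(r.participant_id, []).append(r)
    diet_by_pid: dict[str, list[DietDay]] = {}
    for d in diet_days:
        diet_by_pid.setdefault(d.participant_id, []).append(d)
    last_week = through_week if through_week is not None else min(n_weeks or 78, 52)
    decisions: list[IncentiveDecision] = []
    for p in sorted(participants, key=lambda q: q.participant_id):
        if not p.arm.incentivized:
            continue
        decisions.extend(
            adjudicate_participant(
                p,
                records_by_pid.get(p.participant_id, ()),
                diet_by_pid.get(p.participant_id, ()),
                config,
                through_week=min(last_week, 52),
            )
        )
    return decisions


def run_pipeline(
    cohort: SimulatedCohort,
    config: IncentiveConfig | None = None,
    resets: Sequence[ReferenceReset] = (),
) -> PipelineResult:
    """Run the full flow over a simulated cohort."""
    config = config or IncentiveConfig()
    records, unbound = screen_cohort(cohort.participants, cohort.scale_payloads, resets)
    decisions = adjudicate_cohort(
        cohort.participants,
        records,
        cohort.diet_days,
        config,
        n_weeks=cohort.config.n_weeks,
    )
    messages = apply_receipts(cohort.messages, cohort.receipts)
    summary = summarize(
        weight_records=records,
        messages=messages,
        diet_days=cohort.diet_days,
        decisions=decisions,
    )
    return PipelineResult(records, unbound, decisions, messages, summary)
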