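import datetime as dt
import re

import pytest
from hypothesis import given, settings, strategies as st

from tests.conftest import make_participant
from trialops.incentives import IncentiveConfig, decide_week
from trialops.messaging import (
    CarrierEvent,
    FailureReason,
    Message,
    MessageStatus,
    MessageType,
    StateError,
    compose_incentive_body,
    compute_delivery_stats,
    record_receipt,
    retry_failed,
    schedule_week,
    us_federal_holidays,
)
from trialops.trial_core import Arm

CFG = IncentiveConfig(amount_full=10.0, amount_partial=5.0)


def by_type(messages):
    out = {}
    for m in messages:
        out.setdefault(m.mtype, []).append(m)
    return out


class TestScheduling:
    def test_incentivized_phase1_week_has_three_messages(self, participant):
        msgs = schedule_week([participant], 2, holidays=set(), rng_seed=1)
        assert len(msgs) == 3
        dates = {m.mtype: m.scheduled_local.date().weekday() for m in msgs}
        assert dates[MessageType.INCENTIVE] == 0  # Monday
        motiv = [m.scheduled_local.date().weekday() for m in by_type(msgs)[MessageType.MOTIVATIONAL]]
        assert sorted(motiv) == [1, 4]  # Tuesday and Friday

    def test_control_gets_motivational_only(self):
        p = make_participant(arm=Arm.CONTROL)
        msgs = schedule_week([p], 2, holidays=set(), rng_seed=1)
        assert {m.mtype for m in msgs} == {MessageType.MOTIVATIONAL}
        assert len(msgs) == 2

    def test_phase3_drops_incentive_message(self, participant):
        msgs = schedule_week([participant], 60, holidays=set(), rng_seed=1)
        assert {m.mtype for m in msgs} == {MessageType.MOTIVATIONAL}

    def test_holiday_monday_shifts_to_tuesday(self, participant):
        monday = dt.date(2021, 1, 11)  # week 2 Monday for 2021-01-04 enrollment
        msgs = schedule_week([participant], 2, holidays={monday}, rng_seed=1)
        inc = by_type(msgs)[MessageType.INCENTIVE][0]
        assert inc.scheduled_local.date() == monday + dt.timedelta(days=1)

    def test_send_window_is_local_morning(self, participant):
        for seed in (0, 1, 2):
            for m in schedule_week([participant], 2, holidays=set(), rng_seed=seed):
                assert 8 <= m.scheduled_local.hour < 11

    def test_send_window_holds_across_dst_transition(self):
        # US DST began 2021-03-14; week 11 of a 2021-01-04 enrollment spans it
        p = make_participant(tz="America/New_York")
        msgs = schedule_week([p], 11, holidays=set(), rng_seed=3)
        assert any(m.scheduled_local.date() >= dt.date(2021, 3, 14) for m in msgs)
        for m in msgs:
            assert 8 <= m.scheduled_local.hour < 11
            assert m.scheduled_local.utcoffset() is not None

    def test_seed_changes_times_but_not_dates_or_counts(self, participant):
        a = schedule_week([participant], 2, holidays=set(), rng_seed=1)
        b = schedule_week([participant], 2, holidays=set(), rng_seed=2)
        assert [m.message_id for m in a] == [m.message_id for m in b]
        assert [m.scheduled_local.date() for m in a] == [m.scheduled_local.date() for m in b]
        assert schedule_week([participant], 2, holidays=set(), rng_seed=1) == a

    def test_withdrawn_participant_gets_no_messages(self):
        p = make_participant(withdrawal=dt.date(2021, 1, 4))
        assert schedule_week([p], 1, holidays=set(), rng_seed=1) == []

    def test_default_holiday_calendar_shifts_mlk_monday(self):
        # MLK day 2021-01-18 is the week-3 Monday for a 2021-01-04 enrollment
        p = make_participant()
        assert dt.date(2021, 1, 18) in us_federal_holidays(2021)
        msgs = schedule_week([p], 3, holidays=None, rng_seed=1)
        inc = by_type(msgs)[MessageType.INCENTIVE][0]
        assert inc.scheduled_local.date() == dt.date(2021, 1, 19)


class TestIncentiveBody:
    def test_templates_by_criteria_pattern(self):
        p = make_participant(arm=Arm.COMBINED)
        full = compose_incentive_body(decide_week(p, 5, True, True, CFG))
        partial = compose_incentive_body(decide_week(p, 5, True, False, CFG))
        none = compose_incentive_body(decide_week(p, 5, False, False, CFG))
        assert len({full, partial, none}) == 3

    @pytest.mark.parametrize("diet,weight", [(True, True), (True, False), (False, False)])
    def test_bodies_are_spam_safe(self, diet, weight):
        p = make_participant(arm=Arm.COMBINED)
        body = compose_incentive_body(decide_week(p, 5, diet, weight, CFG))
        assert not re.search(r"[0-9$]", body)

    def test_control_refused(self):
        p = make_participant(arm=Arm.CONTROL)
        with pytest.raises(ValueError):
            compose_incentive_body(decide_week(p, 5, None, None, CFG))


def queued(message_id="M1", attempt=1):
    return Message(
        message_id=message_id,
        participant_id="P001",
        mtype=MessageType.MOTIVATIONAL,
        scheduled_local=dt.datetime(2021, 1, 5, 9, tzinfo=dt.timezone.utc),
        body="x",
        attempt=attempt,
    )


class TestStateMachine:
    def test_happy_path(self):
        m = record_receipt(queued(), CarrierEvent.ACCEPT)
        assert m.status is MessageStatus.ACCEPTED_BY_CARRIER
        m = record_receipt(m, CarrierEvent.DELIVERY_RECEIPT)
        assert m.status is MessageStatus.DELIVERED

    def test_delivered_is_terminal(self):
        m = record_receipt(record_receipt(queued(), CarrierEvent.ACCEPT), CarrierEvent.DELIVERY_RECEIPT)
        for ev in CarrierEvent:
            with pytest.raises(StateError):
                record_receipt(m, ev, reason=FailureReason.OTHER)

    def test_receipt_before_accept_is_illegal(self):
        with pytest.raises(StateError):
            record_receipt(queued(), CarrierEvent.DELIVERY_RECEIPT)

    def test_fail_requires_reason(self):
        with pytest.raises(ValueError):
            record_receipt(queued(), CarrierEvent.FAIL)

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.sampled_from(list(CarrierEvent)), max_size=8))
    def test_random_event_sequences_never_reach_illegal_state(self, events):
        m = queued()
        for ev in events:
            try:
                m = record_receipt(m, ev, reason=FailureReason.OTHER)
            except StateError:
                continue
            assert m.status in set(MessageStatus)
            if m.status is MessageStatus.DELIVERED:
                assert m.carrier_accepted
            if m.status is MessageStatus.FAILED:
                assert m.failure_reason is not None
            else:
                assert m.failure_reason is None


class TestRetry:
    def failed(self, reason, attempt=1):
        return record_receipt(queued(attempt=attempt), CarrierEvent.FAIL, reason=reason)

    def test_transient_failure_requeued_with_attempt_bump(self):
        (m,) = retry_failed([self.failed(FailureReason.SPAM_FLAGGED)])
        assert m.status is MessageStatus.QUEUED
        assert m.attempt == 2

    @pytest.mark.parametrize("reason", [FailureReason.OPTED_OUT, FailureReason.LANDLINE])
    def test_final_reasons_never_retried(self, reason):
        (m,) = retry_failed([self.failed(reason)])
        assert m.status is MessageStatus.FAILED

    def test_attempt_cap(self):
        (m,) = retry_failed([self.failed(FailureReason.OTHER, attempt=3)], max_attempts=3)
        assert m.status is MessageStatus.FAILED


class TestDeliveryStats:
    def test_published_scale_worked_example(self):
        # 126,082 accepted of 126,283 attempted -> delivery rate ~0.9984
        msgs = [queued(f"M{i}") for i in range(126_283)]
        msgs = [
            record_receipt(m, CarrierEvent.ACCEPT) if i < 126_082 else
            record_receipt(m, CarrierEvent.FAIL, reason=FailureReason.OTHER)
            for i, m in enumerate(msgs)
        ]
        stats = compute_delivery_stats(msgs)
        assert stats.attempted == 126_283
        assert stats.accepted == 126_082
        assert stats.delivery_rate == pytest.approx(126_082 / 126_283)
        assert round(stats.delivery_rate, 4) == 0.9984

    def test_empty_rates_are_zero(self):
        s = compute_delivery_stats([])
        assert (s.delivery_rate, s.success_rate) == (0.0, 0.0)

    def test_all_delivered(self):
        m = record_receipt(record_receipt(queued(), CarrierEvent.ACCEPT), CarrierEvent.DELIVERY_RECEIPT)
        s = compute_delivery_stats([m])
        assert (s.delivery_rate, s.success_rate) == (1.0, 1.0)

    def test_failure_after_acceptance_still_counts_accepted(self):
        m = record_receipt(queued(), CarrierEvent.ACCEPT)
        m = record_receipt(m, CarrierEvent.FAIL, reason=FailureReason.UNREACHABLE)
        s = compute_delivery_stats([m])
        assert s.accepted == 1 and s.delivered == 0
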