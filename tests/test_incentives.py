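import datetime as dt
import itertools

import pytest

from tests.conftest import make_participant
from trialops.incentives import (
    AdjudicationDeferred,
    IncentiveConfig,
    IncentiveDecision,
    ProcessingMode,
    adjudicate_participant,
    decide_week,
    evaluate_diet_criterion,
    evaluate_weight_criterion_phase1,
    evaluate_weight_criterion_phase2,
    mark_manual,
    run_weekly_batch,
)
from trialops.ingestion import BoundMeasurement, DietDay
from trialops.screening import screen_stream
from trialops.trial_core import Arm, Phase, map_week_to_phase

UTC = dt.timezone.utc
CFG = IncentiveConfig(amount_full=10.0, amount_partial=5.0)


def diet_week(kcals, pid="P001", start=dt.date(2021, 2, 1)):
    return [
        DietDay(pid, start + dt.timedelta(days=i), kcal, 2 if kcal else 0)
        for i, kcal in enumerate(kcals)
    ]


class TestDietCriterion:
    def test_five_good_days_meet_default(self):
        assert evaluate_diet_criterion(diet_week([1800] * 5), CFG)

    def test_low_calorie_day_does_not_count(self):
        assert not evaluate_diet_criterion(diet_week([1800] * 4 + [300]), CFG)

    def test_empty_week_fails(self):
        assert not evaluate_diet_criterion([], CFG)

    def test_requirement_is_configurable(self):
        cfg = IncentiveConfig(diet_days_required_per_week=3, amount_full=10, amount_partial=5)
        assert evaluate_diet_criterion(diet_week([1800] * 3), cfg)


def days(weights, start=dt.date(2021, 2, 1)):
    return {start + dt.timedelta(days=2 * i): w for i, w in enumerate(weights)}


class TestPhase1WeightCriterion:
    def test_new_weekly_low_with_enough_weighins(self):
        assert evaluate_weight_criterion_phase1(days([99.3, 99.5]), [100.0], CFG)

    def test_no_change_fails_strict_decrease(self):
        assert not evaluate_weight_criterion_phase1(days([100.0, 100.0]), [100.0], CFG)

    def test_too_few_weighin_days_fails_despite_loss(self):
        assert not evaluate_weight_criterion_phase1(days([95.0]), [100.0], CFG)

    def test_ratchet_uses_all_time_low(self):
        # lost to 98 previously, regained: beating last week is not enough
        assert not evaluate_weight_criterion_phase1(days([99.0, 99.0]), [100.0, 98.0, 99.5], CFG)

    def test_prior_week_rule_when_ratchet_disabled(self):
        cfg = IncentiveConfig(ratchet_phase1=False, amount_full=10, amount_partial=5)
        assert evaluate_weight_criterion_phase1(days([99.0, 99.0]), [100.0, 98.0, 99.5], cfg)


class TestPhase2WeightCriterion:
    def test_within_band(self):
        assert evaluate_weight_criterion_phase2(days([91.0]), 90.0, CFG)

    def test_outside_band(self):
        assert not evaluate_weight_criterion_phase2(days([92.0]), 90.0, CFG)

    def test_no_weighins_fails(self):
        assert not evaluate_weight_criterion_phase2({}, 90.0, CFG)

    def test_missing_anchor_defers_to_manual(self):
        with pytest.raises(AdjudicationDeferred):
            evaluate_weight_criterion_phase2(days([91.0]), None, CFG)


def expected_amount(arm, phase, diet, weight):
    """Independent statement of the payment rules."""
    if arm is Arm.CONTROL or phase is Phase.III:
        return 0.0
    if arm is Arm.DIET_ONLY:
        return 10.0 if diet else 0.0
    if arm is Arm.WEIGHT_ONLY:
        return 10.0 if weight else 0.0
    return {0: 0.0, 1: 5.0, 2: 10.0}[int(diet) + int(weight)]


@pytest.mark.parametrize(
    "arm,week,diet,weight",
    list(
        itertools.product(
            list(Arm), [5, 30, 60], [False, True], [False, True]
        )
    ),
)
def test_decision_truth_table(arm, week, diet, weight):
    p = make_participant(arm=arm)
    d = decide_week(p, week, diet, weight, CFG)
    assert d.amount == expected_amount(arm, map_week_to_phase(week), diet, weight)
    if arm is Arm.DIET_ONLY and map_week_to_phase(week) is not Phase.III:
        assert d.weight_criterion_met is None
    if arm is Arm.WEIGHT_ONLY and map_week_to_phase(week) is not Phase.III:
        assert d.diet_criterion_met is None


def test_combined_monotone_in_criteria_met():
    p = make_participant(arm=Arm.COMBINED)
    amounts = {
        (d, w): decide_week(p, 5, d, w, CFG).amount
        for d in (False, True)
        for w in (False, True)
    }
    assert amounts[(False, False)] <= amounts[(True, False)] <= amounts[(True, True)]
    assert amounts[(False, False)] <= amounts[(False, True)] <= amounts[(True, True)]


class TestMarkManual:
    def make_decision(self):
        return decide_week(make_participant(arm=Arm.COMBINED), 5, False, False, CFG)

    def test_override_preserves_audit_trail(self):
        d = mark_manual(self.make_decision(), "device outage week", amount_override=10.0)
        assert d.processing_mode is ProcessingMode.MANUAL
        assert d.amount == 10.0
        assert len(d.audit) == 2
        assert d.audit[0] == ("AUTO", 0.0, "")

    def test_empty_note_refused(self):
        with pytest.raises(ValueError):
            mark_manual(self.make_decision(), "  ")

    def test_control_payment_refused(self):
        d = decide_week(make_participant(arm=Arm.CONTROL), 5, None, None, CFG)
        with pytest.raises(ValueError):
            mark_manual(d, "attempted override", amount_override=10.0)


def scale_week(pid, weights_by_day, enrollment=dt.date(2021, 1, 4)):
    """BoundMeasurements at 9 AM UTC on given (day_offset, weight) pairs."""
    return [
        BoundMeasurement(
            pid,
            dt.datetime.combine(enrollment + dt.timedelta(days=off), dt.time(15), tzinfo=UTC),
            w,
        )
        for off, w in weights_by_day
    ]


def adjudicate(p, weighins, diet_days, through_week=2):
    records = screen_stream(sorted(weighins, key=lambda m: m.timestamp_utc), p.baseline_weight_kg)
    return adjudicate_participant(p, records, diet_days, CFG, through_week)


def test_adjudication_pays_for_loss_against_baseline():
    p = make_participant(arm=Arm.WEIGHT_ONLY, baseline=100.0)
    weighins = scale_week("P001", [(0, 99.4), (2, 99.2), (7, 98.8), (9, 98.6)])
    decisions = adjudicate(p, weighins, [])
    assert [d.amount for d in decisions] == [10.0, 10.0]


def test_rejected_weights_change_no_decision():
    p = make_participant(arm=Arm.WEIGHT_ONLY, baseline=100.0)
    base = scale_week("P001", [(0, 99.4), (2, 99.2), (7, 98.8), (9, 98.6)])
    junk = scale_week("P001", [(1, 140.0), (3, 150.0), (8, 60.0), (9, 130.0)])
    clean = adjudicate(p, base, [])
    noisy = adjudicate(p, base + junk, [])
    assert [(d.week_index, d.amount) for d in clean] == [
        (d.week_index, d.amount) for d in noisy
    ]


def test_missing_anchor_routes_phase2_week_to_manual():
    p = make_participant(arm=Arm.WEIGHT_ONLY, baseline=100.0)
    # no phase-I weights at all; one weigh-in during week 27
    weighins = scale_week("P001", [(26 * 7 + 1, 97.0)])
    decisions = adjudicate(p, weighins, [], through_week=27)
    wk27 = next(d for d in decisions if d.week_index == 27)
    assert wk27.processing_mode is ProcessingMode.MANUAL
    assert wk27.amount == 0.0


def test_weekly_batch_skips_control_and_withdrawn(four_arm_roster):
    withdrawn = make_participant(
        pid="P005", arm=Arm.COMBINED, device="IMEI000005", withdrawal=dt.date(2021, 1, 6)
    )
    roster = four_arm_roster + [withdrawn]
    decisions, queue = run_weekly_batch(roster, {}, {}, dt.date(2021, 1, 10), CFG)
    assert {d.participant_id for d in decisions} == {"P001", "P002", "P003"}
    assert queue == []  # nobody met anything with no data


def test_weekly_batch_is_deterministic(four_arm_roster):
    weights = {
        "P003": screen_stream(
            scale_week("P003", [(0, 99.0), (2, 98.8)]), 100.0
        )
    }
    diet = {"P001": diet_week([1800] * 7, pid="P001", start=dt.date(2021, 1, 4))}
    args = (four_arm_roster, weights, diet, dt.date(2021, 1, 10), CFG)
    d1, q1 = run_weekly_batch(*args)
    d2, q2 = run_weekly_batch(*args)
    assert d1 == d2 and q1 == q2
    assert sum(e.amount for e in q1) == sum(d.amount for d in d1)
    paid = {e.participant_id for e in q1}
    assert paid == {"P001", "P003"}  # diet-partial combined + weight-only full
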