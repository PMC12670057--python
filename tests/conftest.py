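import datetime as dt

import pytest

from trialops.trial_core import Arm, Participant, Site


def make_participant(
    pid="P001",
    arm=Arm.COMBINED,
    site=Site.WI,
    tz="America/Chicago",
    baseline=100.0,
    enrollment=dt.date(2021, 1, 4),
    device="IMEI000001",
    withdrawal=None,
):
    return Participant(
        participant_id=pid,
        site=site,
        arm=arm,
        timezone=tz,
        baseline_weight_kg=baseline,
        enrollment_date=enrollment,
        scale_device_id=device,
        withdrawal_date=withdrawal,
    )


@pytest.fixture
def participant():
    return make_participant()


@pytest.fixture
def four_arm_roster():
    """One participant per arm, enrolled the same Monday."""
    return [
        make_participant(pid=f"P{i+1:03d}", arm=arm, device=f"IMEI{i+1:06d}")
        for i, arm in enumerate([Arm.COMBINED, Arm.DIET_ONLY, Arm.WEIGHT_ONLY, Arm.CONTROL])
    ]
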