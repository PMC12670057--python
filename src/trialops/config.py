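"""Study configuration file (YAML).

Schema::

    screening:
      threshold: 0.03          # relative deviation; strictly-greater rejects
    incentives:
      diet_days_required_per_week: 5
      min_kcal_per_logging_day: 500
      weighins_required_phase1: 2
      weighins_required_phase2: 1
      maintenance_band_fraction: 0.02
      amount_full: 1.0
      amount_partial: 0.5
      ratchet_phase1: true
    holidays:                  # optional; omit to use US federal holidays
      - 2021-01-01
      - 2021-05-31

All keys are optional; omitted keys take the package defaults.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from trialops.incentives import IncentiveConfig
from trialops.screening import DEFAULT_THRESHOLD


@dataclass(frozen=True)
class StudyConfig:
    incentives: IncentiveConfig = field(default_factory=IncentiveConfig)
    screening_threshold: float = DEFAULT_THRESHOLD
    holidays: frozenset[dt.date] | None = None  # None -> US federal calendar


def load_config(path: str | Path) -> StudyConfig:
    """Load a study configuration YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    inc = IncentiveConfig(**(raw.get("incentives") or {}))
    screening = raw.get("screening") or {}
    holidays = raw.get("holidays")
    parsed_holidays = None
    if holidays is not None:
        parsed_holidays = frozenset(
            d if isinstance(d, dt.date) else dt.date.fromisoformat(str(d))
            for d in holidays
        )
    return StudyConfig(
        incentives=inc,
        screening_threshold=float(screening.get("threshold", DEFAULT_THRESHOLD)),
        holidays=parsed_holidays,
    )
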