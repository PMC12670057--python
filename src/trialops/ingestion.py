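"""Parse device-style data streams into validated domain records.

Cellular scales transmit weights autonomously over the mobile network;
the wire format modeled here is JSON-lines with a device identifier,
an epoch-millisecond UTC timestamp, and an integer weight in grams.
Dietary logs arrive as CSV of participant-day totals, historically via a
MyFitnessPal-to-Fitbit sync chain that produced duplicate rows, so
duplicates are merged rather than rejected.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from trialops.trial_core import Participant

logger = logging.getLogger(__name__)

# Physiological plausibility gate in grams: removes non-human artifacts
# (untared scales, objects placed on the platform) before any screening.
MIN_PLAUSIBLE_G = 20_000
MAX_PLAUSIBLE_G = 300_000


@dataclass(frozen=True)
class RawScalePayload:
    """One scale transmission as it arrives off the wire."""

    device_id: str
    timestamp_utc: int  # epoch milliseconds
    weight_g: int

    @property
    def weight_kg(self) -> float:
        return self.weight_g / 1000.0

    @property
    def datetime_utc(self) -> dt.datetime:
        return dt.datetime.fromtimestamp(self.timestamp_utc / 1000.0, tz=dt.timezone.utc)

    def to_json(self) -> str:
        return json.dumps(
            {
                "device_id": self.device_id,
                "timestamp_utc": self.timestamp_utc,
                "weight_g": self.weight_g,
            },
            separators=(",", ":"),
        )


class DietSource(str, Enum):
    MFP_VIA_FITBIT = "MFP_VIA_FITBIT"
    FITBIT_DIRECT = "FITBIT_DIRECT"


@dataclass(frozen=True)
class DietDay:
    """One participant-day of dietary logging."""

    participant_id: str
    date: dt.date
    total_kcal: float
    n_entries: int
    source: DietSource = DietSource.MFP_VIA_FITBIT

    def __post_init__(self) -> None:
        if self.total_kcal < 0:
            raise ValueError(f"total_kcal must be nonnegative, got {self.total_kcal}")
        if self.n_entries < 0:
            raise ValueError(f"n_entries must be nonnegative, got {self.n_entries}")
        if self.n_entries == 0 and self.total_kcal != 0:
            raise ValueError("n_entries = 0 requires total_kcal = 0")


@dataclass(frozen=True)
class BoundMeasurement:
    """A scale payload matched to a participant, in study units."""

    participant_id: str
    timestamp_utc: dt.datetime
    weight_kg: float


@dataclass
class ScaleParseResult:
    payloads: list[RawScalePayload]
    n_skipped_malformed: int
    n_dropped_implausible: int


def _iter_lines(source: Union[str, Path, TextIO, Iterable[str]]) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def parse_scale_stream(
    source: Union[str, Path, TextIO, Iterable[str]]
) -> ScaleParseResult:
    """Parse a JSON-lines scale stream.

    Malformed lines are logged and skipped; weights outside the 20-300 kg
    plausibility gate are dropped with a warning.  Valid payloads are
    returned in timestamp order.
    """
    payloads: list[RawScalePayload] = []
    skipped = 0
    dropped = 0
    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
            payload = RawScalePayload(
                device_id=str(obj["device_id"]),
                timestamp_utc=int(obj["timestamp_utc"]),
                weight_g=int(obj["weight_g"]),
            )
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            logger.warning("skipping malformed scale line %d: %s", lineno, exc)
            skipped += 1
            continue
        if not MIN_PLAUSIBLE_G <= payload.weight_g <= MAX_PLAUSIBLE_G:
            logger.warning(
                "dropping implausible weight %d g on device %s (line %d)",
                payload.weight_g,
                payload.device_id,
                lineno,
            )
            dropped += 1
            continue
        payloads.append(payload)
    payloads.sort(key=lambda p: p.timestamp_utc)
    return ScaleParseResult(payloads, skipped, dropped)


def write_scale_stream(
    payloads: Iterable[RawScalePayload], sink: Union[str, Path, TextIO]
) -> None:
    """Write payloads back to the JSON-lines interchange format."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            for p in payloads:
                fh.write(p.to_json() + "\n")
    else:
        for p in payloads:
            sink.write(p.to_json() + "\n")


def build_device_index(registry: Sequence[Participant]) -> dict[str, Participant]:
    """Index participants by device ID, erroring on shared devices."""
    index: dict[str, Participant] = {}
    for p in registry:
        if p.scale_device_id in index:
            raise ValueError(
                f"device {p.scale_device_id!r} registered to multiple participants"
            )
        index[p.scale_device_id] = p
    return index


def bind_device(
    payload: RawScalePayload, registry: Sequence[Participant] | dict[str, Participant]
) -> BoundMeasurement | None:
    """Match a payload to its participant by device ID.

    Returns None (the unbound marker) for unknown devices, which are
    routed to staff review rather than silently discarded.
    """
    index = registry if isinstance(registry, dict) else build_device_index(registry)
    participant = index.get(payload.device_id)
    if participant is None:
        return None
    return BoundMeasurement(
        participant_id=participant.participant_id,
        timestamp_utc=payload.datetime_utc,
        weight_kg=payload.weight_kg,
    )


def bind_stream(
    payloads: Iterable[RawScalePayload], registry: Sequence[Participant]
) -> tuple[list[BoundMeasurement], list[RawScalePayload]]:
    """Bind a whole stream; returns (bound measurements, unbound payloads)."""
    index = build_device_index(registry)
    bound: list[BoundMeasurement] = []
    unbound: list[RawScalePayload] = []
    for payload in payloads:
        m = bind_device(payload, index)
        if m is None:
            unbound.append(payload)
        else:
            bound.append(m)
    return bound, unbound


DIET_COLUMNS = ["participant_id", "date", "total_kcal", "n_entries", "source"]


def read_diet_log(source: Union[str, Path, TextIO]) -> list[DietDay]:
    """Read the daily dietary-log CSV.

    One DietDay per participant-date; duplicate participant-date rows are
    merged by summing kcal and entry counts (with a warning), reflecting
    the duplicate-prone app-sync chain.  Negative kcal is a validation
    error.
    """
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source, "r", newline="", encoding="utf-8")
        close = True
    else:
        handle, close = source, False
    merged: dict[tuple[str, dt.date], dict] = {}
    try:
        reader = csv.DictReader(handle)
        for row in reader:
            kcal = float(row["total_kcal"])
            if kcal < 0:
                raise ValueError(
                    f"negative total_kcal {kcal} for {row['participant_id']}"
                )
            key = (row["participant_id"].strip(), dt.date.fromisoformat(row["date"].strip()))
            source_val = DietSource(row.get("source") or DietSource.MFP_VIA_FITBIT)
            if key in merged:
                logger.warning("merging duplicate diet rows for %s on %s", *key)
                merged[key]["total_kcal"] += kcal
                merged[key]["n_entries"] += int(row["n_entries"])
            else:
                merged[key] = {
                    "total_kcal": kcal,
                    "n_entries": int(row["n_entries"]),
                    "source": source_val,
                }
    finally:
        if close:
            handle.close()
    return [
        DietDay(pid, date, v["total_kcal"], v["n_entries"], v["source"])
        for (pid, date), v in sorted(merged.items())
    ]


def write_diet_log(days: Iterable[DietDay], sink: Union[str, Path, TextIO]) -> None:
    """Write DietDay records to the diet-log CSV format."""
    if isinstance(sink, (str, Path)):
        handle: TextIO = open(sink, "w", newline="", encoding="utf-8")
        close = True
    else:
        handle, close = sink, False
    try:
        writer = csv.writer(handle)
        writer.writerow(DIET_COLUMNS)
        for d in days:
            writer.writerow(
                [d.participant_id, d.date.isoformat(), f"{d.total_kcal:g}", d.n_entries, d.source.value]
            )
    finally:
        if close:
            handle.close()
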