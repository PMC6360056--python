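"""Timeframe-based encounter assignment.

The source system has no usable visit/encounter identifier for most tables,
so the transplantation identifier serves as the i2b2 encounter number. Facts
without a foreign key toward the transplantation table are attached by
*timeframes*: each transplantation owns the interval from 14 days before the
transplant date to 14 days after organ failure; a never-failed graft's window
stays open until the next transplantation's window begins. Facts falling
outside every window receive a deterministic negative *surrogate* encounter
id — one per (patient, inter-window gap) — so no fact is ever dropped.

Boundary convention: both closed ends are inclusive ("two weeks" = exactly 14
calendar days). When a failed graft's +14-day tail overlaps the next
transplant's −14-day lead, the window with the later start (the more recent
transplantation) wins.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "EXTENSION_DAYS",
    "Timeframe",
    "SurrogateRegistry",
    "TransplantRecord",
    "AmbiguousTransplantError",
    "TemporalIntegrityError",
    "build_timeframes",
    "assign_encounter",
    "assign_encounter_with_rule",
    "surrogate_for",
]

#: Window extension on either side of the transplant episode, in calendar
#: days ("two weeks before the transplantation ... two weeks after a possible
#: organ failure").
EXTENSION_DAYS = 14

_EXT = dt.timedelta(days=EXTENSION_DAYS)


class AmbiguousTransplantError(ValueError):
    """Two transplants of one patient share a date; windows cannot be ordered."""


class TemporalIntegrityError(ValueError):
    """A failure date precedes its transplant date."""


@dataclass(frozen=True)
class TransplantRecord:
    transplant_id: int
    date: dt.date
    failure_date: Optional[dt.date] = None


@dataclass(frozen=True)
class Timeframe:
    """One transplantation's encounter window.

    ``window_end`` is the inclusive closed end (failure + 14 days) or ``None``
    for an open window; ``truncated_at`` is the exclusive cut imposed on an
    open window by the next transplantation's window start. A failed graft's
    tail is never truncated — it may overlap the next window's lead, which
    the assignment tie-break resolves.
    """

    encounter_id: int
    patient_id: int
    window_start: dt.date
    transplant_date: dt.date
    failure_date: Optional[dt.date] = None
    window_end: Optional[dt.date] = None
    truncated_at: Optional[dt.date] = None

    def contains(self, day: dt.date) -> bool:
        if day < self.window_start:
            return False
        if self.window_end is not None:
            return day <= self.window_end
        if self.truncated_at is not None:
            return day < self.truncated_at
        return True


def build_timeframes(
    patient_id: int, transplants: Sequence[TransplantRecord]
) -> list[Timeframe]:
    """Build the ordered window list for one patient.

    ``transplants`` must be sorted by date (the function verifies this and
    rejects duplicate dates). Non-failed windows are open-ended but cut
    (exclusively) at the next window's start; failed windows end exactly 14
    days after the failure date regardless of later transplants.
    """
    for a, b in zip(transplants, transplants[1:]):
        if a.date == b.date:
            raise AmbiguousTransplantError(
                f"patient {patient_id}: transplants {a.transplant_id} and "
                f"{b.transplant_id} share date {a.date}"
            )
        if a.date > b.date:
            raise ValueError(f"patient {patient_id}: transplants not sorted by date")
    frames: list[Timeframe] = []
    for i, rec in enumerate(transplants):
        if rec.failure_date is not None and rec.failure_date < rec.date:
            raise TemporalIntegrityError(
                f"patient {patient_id}: transplant {rec.transplant_id} failure "
                f"date {rec.failure_date} precedes transplant date {rec.date}"
            )
        start = rec.date - _EXT
        end = rec.failure_date + _EXT if rec.failure_date is not None else None
        trunc = None
        if end is None and i + 1 < len(transplants):
            trunc = transplants[i + 1].date - _EXT
        frames.append(
            Timeframe(
                encounter_id=rec.transplant_id,
                patient_id=patient_id,
                window_start=start,
                transplant_date=rec.date,
                failure_date=rec.failure_date,
                window_end=end,
                truncated_at=trunc,
            )
        )
    return frames


class SurrogateRegistry:
    """Deterministic negative surrogate encounter ids, one per (patient, gap).

    Ids are a pure function of the patient's rank (sorted patient ids at
    construction) and the gap index, so they are stable under any fact
    processing order. Gap index 0 is the stretch before the first window;
    gap k the stretch after window k.
    """

    def __init__(self, windows_per_patient: Mapping[int, int]):
        self._offsets: dict[int, int] = {}
        self._slots: dict[int, int] = {}
        offset = 0
        for pid in sorted(windows_per_patient):
            n_gaps = windows_per_patient[pid] + 1
            self._offsets[pid] = offset
            self._slots[pid] = n_gaps
            offset += n_gaps
        self.issued: dict[tuple[int, int], int] = {}

    def surrogate_for(self, patient_id: int, gap_index: int) -> int:
        if patient_id not in self._offsets:
            raise KeyError(f"patient {patient_id} not registered")
        if not 0 <= gap_index < self._slots[patient_id]:
            raise ValueError(
                f"patient {patient_id}: gap index {gap_index} out of range "
                f"(0..{self._slots[patient_id] - 1})"
            )
        sid = -(self._offsets[patient_id] + gap_index + 1)
        self.issued[(patient_id, gap_index)] = sid
        return sid


def surrogate_for(registry: SurrogateRegistry, patient_id: int, gap_index: int) -> int:
    return registry.surrogate_for(patient_id, gap_index)


def _gap_index(timeframes: Sequence[Timeframe], day: dt.date) -> int:
    return sum(1 for tf in timeframes if tf.window_start <= day)


def assign_encounter_with_rule(
    patient_id: int,
    fact_date: dt.date,
    timeframes: Sequence[Timeframe],
    registry: SurrogateRegistry,
) -> tuple[int, str]:
    """Assign an encounter id, returning (id, rule label).

    Rule labels: ``WINDOW`` (unique containing window), ``OVERLAP_TIEBREAK``
    (several windows contain the date; the latest window_start wins),
    ``SURROGATE`` (no window contains it). Total: every (patient, date) gets
    an encounter.
    """
    containing = [tf for tf in timeframes if tf.contains(fact_date)]
    if len(containing) == 1:
        return containing[0].encounter_id, "WINDOW"
    if containing:
        winner = max(containing, key=lambda tf: tf.window_start)
        return winner.encounter_id, "OVERLAP_TIEBREAK"
    gap = _gap_index(timeframes, fact_date)
    return registry.surrogate_for(patient_id, gap), "SURROGATE"


def assign_encounter(
    patient_id: int,
    fact_date: dt.date,
    timeframes: Sequence[Timeframe],
    registry: SurrogateRegistry,
) -> int:
    return assign_encounter_with_rule(patient_id, fact_date, timeframes, registry)[0]
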