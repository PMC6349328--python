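"""Measurement-and-action log containers shared across modules."""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .protocol import BGCategory, Frailty


@dataclass(slots=True)
class BGRecord:
    """One timestamped BG measurement with its prescribed and applied action.

    ``prescribed_rate`` may be NaN when no rate prescription accompanied
    the measurement; ``actual_gap`` is NaN for the final record of a
    patient (no subsequent measurement).
    """

    patient_id: str
    time: float  # hours since infusion start
    bg: float  # mg/dl
    category: BGCategory
    prescribed_rate: float  # units/h (NaN = no prescription)
    applied_rate: float  # units/h
    bolus_g: float  # grams of rescue glucose actually given
    prescribed_next_check: float  # hours
    actual_gap: float  # hours to the next measurement (NaN for last)


@dataclass
class TrialDataset:
    """Per-arm collection of patient logs.

    ``records`` maps patient id to its time-ordered list of
    :class:`BGRecord`; ``profiles`` maps patient id to frailty status;
    ``infusion_end`` to the time of the last measurement.
    """

    arm: str
    records: dict[str, list[BGRecord]]
    profiles: dict[str, Frailty]
    infusion_end: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.records:
            raise ValueError("dataset has no patients")
        for pid, recs in self.records.items():
            if not recs:
                raise ValueError(f"patient {pid} has no records")
            if pid not in self.profiles:
                raise ValueError(f"patient {pid} has no profile")
            times = [r.time for r in recs]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"patient {pid}: times not strictly increasing")
            if any(r.applied_rate < 0 for r in recs):
                raise ValueError(f"patient {pid}: negative applied rate")

    @property
    def n_patients(self) -> int:
        return len(self.records)

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self.records.values())

    def all_records(self) -> list[BGRecord]:
        out: list[BGRecord] = []
        for recs in self.records.values():
            out.extend(recs)
        return out

    def per_day_measurements(self) -> list[float]:
        """Mean measurements per 24 h of infusion, one value per patient."""
        out = []
        for pid, recs in self.records.items():
            span = self.infusion_end.get(pid, recs[-1].time)
            days = max(span / 24.0, 1.0)  # sub-day infusions count as one day
            out.append(len(recs) / days)
        return out
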