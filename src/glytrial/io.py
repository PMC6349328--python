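"""Readers and writers for BG logs, configs and evaluation reports.

One delimited text format (comma-separated, UTF-8, decimal point) serves
both simulated and imported real-world logs so the evaluation code path
stays single.  Times are fractional hours since infusion start.
"""
from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .patients import CohortSpec
from .protocol import (
    BGCategory,
    Frailty,
    ProtocolConfig,
    classify_bg,
)
from .records import BGRecord, TrialDataset
from .trial import ComplianceModel

LOG_COLUMNS = [
    "patient_id",
    "arm",
    "profile",
    "time_h",
    "bg_mgdl",
    "category",
    "prescribed_rate_uh",
    "applied_rate_uh",
    "bolus_g",
    "prescribed_gap_h",
    "actual_gap_h",
]


class ParseError(ValueError):
    """A log file failed schema or consistency validation."""


def write_log(dataset: TrialDataset, path) -> None:
    """Write a dataset to the delimited BG-log format."""
    rows = []
    for pid, recs in dataset.records.items():
        prof = dataset.profiles[pid].value
        for r in recs:
            rows.append(
                (
                    pid,
                    dataset.arm,
                    prof,
                    r.time,
                    r.bg,
                    r.category.value,
                    r.prescribed_rate,
                    r.applied_rate,
                    r.bolus_g,
                    r.prescribed_next_check,
                    r.actual_gap,
                )
            )
    # %.17g guarantees binary round-trip of doubles through the text format
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_log(path) -> TrialDataset:
    """Read and validate a BG log.

    Raises :class:`ParseError` (naming the offending line where
    applicable) on missing columns, non-monotone per-patient times,
    non-positive BG or negative rates.  Rows whose stored category
    disagrees with re-classification are accepted but counted in
    ``dataset.warnings``.
    """
    # round_trip parsing keeps write -> read an exact identity on doubles
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records: dict[str, list[BGRecord]] = {}
    profiles: dict[str, Frailty] = {}
    infusion_end: dict[str, float] = {}
    warnings: list[str] = []
    arms = df["arm"].unique().tolist()
    if len(arms) != 1:
        raise ParseError(f"{path}: expected a single arm per file, got {arms}")
    last_time: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        pid = str(row.patient_id)
        try:
            profile = Frailty(row.profile)
            category = BGCategory(row.category)
        except ValueError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from None
        if row.bg_mgdl <= 0:
            raise ParseError(f"{path}:{line}: non-positive bg {row.bg_mgdl}")
        if row.applied_rate_uh < 0:
            raise ParseError(f"{path}:{line}: negative applied rate")
        if pid in last_time and row.time_h <= last_time[pid]:
            raise ParseError(
                f"{path}:{line}: time {row.time_h} not after {last_time[pid]} "
                f"for patient {pid}"
            )
        last_time[pid] = row.time_h
        if pid in profiles and profiles[pid] != profile:
            raise ParseError(f"{path}:{line}: profile changes for patient {pid}")
        profiles[pid] = profile
        expected = classify_bg(row.bg_mgdl, profile)
        if expected is not category:
            warnings.append(
                f"{path}:{line}: category {category.value} inconsistent with "
                f"thresholds (expected {expected.value})"
            )
        records.setdefault(pid, []).append(
            BGRecord(
                patient_id=pid,
                time=float(row.time_h),
                bg=float(row.bg_mgdl),
                category=category,
                prescribed_rate=float(row.prescribed_rate_uh)
                if not pd.isna(row.prescribed_rate_uh)
                else math.nan,
                applied_rate=float(row.applied_rate_uh),
                bolus_g=float(row.bolus_g) if not pd.isna(row.bolus_g) else 0.0,
                prescribed_next_check=float(row.prescribed_gap_h)
                if not pd.isna(row.prescribed_gap_h)
                else math.nan,
                actual_gap=float(row.actual_gap_h)
                if not pd.isna(row.actual_gap_h)
                else math.nan,
            )
        )
        infusion_end[pid] = float(row.time_h)
    ds = TrialDataset(
        arm=str(arms[0]),
        records=records,
        profiles=profiles,
        infusion_end=infusion_end,
        warnings=warnings,
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# configs and reports


def save_config(model, path) -> None:
    Path(path).write_text(model.model_dump_json(indent=2))


def load_protocol_config(path) -> ProtocolConfig:
    return ProtocolConfig.model_validate_json(Path(path).read_text())


def load_cohort_spec(path) -> CohortSpec:
    return CohortSpec.model_validate_json(Path(path).read_text())


def load_compliance(path) -> ComplianceModel:
    return ComplianceModel.model_validate_json(Path(path).read_text())


def write_report(report: dict, path) -> None:
    """Serialize an evaluation report with stable field order."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
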