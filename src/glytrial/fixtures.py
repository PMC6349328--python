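"""Deterministic engineered logs with prescribed classification marginals.

These builders construct synthetic per-patient logs whose *marginal
counts* (episodes, patients with at least one episode, post-target
records, deviations...) hit exact requested values, so that rate
computations can be checked against published-table-style fractions to
the printed decimal.  They are synthetic stand-ins: record timing and BG
values are schematic, only the counted marginals are meaningful.

Event logs control, per profile stratum: total records, post-target
records, mild/marked episode counts and the numbers of patients with at
least one, severe-hyperglycaemia counts after reaching the target, and
how many patients never reach the target.  Feasibility logs control
monitoring/rate deviation counts and hypoglycaemia-management
compliance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .io import save_config, write_log
from .patients import CohortSpec
from .protocol import (
    Frailty,
    classify_bg,
    default_dynamic_config,
    default_static_config,
)
from .records import BGRecord, TrialDataset

# schematic BG values (mg/dl) per role; classification is profile-aware
_BG_IN_TARGET = 150.0  # in target for both profiles
_BG_ABOVE = 235.0  # above target (not severe) for both profiles
_BG_HYPER = 300.0  # severe hyperglycaemia (>250)
_BG_MILD = {Frailty.FRAIL: 80.0, Frailty.VIGOROUS: 60.0}
_BG_MARKED = {Frailty.FRAIL: 60.0, Frailty.VIGOROUS: 40.0}

_HYPO_GAP = 0.5
_PRE_GAP = 2.0
_POST_GAP = 4.0


def _spread(total: int, k: int) -> list[int]:
    """Split ``total`` into k near-equal non-negative integers."""
    if k <= 0:
        return []
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


@dataclass(frozen=True)
class ProfileEventSpec:
    """Marginal counts requested for one profile stratum of an event log."""

    n_patients: int
    total_records: int
    post_target_records: int
    mild_episodes: int
    patients_with_mild: int
    marked_episodes: int
    patients_with_marked: int
    hyper_episodes: int
    patients_with_hyper: int
    non_reachers: int
    non_reacher_records: int


# Stratum marginals mirroring the published safety tables of a two-period
# infusion study (static "before" arm: 72 patients / 1517 measurements;
# dynamic "after" arm: 66 / 1324).
STATIC_EVENT_SPECS = {
    Frailty.FRAIL: ProfileEventSpec(
        n_patients=43, total_records=934, post_target_records=849,
        mild_episodes=102, patients_with_mild=26,
        marked_episodes=20, patients_with_marked=8,
        hyper_episodes=136, patients_with_hyper=28,
        non_reachers=2, non_reacher_records=20,
    ),
    Frailty.VIGOROUS: ProfileEventSpec(
        n_patients=29, total_records=583, post_target_records=501,
        mild_episodes=8, patients_with_mild=3,
        marked_episodes=3, patients_with_marked=2,
        hyper_episodes=92, patients_with_hyper=19,
        non_reachers=1, non_reacher_records=20,
    ),
}
DYNAMIC_EVENT_SPECS = {
    Frailty.FRAIL: ProfileEventSpec(
        n_patients=37, total_records=870, post_target_records=809,
        mild_episodes=45, patients_with_mild=22,
        marked_episodes=12, patients_with_marked=7,
        hyper_episodes=161, patients_with_hyper=26,
        non_reachers=2, non_reacher_records=13,
    ),
    Frailty.VIGOROUS: ProfileEventSpec(
        n_patients=29, total_records=454, post_target_records=402,
        mild_episodes=20, patients_with_mild=10,
        marked_episodes=3, patients_with_marked=3,
        hyper_episodes=53, patients_with_hyper=15,
        non_reachers=1, non_reacher_records=20,
    ),
}


def _patient_records(
    pid: str,
    profile: Frailty,
    leading_above: int,
    reaches_target: bool,
    post_mild: int,
    post_marked: int,
    post_hyper: int,
    post_total: int,
    total_if_non_reacher: int = 0,
) -> list[BGRecord]:
    bgs: list[float] = []
    if reaches_target:
        bgs.extend([_BG_ABOVE] * leading_above)
        bgs.append(_BG_IN_TARGET)
        filler = post_total - post_mild - post_marked - post_hyper
        if filler < 0:
            raise ValueError(f"{pid}: events exceed post-target budget")
        bgs.extend([_BG_MILD[profile]] * post_mild)
        bgs.extend([_BG_MARKED[profile]] * post_marked)
        bgs.extend([_BG_HYPER] * post_hyper)
        bgs.extend([_BG_IN_TARGET] * filler)
    else:
        bgs.extend([_BG_ABOVE] * total_if_non_reacher)

    recs: list[BGRecord] = []
    t = 0.0
    reached = False
    for i, bg in enumerate(bgs):
        category = classify_bg(bg, profile)
        if category.value == "in_target":
            reached = True
        if category.value in ("mild_hypo", "marked_hypo"):
            gap = _HYPO_GAP
            bolus = 15.0 if category.value == "mild_hypo" else 30.0
        else:
            gap = _POST_GAP if reached else _PRE_GAP
            bolus = 0.0
        last = i == len(bgs) - 1
        recs.append(
            BGRecord(
                patient_id=pid,
                time=t,
                bg=bg,
                category=category,
                prescribed_rate=1.0,
                applied_rate=1.0,
                bolus_g=bolus,
                prescribed_next_check=gap,
                actual_gap=math.nan if last else gap,
            )
        )
        t += gap
    return recs


def build_event_log(
    arm: str, specs: dict[Frailty, ProfileEventSpec]
) -> TrialDataset:
    """Build an arm log hitting the requested per-stratum marginals exactly."""
    records: dict[str, list[BGRecord]] = {}
    profiles: dict[str, Frailty] = {}
    infusion_end: dict[str, float] = {}
    for profile, s in specs.items():
        reachers = s.n_patients - s.non_reachers
        nr_total = s.non_reachers * s.non_reacher_records
        lead_total = s.total_records - nr_total - s.post_target_records - reachers
        if lead_total < 0:
            raise ValueError("marginals infeasible: negative leading budget")
        leading = _spread(lead_total, reachers)
        post = _spread(s.post_target_records, reachers)
        mild = _spread(s.mild_episodes, s.patients_with_mild) + [0] * (
            reachers - s.patients_with_mild
        )
        marked = _spread(s.marked_episodes, s.patients_with_marked) + [0] * (
            reachers - s.patients_with_marked
        )
        hyper = _spread(s.hyper_episodes, s.patients_with_hyper) + [0] * (
            reachers - s.patients_with_hyper
        )
        for i in range(reachers):
            pid = f"{arm}-{profile.value}-{i:03d}"
            records[pid] = _patient_records(
                pid, profile, leading[i], True, mild[i], marked[i], hyper[i], post[i]
            )
            profiles[pid] = profile
            infusion_end[pid] = records[pid][-1].time
        for j in range(s.non_reachers):
            pid = f"{arm}-{profile.value}-nr{j:02d}"
            records[pid] = _patient_records(
                pid, profile, 0, False, 0, 0, 0, 0, s.non_reacher_records
            )
            profiles[pid] = profile
            infusion_end[pid] = records[pid][-1].time
    ds = TrialDataset(
        arm=arm, records=records, profiles=profiles, infusion_end=infusion_end
    )
    ds.validate()
    return ds


def build_static_event_log() -> TrialDataset:
    return build_event_log("static", STATIC_EVENT_SPECS)


def build_dynamic_event_log() -> TrialDataset:
    return build_event_log("dynamic", DYNAMIC_EVENT_SPECS)


# ---------------------------------------------------------------------------
# feasibility (deviation / compliance) logs


@dataclass(frozen=True)
class FeasibilitySpec:
    """Marginal counts requested for a deviation-audit log."""

    n_patients: int
    total_records: int
    monitoring_deviations: int
    rate_deviations: int
    missing_prescriptions: int
    mild_episodes: int
    mild_treated: int
    marked_episodes: int
    marked_treated: int
    frail_fraction: float = 0.58


STATIC_FEASIBILITY_SPEC = FeasibilitySpec(
    n_patients=72, total_records=1517,
    monitoring_deviations=867, rate_deviations=312, missing_prescriptions=0,
    mild_episodes=109, mild_treated=9, marked_episodes=22, marked_treated=7,
)
DYNAMIC_FEASIBILITY_SPEC = FeasibilitySpec(
    n_patients=66, total_records=1324,
    monitoring_deviations=423, rate_deviations=287, missing_prescriptions=1,
    mild_episodes=61, mild_treated=27, marked_episodes=15, marked_treated=13,
)


def build_feasibility_log(arm: str, s: FeasibilitySpec) -> TrialDataset:
    """Audit-style log hitting exact deviation and compliance marginals.

    Per patient: a run of in-target records (late checks flagged on the
    leading gaps), then the patient's hypoglycaemia episodes (treated
    episodes carry the rescue bolus and the prompt recheck), then a
    final record with no following gap.  Rate deviations are flagged
    greedily across prescribable records.
    """
    n = s.n_patients
    per_patient = _spread(s.total_records, n)
    mild = _spread(s.mild_episodes, n)
    marked = _spread(s.marked_episodes, n)
    n_frail = round(n * s.frail_fraction)

    mon_left = s.monitoring_deviations
    rate_left = s.rate_deviations
    mild_treated_left = s.mild_treated
    marked_treated_left = s.marked_treated
    missing_left = s.missing_prescriptions

    records: dict[str, list[BGRecord]] = {}
    profiles: dict[str, Frailty] = {}
    infusion_end: dict[str, float] = {}
    for i in range(n):
        profile = Frailty.FRAIL if i < n_frail else Frailty.VIGOROUS
        pid = f"{arm}-f{i:03d}"
        total = per_patient[i]
        n_hypo = mild[i] + marked[i]
        n_plain = total - n_hypo
        if n_plain < 1:
            raise ValueError("patient needs at least one non-hypo record")
        roles: list[str] = ["plain"] * (n_plain - 1)
        roles += ["mild"] * mild[i] + ["marked"] * marked[i] + ["last"]

        recs: list[BGRecord] = []
        t = 0.0
        for j, role in enumerate(roles):
            if role in ("mild", "marked"):
                bg = (_BG_MILD if role == "mild" else _BG_MARKED)[profile]
                presc_gap = _HYPO_GAP
                gap = _HYPO_GAP
                if role == "mild" and mild_treated_left > 0:
                    bolus = 15.0
                    mild_treated_left -= 1
                elif role == "marked" and marked_treated_left > 0:
                    bolus = 30.0
                    marked_treated_left -= 1
                else:
                    bolus = 0.0
            else:
                bg = _BG_IN_TARGET
                presc_gap = _POST_GAP
                bolus = 0.0
                if role == "plain" and mon_left > 0:
                    gap = _POST_GAP + 1.0  # exceeds tolerance -> late check
                    mon_left -= 1
                else:
                    gap = _POST_GAP
            presc_rate = 1.0
            applied = 1.0
            if role == "last" and missing_left > 0:
                presc_rate = math.nan
                missing_left -= 1
            elif rate_left > 0:
                applied = 1.5  # prescribed change not executed
                rate_left -= 1
            last = role == "last"
            recs.append(
                BGRecord(
                    patient_id=pid,
                    time=t,
                    bg=bg,
                    category=classify_bg(bg, profile),
                    prescribed_rate=presc_rate,
                    applied_rate=applied,
                    bolus_g=bolus,
                    prescribed_next_check=presc_gap,
                    actual_gap=math.nan if last else gap,
                )
            )
            t += gap
        records[pid] = recs
        profiles[pid] = profile
        infusion_end[pid] = recs[-1].time

    if mon_left or rate_left or mild_treated_left or marked_treated_left or missing_left:
        raise ValueError("could not place all requested marginals")
    ds = TrialDataset(
        arm=arm, records=records, profiles=profiles, infusion_end=infusion_end
    )
    ds.validate()
    return ds


def build_static_feasibility_log() -> TrialDataset:
    return build_feasibility_log("static", STATIC_FEASIBILITY_SPEC)


def build_dynamic_feasibility_log() -> TrialDataset:
    return build_feasibility_log("dynamic", DYNAMIC_FEASIBILITY_SPEC)


def make_fixtures(outdir, seed: int = 0) -> dict[str, Path]:
    """Write the deterministic fixture set; returns name -> path.

    The engineered builders are fully deterministic, so the same seed (or
    any seed) reproduces byte-identical files; the seed is recorded in
    the default cohort spec written alongside.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, ds in [
        ("static_table3", build_static_event_log()),
        ("dynamic_table3", build_dynamic_event_log()),
        ("static_table5", build_static_feasibility_log()),
        ("dynamic_table5", build_dynamic_feasibility_log()),
    ]:
        p = out / f"{name}.csv"
        write_log(ds, p)
        paths[name] = p
    for name, cfg in [
        ("protocol_static", default_static_config()),
        ("protocol_dynamic", default_dynamic_config()),
        ("cohort_default", CohortSpec(n=72, seed=seed)),
    ]:
        p = out / f"{name}.json"
        save_config(cfg, p)
        paths[name] = p
    return paths
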