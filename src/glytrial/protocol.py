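"""Glycaemic classification and insulin-infusion decision engines.

Two protocol families for intravenous insulin in non-critically-ill
diabetic inpatients are encoded as pure, configurable functions:

* the **static** protocol — a stateless sliding scale mapping the current
  blood glucose (BG) band to a fixed infusion rate;
* the **dynamic** algorithm — discrete rate tiers shifted one step at a
  time according to the BG category *and* the rate of change of BG since
  the previous measurement under the current infusion rate, so that the
  running rate acts as an implicit carrier of the patient's insulin
  sensitivity.

Patients are stratified into two profiles with distinct target bands and
hypoglycaemia thresholds: *vigorous* (target 100-180 mg/dl, mild hypo
50-70, marked <50) and *frail* (target 140-220 mg/dl, mild hypo 70-100,
marked <70).  Monitoring runs every 2 h until the target is first reached
and every 4 h afterwards, with a short recheck interval after any
hypoglycaemia.

All BG values are capillary glucose in mg/dl; rates are insulin units per
hour; times are fractional hours since infusion start.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .util import round_half_up


class _StrictModel(BaseModel):
    """Config documents reject unknown fields so typos fail validation."""

    model_config = ConfigDict(extra="forbid")

#: mg/dl per mmol/l used for display conversion (247 mg/dl -> 13.7 mmol/l).
MGDL_PER_MMOL = 18.0


class Frailty(str, Enum):
    """Patient profile driving target band and hypoglycaemia thresholds."""

    VIGOROUS = "vigorous"
    FRAIL = "frail"


#: Alias used where the clinical reading is "the patient's profile".
PatientProfile = Frailty


class BGCategory(str, Enum):
    """Exhaustive partition of positive BG values for a given profile."""

    MARKED_HYPO = "marked_hypo"
    MILD_HYPO = "mild_hypo"
    BELOW_TARGET = "below_target"
    IN_TARGET = "in_target"
    ABOVE_TARGET = "above_target"
    SEVERE_HYPER = "severe_hyper"


HYPO_CATEGORIES = frozenset((BGCategory.MARKED_HYPO, BGCategory.MILD_HYPO))


class ActionNote(str, Enum):
    MAINTAIN = "maintain"
    STEP_UP = "step_up"
    STEP_DOWN = "step_down"
    SUSPEND = "suspend"
    RESUME = "resume"
    HYPO_TREAT = "hypo_treat"


class GlycemicThresholds(_StrictModel):
    """All BG cutoffs (mg/dl) for one patient profile.

    Bands are a partition of (0, inf): marked hypo below
    ``marked_hypo_below``; mild hypo is lower-closed
    ``[marked_hypo_below, mild_hypo_high)``; below-target
    ``[mild_hypo_high, target_low)``; the target band is closed on both
    ends; severe hyperglycaemia is strictly above ``severe_hyper_above``.
    """

    target_low: float
    target_high: float
    mild_hypo_low: float
    mild_hypo_high: float
    marked_hypo_below: float
    severe_hyper_above: float = 250.0

    @model_validator(mode="after")
    def _check_order(self) -> "GlycemicThresholds":
        ok = (
            self.marked_hypo_below <= self.mild_hypo_low
            < self.mild_hypo_high <= self.target_low
            < self.target_high < self.severe_hyper_above
        )
        if not ok:
            raise ValueError(
                "thresholds must satisfy marked <= mild_low < mild_high <= "
                "target_low < target_high < severe_hyper"
            )
        return self


VIGOROUS_THRESHOLDS = GlycemicThresholds(
    target_low=100, target_high=180,
    mild_hypo_low=50, mild_hypo_high=70, marked_hypo_below=50,
)
FRAIL_THRESHOLDS = GlycemicThresholds(
    target_low=140, target_high=220,
    mild_hypo_low=70, mild_hypo_high=100, marked_hypo_below=70,
)


def default_thresholds(profile: Frailty) -> GlycemicThresholds:
    return FRAIL_THRESHOLDS if profile == Frailty.FRAIL else VIGOROUS_THRESHOLDS


class StaticBand(_StrictModel):
    """One row of the sliding scale: rate applies for bg in [low, high)."""

    bg_low: float
    bg_high: Optional[float] = None  # None = open upper end
    rate: float = Field(ge=0)

    @property
    def high(self) -> float:
        return math.inf if self.bg_high is None else self.bg_high

    def contains(self, bg: float) -> bool:
        return self.bg_low <= bg < self.high


# Conventional sliding scale with the stateless property of the "before"
# protocol; every number is a config default, not a clinical claim.
DEFAULT_STATIC_TABLE = [
    StaticBand(bg_low=0, bg_high=80, rate=0.0),
    StaticBand(bg_low=80, bg_high=140, rate=0.5),
    StaticBand(bg_low=140, bg_high=180, rate=1.0),
    StaticBand(bg_low=180, bg_high=250, rate=2.0),
    StaticBand(bg_low=250, bg_high=300, rate=3.0),
    StaticBand(bg_low=300, bg_high=350, rate=4.0),
    StaticBand(bg_low=350, bg_high=None, rate=5.0),
]


class DynamicParams(_StrictModel):
    """Parameters of the tiered rate-of-change algorithm.

    ``fall_min``/``fall_fast`` (mg/dl per hour, negative = falling) split
    the rate-of-change axis into "not falling enough" (step up while above
    target), "falling adequately" (maintain) and "falling too fast" (step
    down).  Tier shifts move exactly one position in ``rate_tiers`` and
    saturate at both ends.
    """

    fall_min: float = -10.0
    fall_fast: float = -50.0
    rate_tiers: list[float] = Field(
        default_factory=lambda: [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
    )
    hypo_resume_fraction: float = 0.5
    recheck_interval_hypo: float = 0.5
    #: divisor of the starting-rate rule: floor(admission BG / this) u/h.
    bg_per_initial_unit: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "DynamicParams":
        t = self.rate_tiers
        if len(t) < 2 or t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("rate_tiers must be strictly increasing and start at 0")
        if not self.fall_fast < self.fall_min:
            raise ValueError("fall_fast must be below fall_min")
        if not 0 < self.hypo_resume_fraction <= 1:
            raise ValueError("hypo_resume_fraction must be in (0, 1]")
        if self.recheck_interval_hypo <= 0:
            raise ValueError("recheck_interval_hypo must be positive")
        return self


class ProtocolConfig(_StrictModel):
    """Complete parameterization of a dosing protocol."""

    mode: str  # "static" | "dynamic"
    static_table: list[StaticBand] = Field(
        default_factory=lambda: [b.model_copy() for b in DEFAULT_STATIC_TABLE]
    )
    dynamic: DynamicParams = Field(default_factory=DynamicParams)
    thresholds_by_profile: dict[Frailty, GlycemicThresholds] = Field(
        default_factory=lambda: {
            Frailty.VIGOROUS: VIGOROUS_THRESHOLDS.model_copy(),
            Frailty.FRAIL: FRAIL_THRESHOLDS.model_copy(),
        }
    )
    monitor_pre_target: float = 2.0
    monitor_post_target: float = 4.0
    #: slack (hours) before a late check counts as a deviation (20 min).
    deviation_tolerance: float = 1.0 / 3.0
    mild_bolus_g: float = 15.0
    marked_bolus_g: float = 30.0
    #: BG rise (mg/dl) per gram of rescue glucose in the simulator.
    bolus_bg_rise_per_g: float = 4.0
    #: infusion stops after this long continuously in target.
    stop_after_in_target_h: float = 48.0

    @model_validator(mode="after")
    def _check(self) -> "ProtocolConfig":
        if self.mode not in ("static", "dynamic"):
            raise ValueError("mode must be 'static' or 'dynamic'")
        bands = self.static_table
        if not bands or bands[0].bg_low != 0 or bands[-1].bg_high is not None:
            raise ValueError("static_table must start at 0 and end open")
        for a, b in zip(bands, bands[1:]):
            if a.bg_high is None or a.bg_high != b.bg_low:
                raise ValueError("static_table bands must be contiguous")
        if self.monitor_pre_target <= 0 or self.monitor_post_target <= 0:
            raise ValueError("monitoring intervals must be positive")
        return self


def default_static_config() -> ProtocolConfig:
    return ProtocolConfig(mode="static")


def default_dynamic_config() -> ProtocolConfig:
    return ProtocolConfig(mode="dynamic")


@dataclass
class InfusionState:
    """Per-patient state carried between protocol decisions."""

    rate: float = 0.0
    target_reached: bool = False
    last_bg: float = math.nan
    last_time: float = 0.0
    suspended: bool = False
    #: rate running just before suspension; basis of the resume rule.
    pre_hypo_rate: float = 0.0


@dataclass(frozen=True)
class ProtocolAction:
    """One prescription: new rate, next check, and any rescue glucose."""

    new_rate: float
    next_check_in: float
    glucose_bolus_g: float
    note: ActionNote

    def __post_init__(self) -> None:
        if self.new_rate < 0:
            raise ValueError("new_rate must be >= 0")
        if self.next_check_in <= 0:
            raise ValueError("next_check_in must be positive")
        if self.glucose_bolus_g > 0 and self.note is not ActionNote.HYPO_TREAT:
            raise ValueError("glucose bolus only allowed with hypo_treat")


# ---------------------------------------------------------------------------
# classification & conversion


def classify_bg(
    bg: float,
    profile: Frailty = Frailty.VIGOROUS,
    thresholds: GlycemicThresholds | None = None,
) -> BGCategory:
    """Assign a BG value (mg/dl) to exactly one category for a profile."""
    if bg <= 0:
        raise ValueError(f"bg must be positive, got {bg}")
    t = thresholds if thresholds is not None else default_thresholds(profile)
    if bg < t.marked_hypo_below:
        return BGCategory.MARKED_HYPO
    if bg < t.mild_hypo_high:
        return BGCategory.MILD_HYPO
    if bg < t.target_low:
        return BGCategory.BELOW_TARGET
    if bg <= t.target_high:
        return BGCategory.IN_TARGET
    if bg > t.severe_hyper_above:
        return BGCategory.SEVERE_HYPER
    return BGCategory.ABOVE_TARGET


def mgdl_to_mmol(bg: float) -> float:
    """Convert mg/dl to mmol/l (exact value; use round for display)."""
    if bg < 0:
        raise ValueError("bg must be non-negative")
    return bg / MGDL_PER_MMOL


def mgdl_to_mmol_display(bg: float) -> float:
    """mg/dl -> mmol/l rounded half-up to one decimal, as tables print it."""
    return round_half_up(mgdl_to_mmol(bg), 1)


# ---------------------------------------------------------------------------
# scheduling


def next_check_interval(
    state: InfusionState, last_category: BGCategory, config: ProtocolConfig
) -> float:
    """Hours until the next BG measurement.

    Hypoglycaemia forces the short recheck interval; otherwise 2-hourly
    until the target has been reached once, 4-hourly afterwards.  The
    in-target latch is applied by the caller *after* scheduling, so the
    measurement that first reaches the target still schedules at the
    pre-target cadence.
    """
    if last_category in HYPO_CATEGORIES:
        return config.dynamic.recheck_interval_hypo
    if not state.target_reached:
        return config.monitor_pre_target
    return config.monitor_post_target


# ---------------------------------------------------------------------------
# rate engines


def static_rate(bg: float, config: ProtocolConfig) -> float:
    """Sliding-scale lookup: the rate of the unique band containing bg."""
    if bg <= 0:
        raise ValueError("bg must be positive")
    for band in config.static_table:
        if band.contains(bg):
            return band.rate
    raise AssertionError("static table does not cover bg; config invariant broken")


def _tier_index(rate: float, tiers: Sequence[float]) -> int:
    for i, t in enumerate(tiers):
        if abs(rate - t) < 1e-9:
            return i
    raise ValueError(f"rate {rate} is not a member of the configured tiers")


def highest_tier_at_most(value: float, tiers: Sequence[float]) -> float:
    """Largest tier not exceeding ``value`` (tier 0 if all exceed it)."""
    best = tiers[0]
    for t in tiers:
        if t <= value + 1e-9:
            best = t
    return best


def dynamic_rate(
    prev_bg: float,
    cur_bg: float,
    dt: float,
    state: InfusionState,
    profile: Frailty,
    config: ProtocolConfig,
) -> ProtocolAction:
    """Tier-shift decision from (category, rate of change, current tier).

    roc = (cur_bg - prev_bg) / dt in mg/dl per hour.  Above target: step up
    one tier unless BG is already falling by at least ``fall_min``; step
    down if falling faster than ``fall_fast``; otherwise maintain.  In
    target: maintain, unless falling faster than ``fall_fast`` (step
    down).  Below target but not hypoglycaemic: step down.  Any
    hypoglycaemia suspends the infusion and triggers rescue glucose.
    Shifts saturate at both ends of the tier ladder.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    thresholds = config.thresholds_by_profile.get(profile)
    category = classify_bg(cur_bg, profile, thresholds)
    if category in HYPO_CATEGORIES:
        return hypo_management(category, profile, state, config)

    p = config.dynamic
    roc = (cur_bg - prev_bg) / dt
    idx = _tier_index(state.rate, p.rate_tiers)
    if category in (BGCategory.ABOVE_TARGET, BGCategory.SEVERE_HYPER):
        if roc >= p.fall_min:
            shift = 1
        elif roc < p.fall_fast:
            shift = -1
        else:
            shift = 0
    elif category is BGCategory.IN_TARGET:
        shift = -1 if roc < p.fall_fast else 0
    else:  # below target, not hypo
        shift = -1
    new_idx = min(max(idx + shift, 0), len(p.rate_tiers) - 1)
    note = (
        ActionNote.STEP_UP if shift > 0
        else ActionNote.STEP_DOWN if shift < 0
        else ActionNote.MAINTAIN
    )
    return ProtocolAction(
        new_rate=p.rate_tiers[new_idx],
        next_check_in=next_check_interval(state, category, config),
        glucose_bolus_g=0.0,
        note=note,
    )


def hypo_management(
    category: BGCategory,
    profile: Frailty,
    state: InfusionState,
    config: ProtocolConfig,
) -> ProtocolAction:
    """Suspend the infusion and prescribe rescue glucose.

    Mild hypoglycaemia: 15 g oral glucose equivalent; marked: 30 g IV.
    Recheck after ``recheck_interval_hypo``.  Resumption (at
    ``hypo_resume_fraction`` of the pre-hypo rate, snapped down to a
    tier) happens at the first post-hypo BG at or above the mild band's
    upper edge and is handled by :func:`resume_rate`.
    """
    if category not in HYPO_CATEGORIES:
        raise ValueError("hypo_management requires a hypoglycaemic category")
    bolus = (
        config.marked_bolus_g
        if category is BGCategory.MARKED_HYPO
        else config.mild_bolus_g
    )
    return ProtocolAction(
        new_rate=0.0,
        next_check_in=config.dynamic.recheck_interval_hypo,
        glucose_bolus_g=bolus,
        note=ActionNote.HYPO_TREAT,
    )


def resume_rate(pre_hypo_rate: float, config: ProtocolConfig) -> float:
    """Post-hypo restart rate: fraction of the prior rate, floored to a tier."""
    p = config.dynamic
    return highest_tier_at_most(p.hypo_resume_fraction * pre_hypo_rate, p.rate_tiers)


def initial_rate(admission_bg: float, config: ProtocolConfig) -> float:
    """Starting infusion rate from the admission BG.

    Static mode: plain sliding-scale lookup.  Dynamic mode: BG / 100
    units per hour snapped to the *nearest* tier (exact ties resolve to
    the higher tier, since the admission indication is marked
    hyperglycaemia), except that BG below 100 mg/dl starts without
    insulin.  Very high BG saturates at the top tier.
    """
    if admission_bg <= 0:
        raise ValueError("admission_bg must be positive")
    if config.mode == "static":
        return static_rate(admission_bg, config)
    p = config.dynamic
    x = admission_bg / p.bg_per_initial_unit
    if x < 1.0:
        return 0.0
    return min(p.rate_tiers, key=lambda t: (abs(t - x), -t))


# ---------------------------------------------------------------------------
# protocol-deviation detection


@dataclass
class DeviationSummary:
    """Counted protocol deviations with explicit denominators.

    Monitoring deviations: executed inter-measurement gap exceeding the
    prescribed interval by more than the tolerance; denominator = all
    measurements.  Rate deviations: applied rate differing from the
    prescribed rate; denominator = measurements carrying a prescription.
    Hypoglycaemia management: episodes followed by the prescribed bolus
    and a recheck within tolerance, split by intensity.
    """

    monitoring_deviations: int = 0
    monitoring_total: int = 0
    rate_deviations: int = 0
    rate_total: int = 0
    mild_treated: int = 0
    mild_total: int = 0
    marked_treated: int = 0
    marked_total: int = 0

    @property
    def hypo_treated(self) -> int:
        return self.mild_treated + self.marked_treated

    @property
    def hypo_total(self) -> int:
        return self.mild_total + self.marked_total

    def monitoring_pct(self) -> float:
        return round_half_up(100.0 * self.monitoring_deviations / self.monitoring_total, 1)

    def rate_pct(self) -> float:
        return round_half_up(100.0 * self.rate_deviations / self.rate_total, 1)

    def mild_management_pct(self) -> float:
        return round_half_up(100.0 * self.mild_treated / self.mild_total, 1)

    def marked_management_pct(self) -> float:
        return round_half_up(100.0 * self.marked_treated / self.marked_total, 1)

    def as_dict(self) -> dict:
        d = {
            "monitoring_deviations": [self.monitoring_deviations, self.monitoring_total],
            "rate_deviations": [self.rate_deviations, self.rate_total],
            "mild_hypo_managed": [self.mild_treated, self.mild_total],
            "marked_hypo_managed": [self.marked_treated, self.marked_total],
        }
        pct = {}
        if self.monitoring_total:
            pct["monitoring_deviation_pct"] = self.monitoring_pct()
        if self.rate_total:
            pct["rate_deviation_pct"] = self.rate_pct()
        if self.mild_total:
            pct["mild_hypo_managed_pct"] = self.mild_management_pct()
        if self.marked_total:
            pct["marked_hypo_managed_pct"] = self.marked_management_pct()
        return {**d, **pct}


def detect_deviations(
    records,
    config: ProtocolConfig,
    prescribed: Sequence[ProtocolAction] | None = None,
) -> DeviationSummary:
    """Count monitoring, rate, and hypo-management deviations in a log.

    ``records`` is a sequence of :class:`glytrial.records.BGRecord` for one
    or more patients; each record carries both the prescribed and the
    applied action, so ``prescribed`` is only needed when prescriptions
    are supplied separately (it must then align 1:1 with the records).
    """
    records = list(records)
    if prescribed is not None:
        if len(prescribed) != len(records):
            raise ValueError("prescribed actions must align 1:1 with records")
    tol = config.deviation_tolerance
    out = DeviationSummary()
    for i, rec in enumerate(records):
        presc_rate = rec.prescribed_rate
        presc_gap = rec.prescribed_next_check
        bolus = rec.bolus_g
        if prescribed is not None:
            presc_rate = prescribed[i].new_rate
            presc_gap = prescribed[i].next_check_in
        out.monitoring_total += 1
        gap_known = not math.isnan(rec.actual_gap) and not math.isnan(presc_gap)
        if gap_known and rec.actual_gap > presc_gap + tol:
            out.monitoring_deviations += 1
        if not math.isnan(presc_rate):
            out.rate_total += 1
            if abs(rec.applied_rate - presc_rate) > 1e-9:
                out.rate_deviations += 1
        if rec.category in HYPO_CATEGORIES:
            treated = (
                bolus > 0
                and gap_known
                and rec.actual_gap <= config.dynamic.recheck_interval_hypo + tol
            )
            if rec.category is BGCategory.MILD_HYPO:
                out.mild_total += 1
                out.mild_treated += int(treated)
            else:
                out.marked_total += 1
                out.marked_treated += int(treated)
    return out
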