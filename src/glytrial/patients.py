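"""Virtual-patient generator and minimal glucose-insulin dynamics.

The cohort generator emulates the admission profile of a non-critically
ill diabetic inpatient population: admission BG around 250 mg/dl with a
wide spread (SD ~105, truncated below 100 mg/dl since infusion is only
indicated for hyperglycaemia), just under 60% frail patients, and
heterogeneous insulin sensitivity (lognormal).  Frail patients receive a
lower insulin-sensitivity multiplier and a higher process-noise
multiplier, the mechanism behind their greater observed instability.

The physiology is a deliberately minimal one-compartment model, not a
physiological pharmacokinetic model: plasma insulin relaxes toward the
infusion rate with a 1 h time constant, and glucose changes by endogenous
production plus meal input minus insulin-mediated disposal proportional
to BG:

    dI/dt  = (rate - I) / tau_i
    dBG/dt = EGP + meal(t) - s_i * I * BG/100  (+ noise)

With constant rate, no meals and no noise the model converges
monotonically to the fixed point BG* = 100 * EGP / (s_i * rate).  Meals
are raised-cosine pulses of 2 h width at 07:00, 12:00 and 19:00 whose
integral equals ``meal_carb_effect`` mg/dl.  Capillary meter error is
multiplicative with a 5% CV by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import Field, model_validator

from .protocol import Frailty, _StrictModel

#: width of a meal pulse, hours
MEAL_WIDTH_H = 2.0
#: hard floor for simulated glucose, mg/dl
BG_FLOOR = 20.0


@dataclass
class PatientParams:
    """Physiology and admission parameters of one virtual patient."""

    profile: Frailty
    s_i: float  # insulin sensitivity, (mg/dl) per unit
    admission_bg: float  # mg/dl
    egp: float = 50.0  # endogenous glucose production, mg/dl/h
    meal_times: tuple[float, ...] = (7.0, 12.0, 19.0)
    meal_carb_effect: float = 60.0  # total BG rise per meal, mg/dl
    noise_sd: float = 15.0  # process noise, mg/dl per sqrt(h)
    tau_i: float = 1.0  # insulin action time constant, h
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_i <= 0:
            raise ValueError("s_i must be positive")
        if self.egp < 0 or self.noise_sd < 0:
            raise ValueError("egp and noise_sd must be non-negative")
        if self.admission_bg <= 0:
            raise ValueError("admission_bg must be positive")


class CohortSpec(_StrictModel):
    """Sampling distribution of a virtual cohort."""

    n: int = Field(ge=1)
    frail_fraction: float = 0.58
    admission_bg_mean: float = 250.0
    admission_bg_sd: float = 105.0
    admission_bg_min: float = 100.0
    s_i_median: float = 8.0
    s_i_log_sd: float = 0.4
    frail_s_i_mult: float = 0.7
    frail_noise_mult: float = 1.5
    egp: float = 50.0
    noise_sd: float = 15.0
    meal_carb_effect: float = 60.0
    duration: float = 168.0  # hours of follow-up simulated (7 days)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if not 0 <= self.frail_fraction <= 1:
            raise ValueError("frail_fraction must be in [0, 1]")
        if self.admission_bg_sd <= 0 or self.s_i_median <= 0:
            raise ValueError("scale parameters must be positive")
        return self


def sample_cohort(spec: CohortSpec) -> list[PatientParams]:
    """Draw a deterministic cohort: pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    n_frail = round(n * spec.frail_fraction)
    profiles = np.array(
        [Frailty.FRAIL] * n_frail + [Frailty.VIGOROUS] * (n - n_frail), dtype=object
    )
    rng.shuffle(profiles)

    # truncated-normal admission BG by rejection (cheap at cohort sizes)
    admission = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(spec.admission_bg_mean, spec.admission_bg_sd, size=2 * n)
        draw = draw[draw >= spec.admission_bg_min]
        take = min(len(draw), n - filled)
        admission[filled : filled + take] = draw[:take]
        filled += take

    s_i = spec.s_i_median * np.exp(spec.s_i_log_sd * rng.standard_normal(n))
    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    cohort = []
    for i in range(n):
        frail = profiles[i] == Frailty.FRAIL
        cohort.append(
            PatientParams(
                profile=Frailty.FRAIL if frail else Frailty.VIGOROUS,
                s_i=float(s_i[i]) * (spec.frail_s_i_mult if frail else 1.0),
                admission_bg=float(admission[i]),
                egp=spec.egp,
                meal_carb_effect=spec.meal_carb_effect,
                noise_sd=spec.noise_sd * (spec.frail_noise_mult if frail else 1.0),
                seed=int(child_seeds[i]),
            )
        )
    return cohort


def meal_rate(t: float, params: PatientParams) -> float:
    """Meal glucose appearance (mg/dl per hour) at clock time t mod 24."""
    tod = t % 24.0
    total = 0.0
    for m in params.meal_times:
        tau = tod - m
        if 0.0 <= tau < MEAL_WIDTH_H:
            # amplitude 2/W * effect makes the pulse integrate to the effect
            total += (
                params.meal_carb_effect * (2.0 / MEAL_WIDTH_H)
                * 0.5 * (1.0 - math.cos(2.0 * math.pi * tau / MEAL_WIDTH_H))
            )
    return total


def step_glucose(
    bg: float,
    plasma_insulin: float,
    rate: float,
    t: float,
    dt: float,
    params: PatientParams,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """One Euler step of the minimal model; returns (bg, plasma_insulin).

    Noise is additive Gaussian with SD ``noise_sd * sqrt(dt)`` so that
    variance accumulates linearly in time; BG is floored at 20 mg/dl and
    plasma insulin at 0.
    """
    if not 0 < dt <= 0.25:
        raise ValueError("dt must be in (0, 0.25] hours")
    insulin = plasma_insulin + dt * (rate - plasma_insulin) / params.tau_i
    insulin = max(insulin, 0.0)
    drift = params.egp + meal_rate(t, params) - params.s_i * insulin * (bg / 100.0)
    noise = 0.0
    if params.noise_sd > 0 and rng is not None:
        noise = params.noise_sd * math.sqrt(dt) * rng.standard_normal()
    return max(bg + dt * drift + noise, BG_FLOOR), insulin


def measure_bg(
    true_bg: float, rng: np.random.Generator | None = None, meter_cv: float = 0.05
) -> float:
    """Capillary meter reading: multiplicative error with CV ``meter_cv``."""
    if true_bg <= 0:
        raise ValueError("true_bg must be positive")
    if meter_cv == 0 or rng is None:
        return true_bg
    return max(true_bg * (1.0 + meter_cv * rng.standard_normal()), 1.0)
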