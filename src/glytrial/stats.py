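"""Efficacy, safety and feasibility statistics for infusion-trial logs.

Implements the full evaluation battery of a before-after glycaemic
control study on :class:`~glytrial.records.TrialDataset` objects:

* event summaries — hypo/hyper classification counts with explicit
  denominators (episode rates over all measurements; post-target
  hyperglycaemia over post-target measurements; patient-level rates over
  patients at risk);
* time-to-target as censored data: Kaplan-Meier product-limit curves and
  a two-group Cox proportional-hazards hazard ratio (Breslow ties, Wald
  confidence interval);
* glycaemic variability: per-patient %CV (100 * SD / mean) with the 36%
  stability cut-off, and the one-way random-effects intraclass
  correlation coefficient (Searle's k0 correction for unbalanced group
  sizes, negative estimates truncated to 0);
* hypoglycaemia recurrence after the first event, as a per-patient
  percentage of subsequent measurements;
* zero-inflated negative binomial models for per-patient event counts
  with a log-exposure offset, and a likelihood-ratio group comparison;
* two-proportion chi-square / Fisher exact contrasts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps
from scipy.special import expit

from .protocol import (
    HYPO_CATEGORIES,
    BGCategory,
    DeviationSummary,
    Frailty,
    ProtocolConfig,
    default_dynamic_config,
    detect_deviations,
)
from .records import BGRecord, TrialDataset
from .util import pct, round_half_up


class ConvergenceError(RuntimeError):
    """A likelihood maximization diverged or failed to converge."""


class DegenerateDataError(ValueError):
    """The data cannot identify the requested model (e.g. all zeros)."""


# ---------------------------------------------------------------------------
# event summaries


@dataclass
class EventSummary:
    """Classification marginals of one arm with explicit denominators."""

    n_measurements: int
    n_patients: int
    category_counts: dict[BGCategory, int]
    patients_with_mild: int
    patients_with_marked: int
    patients_reached_target: int
    post_target_records: int
    post_target_hyper: int
    patients_with_post_target_hyper: int

    @property
    def mild_episodes(self) -> int:
        return self.category_counts.get(BGCategory.MILD_HYPO, 0)

    @property
    def marked_episodes(self) -> int:
        return self.category_counts.get(BGCategory.MARKED_HYPO, 0)

    def as_dict(self) -> dict:
        d = {
            "n_measurements": self.n_measurements,
            "n_patients": self.n_patients,
            "category_counts": {c.value: n for c, n in self.category_counts.items()},
            "mild_hypo_episodes": [self.mild_episodes, self.n_measurements],
            "marked_hypo_episodes": [self.marked_episodes, self.n_measurements],
            "patients_with_mild_hypo": [self.patients_with_mild, self.n_patients],
            "patients_with_marked_hypo": [self.patients_with_marked, self.n_patients],
            "patients_reached_target": [self.patients_reached_target, self.n_patients],
            "post_target_hyper": [self.post_target_hyper, self.post_target_records],
            "patients_with_post_target_hyper": [
                self.patients_with_post_target_hyper,
                self.patients_reached_target,
            ],
        }
        d["mild_hypo_pct"] = pct(self.mild_episodes, self.n_measurements)
        d["marked_hypo_pct"] = pct(self.marked_episodes, self.n_measurements)
        d["patients_with_mild_hypo_pct"] = pct(self.patients_with_mild, self.n_patients)
        d["patients_with_marked_hypo_pct"] = pct(
            self.patients_with_marked, self.n_patients
        )
        if self.post_target_records:
            d["post_target_hyper_pct"] = pct(
                self.post_target_hyper, self.post_target_records
            )
        if self.patients_reached_target:
            d["patients_with_post_target_hyper_pct"] = pct(
                self.patients_with_post_target_hyper, self.patients_reached_target
            )
        return d


def _first_target_index(recs: Sequence[BGRecord]) -> int | None:
    for i, r in enumerate(recs):
        if r.category is BGCategory.IN_TARGET:
            return i
    return None


def summarize_events(
    dataset: TrialDataset, profile: Frailty | None = None
) -> EventSummary:
    """Count classification marginals, optionally for one profile stratum.

    Post-target hyperglycaemia counts records *strictly after* the first
    in-target measurement with BG above the severe threshold (>250
    mg/dl by default); its denominator is the number of post-target
    records, and the patient-level rate is over patients who reached the
    target.
    """
    pids = [
        p
        for p in dataset.records
        if profile is None or dataset.profiles[p] == profile
    ]
    if not pids:
        raise ValueError("no patients in dataset (or stratum)")
    counts: dict[BGCategory, int] = {c: 0 for c in BGCategory}
    n_meas = 0
    with_mild = with_marked = reached = 0
    post_records = post_hyper = with_post_hyper = 0
    for pid in pids:
        recs = dataset.records[pid]
        n_meas += len(recs)
        any_mild = any_marked = False
        for r in recs:
            counts[r.category] += 1
            any_mild |= r.category is BGCategory.MILD_HYPO
            any_marked |= r.category is BGCategory.MARKED_HYPO
        with_mild += any_mild
        with_marked += any_marked
        idx = _first_target_index(recs)
        if idx is not None:
            reached += 1
            post = recs[idx + 1 :]
            post_records += len(post)
            hyper = sum(1 for r in post if r.category is BGCategory.SEVERE_HYPER)
            post_hyper += hyper
            with_post_hyper += hyper > 0
    return EventSummary(
        n_measurements=n_meas,
        n_patients=len(pids),
        category_counts=counts,
        patients_with_mild=with_mild,
        patients_with_marked=with_marked,
        patients_reached_target=reached,
        post_target_records=post_records,
        post_target_hyper=post_hyper,
        patients_with_post_target_hyper=with_post_hyper,
    )


def percent_in_target(dataset: TrialDataset) -> dict:
    """% of measurements in target, overall and from the first in-target.

    Whether pre-target measurements belong in the denominator is an
    analytic choice; both variants are computed and labelled.
    """
    total = in_t = post_total = post_in = 0
    for recs in dataset.records.values():
        total += len(recs)
        in_t += sum(1 for r in recs if r.category is BGCategory.IN_TARGET)
        idx = _first_target_index(recs)
        if idx is not None:
            post = recs[idx:]
            post_total += len(post)
            post_in += sum(1 for r in post if r.category is BGCategory.IN_TARGET)
    out = {
        "overall": [in_t, total],
        "overall_pct": pct(in_t, total),
        "from_first_target": [post_in, post_total],
    }
    if post_total:
        out["from_first_target_pct"] = pct(post_in, post_total)
    return out


# ---------------------------------------------------------------------------
# time to target, KM, Cox


def time_to_target(dataset: TrialDataset) -> pd.DataFrame:
    """Per-patient (time, event) pairs; censored at the last measurement."""
    rows = []
    for pid, recs in dataset.records.items():
        idx = _first_target_index(recs)
        if idx is None:
            rows.append((pid, dataset.infusion_end.get(pid, recs[-1].time), 0))
        else:
            rows.append((pid, recs[idx].time, 1))
    return pd.DataFrame(rows, columns=["patient_id", "time_h", "event"])


@dataclass
class SurvivalFit:
    """Product-limit estimate: S(t) on the observed event grid."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float | None  # first time with S(t) <= 0.5; None if never

    def curve(self) -> list[list[float]]:
        return [[float(t), float(s)] for t, s in zip(self.times, self.survival)]


def km_fit(times: Iterable[float], events: Iterable[int]) -> SurvivalFit:
    """Kaplan-Meier product-limit estimator.

    ``median`` is the first observed time at which the survival curve
    drops to 0.5 or below; ``None`` when the curve never reaches 0.5
    (e.g. everything censored), which callers must treat as undefined.
    """
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # grid includes the t=0 anchor row lifelines adds (S(0) = 1)
    grid = kmf.event_table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=int)
    observed = kmf.event_table["observed"].to_numpy(dtype=int)
    median = kmf.median_survival_time_
    median = None if math.isinf(median) else float(median)
    return SurvivalFit(
        times=grid, survival=surv, n_at_risk=at_risk, n_events=observed,
        median=median,
    )


@dataclass
class CoxFit:
    """Two-group Cox PH fit: hazard of ``group`` relative to ``reference``."""

    hr: float
    ci_low: float
    ci_high: float
    log_hr: float
    se: float
    p: float
    group: str
    reference: str

    def as_dict(self) -> dict:
        return {
            "hr": self.hr,
            "ci95": [self.ci_low, self.ci_high],
            "p": self.p,
            "group": self.group,
            "reference": self.reference,
        }


def cox_two_group(
    times: Iterable[float],
    events: Iterable[int],
    group: Iterable,
    reference=None,
) -> CoxFit:
    """Two-group Cox partial-likelihood fit (Breslow ties, Wald 95% CI).

    Raises :class:`ConvergenceError` on monotone likelihood (groups whose
    risk sets never overlap) and :class:`ValueError` unless both groups
    contribute at least one event.
    """
    import statsmodels.api as sm

    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    group = np.asarray(list(group))
    labels = sorted(np.unique(group).tolist())
    if len(labels) != 2:
        raise ValueError(f"group must have exactly 2 labels, got {labels}")
    ref = labels[0] if reference is None else reference
    other = labels[1] if ref == labels[0] else labels[0]
    x = (group == other).astype(float)
    for lab in labels:
        if events[group == lab].sum() < 1:
            raise ValueError(f"group {lab!r} has no events")
    model = sm.PHReg(times, x[:, None], status=events, ties="breslow")
    with np.errstate(all="ignore"):
        res = model.fit(disp=False)
    beta = float(res.params[0])
    se = float(res.bse[0])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15:
        raise ConvergenceError("monotone partial likelihood; HR diverges")
    z = 1.959963984540054
    return CoxFit(
        hr=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        log_hr=beta,
        se=se,
        p=float(2 * sps.norm.sf(abs(beta) / se)) if se > 0 else float("nan"),
        group=str(other),
        reference=str(ref),
    )


# ---------------------------------------------------------------------------
# variability


def cv_percent(values: Iterable[float]) -> float:
    """Coefficient of variation, 100 * sample SD / mean (requires mean>0)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("cv_percent needs at least 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("cv_percent requires a positive mean")
    return float(100.0 * v.std(ddof=1) / m)


def icc_oneway(groups: Sequence[Sequence[float]]) -> float:
    """One-way random-effects intraclass correlation (ANOVA estimator).

    ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW) with Searle's
    k0 = (N - sum(n_i^2)/N) / (g - 1) adjusting the mean group size for
    unbalance; negative estimates are truncated to 0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    g = len(gs)
    if g < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([len(x) for x in gs], dtype=float)
    N = ns.sum()
    if N <= g:
        raise ValueError("need within-group replication (N > g)")
    grand = np.concatenate(gs).mean()
    ssb = float(sum(n * (x.mean() - grand) ** 2 for n, x in zip(ns, gs)))
    ssw = float(sum(((x - x.mean()) ** 2).sum() for x in gs))
    msb = ssb / (g - 1)
    msw = ssw / (N - g)
    k0 = (N - (ns**2).sum() / N) / (g - 1)
    if msw == 0:
        return 1.0 if msb > 0 else 0.0
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    return float(min(max(icc, 0.0), 1.0))


@dataclass
class VariabilityStats:
    """Per-patient %CV (post-target) and the arm-level ICC."""

    cv_per_patient: dict[str, float]
    cv_mean: float | None
    cv_sd: float | None
    stable_fraction: float | None  # share of patients with %CV <= 36
    icc: float

    def as_dict(self) -> dict:
        return {
            "cv_pct_mean": None if self.cv_mean is None else round_half_up(self.cv_mean, 1),
            "cv_pct_sd": None if self.cv_sd is None else round_half_up(self.cv_sd, 1),
            "stable_fraction_cv_le_36": self.stable_fraction,
            "icc": None if self.icc is None else round(self.icc, 3),
            "n_patients_with_cv": len(self.cv_per_patient),
        }


#: %CV at or below this defines stable glycaemia.
CV_STABILITY_CUTOFF = 36.0


def variability_stats(dataset: TrialDataset) -> VariabilityStats:
    """%CV of each patient's BG once in target, plus the arm ICC.

    The %CV uses measurements from the first in-target record onward
    (patients needing >= 2 such records); the ICC uses every
    measurement, grouping by patient, so it captures how strongly BG
    values cluster within patients relative to the arm.
    """
    cvs: dict[str, float] = {}
    icc_groups: list[list[float]] = []
    for pid, recs in dataset.records.items():
        bgs = [r.bg for r in recs]
        if len(bgs) >= 2:
            icc_groups.append(bgs)
        idx = _first_target_index(recs)
        if idx is not None and len(recs) - idx >= 2:
            cvs[pid] = cv_percent([r.bg for r in recs[idx:]])
    icc = icc_oneway(icc_groups) if len(icc_groups) >= 2 else float("nan")
    vals = np.array(list(cvs.values()))
    return VariabilityStats(
        cv_per_patient=cvs,
        cv_mean=float(vals.mean()) if vals.size else None,
        cv_sd=float(vals.std(ddof=1)) if vals.size > 1 else None,
        stable_fraction=(
            float((vals <= CV_STABILITY_CUTOFF).mean()) if vals.size else None
        ),
        icc=icc,
    )


# ---------------------------------------------------------------------------
# recurrence after the first hypoglycaemia


@dataclass
class RecurrenceStats:
    """Per-patient % of hypoglycaemia among measurements after the first."""

    per_patient: dict[str, float]
    mean: float | None
    sd: float | None
    n: int

    def as_dict(self) -> dict:
        return {
            "mean_pct": None if self.mean is None else round_half_up(self.mean, 1),
            "sd_pct": None if self.sd is None else round_half_up(self.sd, 1),
            "n_qualifying_patients": self.n,
        }


def recurrence_after_first(
    dataset: TrialDataset,
    categories: frozenset[BGCategory] = HYPO_CATEGORIES,
) -> RecurrenceStats:
    """Recurrence of hypoglycaemia after each patient's first episode.

    For every patient with at least one episode *and* at least one later
    measurement: 100 * (# episode measurements strictly after the first
    episode) / (# measurements strictly after the first episode).
    Reported as mean +/- sample SD over qualifying patients.
    """
    per: dict[str, float] = {}
    for pid, recs in dataset.records.items():
        first = next(
            (i for i, r in enumerate(recs) if r.category in categories), None
        )
        if first is None:
            continue
        later = recs[first + 1 :]
        if not later:
            continue
        hits = sum(1 for r in later if r.category in categories)
        per[pid] = 100.0 * hits / len(later)
    vals = np.array(list(per.values()))
    return RecurrenceStats(
        per_patient=per,
        mean=float(vals.mean()) if vals.size else None,
        sd=float(vals.std(ddof=1)) if vals.size > 1 else None,
        n=len(per),
    )


# ---------------------------------------------------------------------------
# zero-inflated negative binomial


@dataclass
class ZinbFit:
    """Intercept-only ZINB fit with log-exposure offset.

    ``mu`` is the event rate per unit exposure in the non-inflated
    component, ``k`` the NB size (dispersion; variance mu + mu^2/k),
    ``pi`` the structural-zero probability.
    """

    mu: float
    k: float
    pi: float
    loglik: float
    converged: bool
    n: int


def _fit_zinb(endog, exog, exog_infl, exposure):
    import warnings

    import statsmodels.api as sm

    model = sm.ZeroInflatedNegativeBinomialP(
        endog, exog, exog_infl=exog_infl, exposure=exposure, p=2
    )
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence is reported via the flag
        res = model.fit(method="bfgs", maxiter=2000, disp=0)
        if not res.mle_retvals.get("converged", False):
            start = res.params
            res = model.fit(start_params=start, method="nm", maxiter=5000, disp=0)
            res = model.fit(start_params=res.params, method="bfgs", maxiter=2000, disp=0)
    return res


def zinb_fit(counts: Iterable[int], exposure: Iterable[float]) -> ZinbFit:
    """Fit an intercept-only ZINB with per-patient log-exposure offset."""
    y = np.asarray(list(counts), dtype=float)
    ex = np.asarray(list(exposure), dtype=float)
    if y.size < 10:
        raise ValueError("zinb_fit needs at least 10 patients")
    if np.all(y == 0):
        raise DegenerateDataError("all counts are zero; rate not identifiable")
    if np.any(ex <= 0):
        raise ValueError("exposures must be positive")
    n = y.size
    res = _fit_zinb(y, np.ones((n, 1)), np.ones((n, 1)), ex)
    params = np.asarray(res.params, dtype=float)
    # parameter order: [inflate intercept, count intercept, alpha]
    pi = float(expit(params[0]))
    mu = float(math.exp(params[1]))
    alpha = float(params[-1])
    converged = bool(res.mle_retvals.get("converged", False)) and alpha > 0
    if not converged:
        raise ConvergenceError("ZINB fit did not converge")
    return ZinbFit(
        mu=mu, k=1.0 / alpha, pi=pi, loglik=float(res.llf), converged=True, n=n
    )


@dataclass
class ZinbComparison:
    rate_ratio: float
    p: float
    lr_stat: float
    converged: bool

    def as_dict(self) -> dict:
        if not self.converged:
            return {"rate_ratio": None, "p": None, "lr_stat": None,
                    "converged": False}
        return {
            "rate_ratio": self.rate_ratio,
            "p": self.p,
            "lr_stat": self.lr_stat,
            "converged": self.converged,
        }


def zinb_compare(
    counts_a: Iterable[int],
    exposure_a: Iterable[float],
    counts_b: Iterable[int],
    exposure_b: Iterable[float],
) -> ZinbComparison:
    """Likelihood-ratio test of a group effect on the ZINB event rate.

    Group B's event rate relative to group A (rate ratio), tested by
    comparing the pooled fit with and without the group term in the
    count model (chi-square, 1 df).
    """
    ya = np.asarray(list(counts_a), dtype=float)
    yb = np.asarray(list(counts_b), dtype=float)
    ea = np.asarray(list(exposure_a), dtype=float)
    eb = np.asarray(list(exposure_b), dtype=float)
    if ya.size < 10 or yb.size < 10:
        raise ValueError("zinb_compare needs at least 10 patients per arm")
    y = np.concatenate([ya, yb])
    ex = np.concatenate([ea, eb])
    if np.all(y == 0):
        raise DegenerateDataError("all counts are zero")
    grp = np.concatenate([np.zeros(ya.size), np.ones(yb.size)])
    n = y.size
    exog_full = np.column_stack([np.ones(n), grp])
    exog_infl = np.ones((n, 1))
    res_full = _fit_zinb(y, exog_full, exog_infl, ex)
    res_null = _fit_zinb(y, np.ones((n, 1)), exog_infl, ex)
    lr = 2.0 * (float(res_full.llf) - float(res_null.llf))
    lr = max(lr, 0.0)
    beta = float(np.asarray(res_full.params)[2])  # [infl, const, group, alpha]
    converged = bool(res_full.mle_retvals.get("converged", False)) and bool(
        res_null.mle_retvals.get("converged", False)
    )
    return ZinbComparison(
        rate_ratio=math.exp(beta),
        p=float(sps.chi2.sf(lr, 1)),
        lr_stat=lr,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# proportion contrasts and the assembled report


@dataclass
class ProportionTest:
    p: float
    method: str
    pct_a: float
    pct_b: float

    def as_dict(self) -> dict:
        return {
            "p": self.p,
            "method": self.method,
            "pct_a": self.pct_a,
            "pct_b": self.pct_b,
        }


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> ProportionTest:
    """Chi-square on the 2x2 table, Fisher exact when cells are sparse."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.min() < 0 or n1 == 0 or n2 == 0:
        raise ValueError("invalid 2x2 table")
    expected = sps.contingency.expected_freq(table)
    if expected.min() < 5:
        _, p = sps.fisher_exact(table)
        method = "fisher"
    else:
        _, p, _, _ = sps.chi2_contingency(table, correction=False)
        method = "chi2"
    return ProportionTest(
        p=float(p), method=method, pct_a=pct(k1, n1), pct_b=pct(k2, n2)
    )


def _arm_report(
    ds: TrialDataset, config: ProtocolConfig
) -> dict:
    summary = summarize_events(ds)
    ttt = time_to_target(ds)
    km = km_fit(ttt["time_h"], ttt["event"])
    dev = detect_deviations(ds.all_records(), config)
    per_day = np.array(ds.per_day_measurements())
    by_profile = {}
    for prof in Frailty:
        try:
            by_profile[prof.value] = summarize_events(ds, prof).as_dict()
        except ValueError:
            pass
    return {
        "n_patients": ds.n_patients,
        "n_measurements": ds.n_records,
        "events": summary.as_dict(),
        "events_by_profile": by_profile,
        "percent_in_target": percent_in_target(ds),
        "time_to_target": {
            "n_events": int(ttt["event"].sum()),
            "median_h": km.median,
            "km_curve": km.curve(),
        },
        "variability": variability_stats(ds).as_dict(),
        "recurrence_after_first_hypo": recurrence_after_first(ds).as_dict(),
        "deviations": dev.as_dict(),
        "bg_per_day": {
            "mean": round_half_up(float(per_day.mean()), 1),
            "sd": round_half_up(float(per_day.std(ddof=1)), 1)
            if per_day.size > 1
            else None,
        },
    }


def compare_arms(
    static: TrialDataset,
    dynamic: TrialDataset,
    config: ProtocolConfig | None = None,
    include_zinb: bool = True,
) -> dict:
    """Assemble the full two-arm evaluation report (JSON-ready dict).

    Per-arm blocks carry every statistic with its raw fraction alongside
    the rounded percentage; the contrast block carries the Cox hazard
    ratio for time-to-target (dynamic vs static), two-proportion tests
    for the rate contrasts and, optionally, the ZINB rate ratio for
    per-patient hypoglycaemia counts.
    """
    config = config or default_dynamic_config()
    arms = {"static": _arm_report(static, config), "dynamic": _arm_report(dynamic, config)}

    ts, td = time_to_target(static), time_to_target(dynamic)
    times = np.concatenate([ts["time_h"], td["time_h"]])
    events = np.concatenate([ts["event"], td["event"]])
    group = np.array(["static"] * len(ts) + ["dynamic"] * len(td))
    contrasts: dict = {}
    try:
        cox = cox_two_group(times, events, group, reference="static")
        contrasts["cox_time_to_target"] = cox.as_dict()
    except (ValueError, ConvergenceError) as exc:
        contrasts["cox_time_to_target"] = {"error": str(exc)}

    ss, sd_ = summarize_events(static), summarize_events(dynamic)
    pit_s, pit_d = percent_in_target(static), percent_in_target(dynamic)
    contrasts["in_target_overall"] = two_proportion_test(
        *pit_s["overall"], *pit_d["overall"]
    ).as_dict()
    contrasts["mild_hypo_rate"] = two_proportion_test(
        ss.mild_episodes, ss.n_measurements, sd_.mild_episodes, sd_.n_measurements
    ).as_dict()
    contrasts["marked_hypo_rate"] = two_proportion_test(
        ss.marked_episodes, ss.n_measurements, sd_.marked_episodes, sd_.n_measurements
    ).as_dict()

    rec_s = recurrence_after_first(static)
    rec_d = recurrence_after_first(dynamic)
    if rec_s.n >= 2 and rec_d.n >= 2:
        t, p = sps.ttest_ind(
            list(rec_s.per_patient.values()),
            list(rec_d.per_patient.values()),
            equal_var=False,
        )
        contrasts["recurrence_after_first_hypo"] = {
            "mean_pct_static": round_half_up(rec_s.mean, 1),
            "mean_pct_dynamic": round_half_up(rec_d.mean, 1),
            "p_welch": float(p),
        }

    if include_zinb:
        def _counts(ds: TrialDataset):
            c, e = [], []
            for pid, recs in ds.records.items():
                c.append(sum(1 for r in recs if r.category in HYPO_CATEGORIES))
                e.append(len(recs))
            return c, e

        try:
            cs, es = _counts(static)
            cd, ed = _counts(dynamic)
            contrasts["zinb_hypo_counts"] = zinb_compare(cs, es, cd, ed).as_dict()
        except (ValueError, ConvergenceError, DegenerateDataError) as exc:
            contrasts["zinb_hypo_counts"] = {"error": str(exc)}

    return {"arms": arms, "contrasts": contrasts}
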