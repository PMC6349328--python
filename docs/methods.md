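# Methods

## Protocol engines

Both engines are pure functions of (measurement, state, config), so they
can be audited cell-by-cell against the written rule.

**Classification.** BG bands form a partition of (0, ∞) per profile:
marked hypoglycaemia below `marked_hypo_below`; mild hypoglycaemia
lower-closed `[marked_hypo_below, mild_hypo_high)`; below-target
`[mild_hypo_high, target_low)`; the target band closed on both ends;
severe hyperglycaemia strictly above 250 mg/dl; the rest above-target.
The published band descriptions ("between 70–100") do not fix the
boundary conventions; lower-closed hypo bands and a closed target band
were chosen so the categories are a true partition, and the conventions
are asserted by property tests.

**Static engine.** A stateless sliding scale: (0,80)→0, [80,140)→0.5,
[140,180)→1, [180,250)→2, [250,300)→3, [300,350)→4, [350,∞)→5 u/h. The
original before-period chart is not public; this table is a
*configuration default* standing in for it — a conventional scale with
the stateless property that defines the family — not a claim about the
original document. Every number is editable in `ProtocolConfig`.

**Dynamic engine.** Discrete rate tiers (0, 0.5, 1, 2, 3, 4, 6, 8 u/h)
with one-tier shifts driven by the BG category and the rate of change
roc = ΔBG/Δt since the previous measurement:

- above target: step up if roc ≥ −10 mg/dl/h (not falling enough); step
  down if roc < −50 (falling dangerously fast); otherwise maintain;
- in target: maintain, except step down if roc < −50;
- below target but not hypoglycaemic: step down;
- any hypoglycaemia: suspend, give rescue glucose (15 g mild / 30 g
  marked), recheck in 30 min; resume at half the pre-suspension rate
  (floored to a tier) at the first reading at or above the mild band's
  upper edge.

Tiered one-step shifts (rather than continuous multipliers) mirror how
nurse-executed paper charts are laid out. Shifts saturate at both ends.
The starting rate is BG/100 u/h snapped to the nearest tier (ties to the
higher tier; no insulin below 100 mg/dl). An earlier floor-and-snap-down
variant of the starting rule was discarded because it made the dynamic
chart start one tier *below* the static scale at almost every admission
BG, which inverts the intended comparison at the first check for no
clinical reason.

**Monitoring.** 2 h between checks until the target has been reached
once (a latch: the measurement that first reaches the target still
schedules at 2 h), 4 h afterwards, 0.5 h after hypoglycaemia. Deviations
are counted against a 20 min tolerance, separately for monitoring gaps
and for the reaction to hypoglycaemia, since the tolerance's intended
scope is ambiguous; both are configurable.

## Virtual patients

The simulator needs plausible, controllable dynamics — not
pharmacokinetic fidelity — so it uses a one-compartment
proportional-disposal model:

    dI/dt  = (rate − I) / τᵢ                        τᵢ = 1 h
    dBG/dt = EGP + meal(t) − sᵢ · I · BG/100  (+ σ·dW)

Euler-integrated at dt = 0.1 h, BG floored at 20 mg/dl, insulin at 0.
With constant rate, no meals and no noise, BG converges to the fixed
point 100·EGP/(sᵢ·rate) monotonically once insulin has equilibrated
(verified against the closed form in tests). Meals are raised-cosine
pulses of 2 h width at 07:00/12:00/19:00 integrating to 60 mg/dl each.
Meter error is multiplicative with 5% CV. Rescue glucose raises BG by
4 mg/dl per gram.

**Cohort defaults** (all in `CohortSpec`): n as requested; 58% frail;
admission BG normal(250, 105) truncated at 100 mg/dl; insulin
sensitivity sᵢ lognormal with median 8 (mg/dl)/u and log-SD 0.4; frail
patients get 0.7× sᵢ and 1.5× process noise (the mechanism behind their
greater observed instability); EGP 50 mg/dl/h; process noise
15 mg/dl/√h; follow-up 168 h (a 7-day horizon); infusion stops after
48 h continuously in target.

**Calibration.** The admission profile (mean, SD, frail share) matches
the admission table of the population being emulated. The physiology
constants were calibrated so that the simulated cohort sits in the
severely insulin-resistant regime that population's HbA1c of ~10–11%
implies: with EGP 50 and median sᵢ 8, holding BG at 180 mg/dl requires
≈3.5 u/h, and a substantial minority of patients need 6–8 u/h — rates
the static scale's mid-bands never prescribe. A first-pass calibration
(sᵢ median 20, EGP 60) made both protocols control glycaemia within
2–4 h, which is neither clinically credible for this population nor able
to resolve protocol differences on a 2 h check grid.

**What the simulation shows, and what it does not.** In this regime the
static scale stalls on resistant patients (its [180,250) band prescribes
2 u/h, below their equilibrium requirement), while the dynamic chart
ratchets up until BG falls — this is precisely the clinical argument for
rate-of-change algorithms, and it makes the dynamic arm's
time-to-target advantage a structural consequence, reproduced in ≥95%
of replicated trials. Two descriptive quantities are *not* reproduced
and should not be read as claims about any real protocol: (i) under
perfect compliance the simulated static arm reaches the target in only
~60% of patients with a median of tens of hours, far worse than
observed wards, where nurses deviate from weak charts more than half
the time and thereby rescue them; (ii) hypoglycaemia frequencies are
lower than observed (the schematic physiology lacks the meal-timing
errors, renal failure and counter-regulatory failures that cause most
real episodes). The engineered audit fixtures — not the simulator —
carry the published-table marginals used to verify the rate
computations to the printed decimal.

## Trial engine

The before-after design is emulated honestly as two *independent*
cohorts (fresh seeds derived from one master seed) drawn from the same
admission distribution, not as paired patients. Nurse non-compliance is
injected *after* the prescribed action is logged, so every record
carries prescribed and applied columns and feasibility metrics can be
computed exactly as a chart audit would. The per-arm compliance defaults
are the audit levels observed in the two periods (late checks 57%/32%,
unexecuted rate change ~21%, hypoglycaemia prescription not acted on
92%/56%); acceptance checks that concern protocol behaviour use perfect
compliance instead. Every trajectory is a pure function of (spec,
protocol, compliance, seed); three independent seeded streams
(physiology, meter, compliance) keep corruption from perturbing
physiology.

## Statistics

- **Kaplan–Meier** via lifelines; the median is the first observed time
  with S(t) ≤ 0.5 and is reported as undefined when the curve never
  reaches 0.5 (all censored). Tests cross-check against an explicit
  product over risk sets.
- **Cox two-group** via statsmodels PHReg with Breslow tie handling and
  Wald 95% CI; monotone likelihood (non-overlapping risk sets) raises a
  convergence error rather than returning a divergent HR. Tests
  cross-check against grid-search maximization of the hand-written
  Breslow partial likelihood.
- **%CV** = 100·sample SD/mean (ddof 1), per patient over measurements
  from the first in-target record onward; 36% is the stability cut-off.
- **ICC** one-way random-effects ANOVA estimator with Searle's
  k₀ = (N − Σnᵢ²/N)/(g−1) for unbalanced groups; negative estimates
  truncated to 0, capped at 1. Hand-written (no installed
  unbalanced-one-way implementation); tests cross-check hand ANOVA sums
  and the iid limit.
- **Recurrence after the first hypoglycaemia**: per qualifying patient
  (≥1 episode and ≥1 later measurement), 100 × episodes strictly after
  the first / measurements strictly after the first; mean ± sample SD
  across patients. Episode *rates*, by contrast, use all measurements as
  denominator; every output field carries its raw fraction so the
  denominators are explicit.
- **ZINB** fits use statsmodels' zero-inflated negative binomial (NB2)
  with log-exposure offset; non-convergence and all-zero degeneracy are
  raised, never silent. The group comparison is a likelihood-ratio test
  on the count-model group term. The dispersion and inflation
  parameters are weakly identified at realistic sizes, so the recovery
  check uses the median over three replicates of n = 2000.
- **Proportion contrasts**: chi-square without continuity correction,
  switching to Fisher's exact test when any expected cell is below 5;
  α = 0.05 two-sided throughout, no multiplicity adjustment.
- All displayed percentages are rounded half-up to one decimal, matching
  printed clinical tables; `round_half_up` exists because Python's
  built-in banker's rounding disagrees at x.x5.

## Numerical and degenerate-input choices

Measurement times snap to the 0.1 h simulation grid. Log round-trips are
exact: floats are written with `%.17g` and parsed with pandas'
round-trip parser. Records with no rate prescription carry NaN and are
excluded from the rate-deviation denominator only. A patient's final
record has no following gap (NaN) and is excluded from monitoring and
hypo-reaction timing checks. ICC requires within-group replication
(N > g); %CV requires ≥2 values and positive mean; Cox requires ≥1 event
per group.

## Known limitations

- The physiology has no meal-stimulated endogenous insulin, renal
  clearance, counter-regulation or steroid effects; absolute
  hypoglycaemia frequencies are therefore underestimated.
- The static chart and the dynamic chart's numeric content are
  config defaults standing in for unpublished documents; conclusions
  about "the static protocol" are conclusions about this default table.
- Sequential cohorts share a distribution but not patients, so arm
  contrasts carry cohort-sampling noise in addition to protocol effects,
  exactly as the emulated design does.
- The ZINB group comparison can fail to converge on near-deterministic
  count data (e.g. the engineered fixtures); it reports
  `converged: false` with nulled estimates in that case.
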