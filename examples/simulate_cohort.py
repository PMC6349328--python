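"""Sample a virtual cohort and inspect its admission profile.

The generator emulates a poorly controlled diabetic inpatient
population: admission BG ~250 +/- 105 mg/dl (truncated at 100), ~58%
frail patients, lognormal insulin sensitivity with frail patients less
sensitive and noisier.
"""
import numpy as np

import glytrial as gt

spec = gt.CohortSpec(n=200, seed=42)
cohort = gt.sample_cohort(spec)

bg = np.array([p.admission_bg for p in cohort])
s_i = np.array([p.s_i for p in cohort])
frail = np.array([p.profile is gt.Frailty.FRAIL for p in cohort])

print(f"cohort size            {len(cohort)}")
print(f"frail patients         {frail.sum()} ({100 * frail.mean():.1f}%)")
print(f"admission BG (mg/dl)   {bg.mean():.0f} +/- {bg.std(ddof=1):.0f}"
      f"  [{bg.min():.0f}, {bg.max():.0f}]")
print(f"admission BG (mmol/l)  {gt.mgdl_to_mmol(bg.mean()):.1f}")
print(f"insulin sensitivity    frail {s_i[frail].mean():.1f}, "
      f"vigorous {s_i[~frail].mean():.1f} (mg/dl per unit)")
print("\nFrail patients get a wider target band (140-220 vs 100-180 mg/dl)")
print("and higher hypoglycaemia thresholds, so the same BG can classify")
print("differently:", end=" ")
print("BG 85 is", gt.classify_bg(85, gt.Frailty.FRAIL).value, "for frail,",
      gt.classify_bg(85, gt.Frailty.VIGOROUS).value, "for vigorous.")
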