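"""Emulate the two-period design and compare the protocols.

Two independent cohorts are drawn from the same admission distribution;
the first runs under the static sliding scale, the second under the
dynamic algorithm; both with perfect nurse compliance.  The printed
medians come from Kaplan-Meier fits of the censored time-to-target, and
the hazard ratio from a two-group Cox fit (dynamic vs static: HR > 1
means the dynamic arm reaches the target faster).
"""
import numpy as np

import glytrial as gt
from glytrial.stats import cox_two_group, km_fit, percent_in_target, time_to_target

spec = gt.CohortSpec(n=100)
ds_static, ds_dynamic = gt.before_after(
    spec, gt.default_static_config(), gt.default_dynamic_config(), seed=1
)

for ds in (ds_static, ds_dynamic):
    ttt = time_to_target(ds)
    km = km_fit(ttt["time_h"], ttt["event"])
    pit = percent_in_target(ds)
    median = "never" if km.median is None else f"{km.median:.1f} h"
    print(f"{ds.arm:8s}  measurements {ds.n_records:5d}   "
          f"median time-to-target {median:>7s}   "
          f"in-target {pit['overall_pct']:.1f}%   "
          f"reached {int(ttt['event'].sum())}/{len(ttt)}")

ts, td = time_to_target(ds_static), time_to_target(ds_dynamic)
cox = cox_two_group(
    np.concatenate([ts["time_h"], td["time_h"]]),
    np.concatenate([ts["event"], td["event"]]),
    ["static"] * len(ts) + ["dynamic"] * len(td),
    reference="static",
)
print(f"\nCox hazard ratio (dynamic vs static): {cox.hr:.2f} "
      f"[{cox.ci_low:.2f}; {cox.ci_high:.2f}], p = {cox.p:.2g}")
print("HR > 1: the dynamic algorithm controls hyperglycaemia faster because")
print("it ratchets the rate up whenever BG fails to fall under the current one.")
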