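"""Walk through single protocol decisions for both infusion engines.

Shows how the same sequence of BG readings is handled by the stateless
sliding scale and by the rate-of-change tier algorithm.
"""
import glytrial as gt

static = gt.default_static_config()
dynamic = gt.default_dynamic_config()

print("Admission BG 260 mg/dl (vigorous patient, target 100-180):")
print(f"  static scale starts at   {gt.initial_rate(260, static):.1f} u/h")
print(f"  dynamic chart starts at  {gt.initial_rate(260, dynamic):.1f} u/h")

# two hours later, BG barely moved: the dynamic engine reacts, the static
# scale cannot (260 and 255 sit in the same band)
state = gt.InfusionState(rate=gt.initial_rate(260, dynamic))
action = gt.dynamic_rate(260, 255, 2.0, state, gt.Frailty.VIGOROUS, dynamic)
print("\nBG 260 -> 255 over 2 h (falling only 2.5 mg/dl/h):")
print(f"  static keeps             {gt.static_rate(255, static):.1f} u/h")
print(f"  dynamic: {action.note.value:9s} ->    {action.new_rate:.1f} u/h "
      f"(next check in {action.next_check_in:.1f} h)")

# a rapid fall triggers a pre-emptive step down instead
action = gt.dynamic_rate(260, 140, 2.0, gt.InfusionState(rate=3.0),
                         gt.Frailty.VIGOROUS, dynamic)
print("\nBG 260 -> 140 over 2 h (falling 60 mg/dl/h):")
print(f"  dynamic: {action.note.value:9s} ->    {action.new_rate:.1f} u/h")

# hypoglycaemia suspends the infusion and prescribes rescue glucose
action = gt.dynamic_rate(120, 62, 2.0, gt.InfusionState(rate=1.0),
                         gt.Frailty.VIGOROUS, dynamic)
print("\nBG 62 mg/dl (mild hypoglycaemia, vigorous):")
print(f"  dynamic: {action.note.value} -> rate {action.new_rate:.1f} u/h, "
      f"{action.glucose_bolus_g:.0f} g glucose, recheck in "
      f"{action.next_check_in:.1f} h")
print("\nThe tier shift is the dynamic algorithm's whole trick: the current")
print("rate plus the observed fall encode the patient's insulin sensitivity.")
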