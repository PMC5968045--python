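"""Re-derive every published ratio from the published aggregate counts.

Counts mode needs no participant-level data: the per-strategy referral
and detection counts published for the KolosSal cohort are enough to
recompute sensitivities with exact 95% confidence intervals, NCN,
incremental NCN and negative predictive values.
"""

from sigscreen import Endpoint, evaluate_counts, round_half_up
from sigscreen.published import reference_counts
from sigscreen.reporting import render_sensitivity_table

table = evaluate_counts(reference_counts())

ref = table.get(">=2 neoplasms, >=1 AN", "both")
print(f"most restrictive rule: {ref.n_referred:.0f} colonoscopies, "
      f"{ref.prox_an_detected:.0f} proximal AN detected, "
      f"NCN = {round_half_up(ref.ncn, 1)}")

for name in ("Any AN", "Any neoplasm"):
    o = table.get(name, "both")
    print(f"{name:<14} NCN = {round_half_up(o.ncn, 1):>5}  "
          f"incremental NCN vs reference = "
          f"{round_half_up(o.delta_ncn(ref), 1)}")

men = table.get("No referral", "men")
print(f"\nno-referral CRC sensitivity, men: {men.sens[Endpoint.CRC]}")
npv = table.get("No referral", "both").npv[Endpoint.ANY_AN]
print(f"no-referral NPV for any AN, both sexes: "
      f"{round_half_up(100 * npv.proportion, 1)}%")

print("\n" + render_sensitivity_table(table))
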