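"""Sex-specific referral policies and the cost of imperfect adherence.

Because neoplasia prevalence is roughly twice as high in men, referring
men on any distal neoplasm but women only on a distal advanced neoplasm
detects more proximal AN with fewer colonoscopies than the reverse
pairing that equalizes sensitivity between the sexes.
"""

from sigscreen import Endpoint, adherence_adjusted_gain, evaluate_counts
from sigscreen.published import reference_counts
from sigscreen.reporting import mixed_policy_summary

table = evaluate_counts(reference_counts())

print("lean policy  (men: any neoplasm / women: any AN)")
print(mixed_policy_summary(table, "Any neoplasm", "Any AN").render())
print("\nheavy policy (men: any AN / women: any neoplasm or HPP)")
print(mixed_policy_summary(table, "Any AN", "Any neoplasm or HPP").render())

men_none = table.get("No referral", "men").sens[Endpoint.ANY_AN].pct
men_plco = table.get("US (PLCO)", "men").sens[Endpoint.ANY_AN].pct
for adherence in (1.0, 0.75):
    gain = adherence_adjusted_gain(men_none, men_plco, adherence)
    print(f"\nPLCO any-AN gain in men at {adherence:.0%} adherence: "
          f"{gain:.0f} percentage points over no referral")
# Only attended follow-up colonoscopies contribute the gain, so the
# expected gain scales linearly with the adherence rate.
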