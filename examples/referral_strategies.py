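"""Apply the 12 built-in colonoscopy referral rules to one FS result.

The same distal findings trigger very different referral decisions
across the trial rules (UK, SCORE, NORCCAP, US/PLCO) and the simpler
threshold rules; the PLCO score additionally weighs age and sex.
"""

from sigscreen import (
    Histology,
    Lesion,
    Sex,
    Site,
    builtin_strategies,
    plco_score,
)

# FS of a 62-year-old man: one 6 mm tubular adenoma in the sigmoid
distal = [Lesion(Site.SIGMOID, 6, Histology.ADENOMA_TUBULAR)]
age, sex = 62, Sex.MALE

print(f"distal findings: one 6 mm tubular adenoma; age {age}, {sex.value}\n")
for strategy in builtin_strategies():
    decision = "refer" if strategy(distal, age, sex) else "-"
    print(f"{strategy.name:<28} {decision}")

score = plco_score(age, sex, distal)
print(f"\nPLCO score: age {score.age_points} + sex {score.sex_points} "
      f"+ finding {score.finding_points} = {score.total} "
      f"(referral at >= 4)")
# A small adenoma refers under NORCCAP (any adenoma) and under PLCO for
# this age/sex (2+1+2 = 5), but not under the advanced-lesion rules.
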