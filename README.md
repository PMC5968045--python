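# sigscreen

Evaluation of colonoscopy referral strategies after flexible-sigmoidoscopy
(FS) screening for colorectal cancer.

FS reliably examines the rectum and sigmoid (and often the descending
colon) but cannot see the proximal colon. Proximal neoplasms are found
only indirectly: a distal finding triggers referral to full colonoscopy.
The choice of referral rule therefore trades sensitivity against
colonoscopy burden, and the landmark FS screening trials (UK, SCORE,
NORCCAP, US/PLCO) used very different rules. `sigscreen` takes
participant-level screening-colonoscopy findings — or a synthetic cohort
calibrated to the published marginals of the KolosSal screening study
(N = 14,947, Saarland, Germany) — and quantifies, sex-stratified, what
each of 12 referral strategies would have achieved.

It is a library for epidemiologists and screening-programme modellers,
with a thin CLI (`sigscreen simulate|evaluate|report`) for batch runs.

## Model and metrics

Each lesion is ranked on the neoplasia hierarchy
CRC > advanced adenoma (AA) > non-advanced adenoma > hyperplastic polyp >
other polyp, where an AA is an adenoma with size ≥ 10 mm, (tubulo-)villous
components, or high-grade dysplasia; advanced neoplasia (AN) = CRC or AA.
FS is assumed to detect, within its reach *R* (rectum+sigmoid+descending,
or rectum+sigmoid), exactly what colonoscopy detects; follow-up
colonoscopy after referral detects everything. For a strategy *S* and
endpoint *E* ∈ {CRC, AA, any AN}:

- **Sensitivity** = (carriers of *E* whose endpoint lesions are all
  detected, by FS itself or after referral) / (all carriers of *E*),
  with exact 95% Clopper–Pearson intervals from beta quantiles.
- **NCN** = referred participants / participants in whom a proximal AN is
  detected — colonoscopies needed per proximal AN found.
- **ΔNCN** = Δreferred / Δdetected versus a reference strategy (default:
  the most restrictive rule, "≥2 neoplasms, ≥1 AN").
- **NPV** = P(no proximal AN | not referred).
- **Adherence**: with follow-up attendance probability *a*, the expected
  sensitivity gain over no referral scales as *a* × (full-adherence gain).

## Worked example

Re-derive the published ratios from the embedded per-strategy aggregate
counts — no participant-level data needed:

```python
from sigscreen import Endpoint, evaluate_counts, round_half_up
from sigscreen.published import reference_counts

table = evaluate_counts(reference_counts())
ref = table.get(">=2 neoplasms, >=1 AN", "both")
print(round_half_up(ref.ncn, 1))                    # 8.2
print(round_half_up(table.get("Any AN", "both").delta_ncn(ref), 1))  # 11.8
print(str(table.get("No referral", "men").sens[Endpoint.CRC]))
# 84% (77-90%)
```

Running `python examples/published_counts_reanalysis.py` prints:

```
most restrictive rule: 547 colonoscopies, 67 proximal AN detected, NCN = 8.2
Any AN         NCN =   9.9  incremental NCN vs reference = 11.8
Any neoplasm   NCN =  14.8  incremental NCN vs reference = 17.8

no-referral CRC sensitivity, men: 84% (77-90%)
no-referral NPV for any AN, both sexes: 96.1%
```

i.e. without any referral FS alone would already find 84% of male CRC
carriers; the most restrictive rule needs 8.2 colonoscopies per proximal
AN detected, and relaxing it to "any distal AN" costs 11.8 additional
colonoscopies per additional proximal AN.

The other `examples/` scripts each demonstrate one capability: lesion
classification, referral-rule decisions with the PLCO score, generating
and evaluating a calibrated synthetic cohort, and sex-specific mixed
policies with adherence adjustment.

Participant-level analyses run on two CSVs (`id,sex,age` and
`participant_id,site,size_mm,histology,hgd`):

```sh
sigscreen simulate --n 14947 --seed 1 --out sim/
sigscreen evaluate --participants sim/participants.csv \
                   --lesions sim/lesions.csv --out results/
sigscreen report --metrics results/metrics.csv \
                 --men-strategy "Any neoplasm" --women-strategy "Any AN"
```

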