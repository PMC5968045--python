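# Methods

## Setting and model

`sigscreen` models once-only flexible sigmoidoscopy (FS) screening whose
findings may trigger referral to full colonoscopy, using complete
screening-colonoscopy records as the ground truth: every lesion's site,
size, histology and dysplasia grade are known, and FS is assumed to find,
within its reach, exactly what colonoscopy found there. This
derive-FS-from-colonoscopy design means estimated FS sensitivities are
*expected* sensitivities under the stated reach assumption, not observed
FS performance; bowel preparation, sedation, operator and insertion-depth
effects are outside the model.

Assumptions, in order of impact:

1. **Reach.** Distal = within FS reach. Main analysis: rectum, sigmoid
   and descending colon are visualized (`descending_visualized`);
   sensitivity analysis: rectum and sigmoid only (`sigmoid_only`). A
   lesion at the splenic flexure or beyond is always proximal.
2. **Perfect FS within reach, perfect colonoscopy after referral.** No
   miss-rate parameters; a referred and attending participant has all
   proximal lesions detected.
3. **Referral decisions see only distal findings** plus age and sex (used
   by the PLCO score alone). This blinding is enforced structurally and
   property-tested.
4. **Adherence.** Attendance at follow-up colonoscopy is an independent
   per-participant Bernoulli(a) coin (default a = 1). The evaluator
   reports either the closed-form expectation over this coin or means
   over seeded Monte-Carlo replicates (default 200); both agree by
   linearity, and the expected sensitivity *gain* over no referral scales
   exactly linearly in a.

## Lesion classification

Advanced adenoma (AA): adenoma with size ≥ 10 mm, (tubulo-)villous
components, or high-grade dysplasia; advanced neoplasia (AN): CRC or AA.
Sizes are integer millimetres and "≥ 1 cm" is `size_mm >= 10`, avoiding
unit mixing and float comparisons. An adenoma with missing size and no
other advanced feature cannot be asserted advanced and is classified
non-advanced with an audit warning. Participants with any
missing-location lesion are dropped by default (such a lesion cannot be
placed relative to reach); a lesion-only drop mode exists.

## Endpoints and detection semantics

Endpoint membership: CRC = at least one cancer; AA = advanced adenoma as
the **most advanced** finding (cancer carriers belong to the CRC
endpoint, keeping the endpoint denominators disjoint); any-AN = at least
one AN lesion. The default detection rule is `all_lesions`: a carrier
counts as detected only when *every* lesion of the endpoint class is
found. This makes the any-AN detected count smaller than the sum of the
CRC and AA columns whenever a distal cancer coexists with an undetected
proximal AA — the published no-referral counts reconcile exactly under
this rule (men 118 + 646 − 752 = 12 such mixed carriers, women 1). The
alternative `any_lesion` rule (one found lesion suffices) is implemented
because the prose definition of sensitivity alone is ambiguous; the
default reproduces the published arithmetic.

## Referral strategies

Twelve built-ins: a no-referral baseline, the UK / SCORE / NORCCAP / US
(PLCO) trial rules, and seven threshold rules over distal findings (≥2
neoplasms with ≥1 AN; ≥2 neoplasms; histology-defined AN; AN ≥ 1 cm; any
AN; any neoplasm; any neoplasm or hyperplastic polyp). Wording
conventions:

- "Polyp" includes hyperplastic and other/unspecified polyps; "adenoma"
  and "neoplasm" exclude them.
- Count criteria (≥ 3 adenomas, ≥ 2 neoplasms) count distal lesion rows.
- UK's "polyp or adenoma > 1 cm" is read with the trial's published
  ≥ 1 cm convention (`size_mm >= 10`); a strict-inequality knob
  (`uk_large_polyp_strict`) is exposed since the wording is not
  resolvable. SCORE's "polyp(s) > 5 mm" is strict.
- UK's "≥ 20 hyperplastic polyps above the rectum" counts distal
  non-rectal hyperplastic lesion rows; without recorded multiplicity it
  simply never fires.
- PLCO score = age points (55–59: 1, 60–64: 2, 65–70: 3) + male (1) +
  most advanced distal finding (none 0, non-neoplastic polyp 1, small
  tubular adenoma 2, advanced lesion 3), referral at ≥ 4. The published
  age bands stop at 70; ages 71–79 keep 3 points (monotone extension —
  the only defensible choice for a 55–79 cohort, flagged here
  deliberately). An other/unspecified polyp scores 1, the lowest polyp
  rung. Ages below 50 are outside the score's definition and raise.

Custom rules can be supplied as restricted boolean expressions over
distal-finding summaries (`n_adenomas`, `n_an`, `max_size_mm`, `age`,
`male`, …), compiled once and checked for unknown names.

## Outcome measures

Clopper–Pearson 95% intervals use beta-distribution quantiles
(`scipy.stats.beta.ppf`), with the conventional closed boundaries at
x = 0 and x = n. NCN = referred / proximal-AN-detected; incremental NCN =
Δreferred / Δdetected versus the most restrictive rule ("≥2 neoplasms,
≥1 AN"), any other pair being computable the same way. Undefined ratios
(zero detections, zero increments) propagate as missing, rendered `NA` —
never 0 or ∞. Display rounding is decimal half-up: whole percent for
proportions, one decimal for NCN/ΔNCN; internal values keep full
precision. A counts-mode evaluator accepts pre-aggregated per-strategy
counts and recomputes every ratio identically, which is how the published
aggregate tables are re-derived without participant-level data.

## Synthetic cohort generator

The generator replaces the undeposited participant-level data. Calibrated
marginals (stored as exact count ratios so probability vectors sum to 1):
sex ratio (49.0% male); per-sex age-band distributions; per-sex
most-advanced-finding prevalences (e.g. male CRC 140/7323, AA 985/7323);
per-sex fractions of CRC and AA carriers whose advanced lesions are all
distal (118/140, 51/73, 646/971, 345/544); per-sex proximal-AN carrier
rates (359/7323, 222/7624).

Mechanism: sample sex, age band then uniform age, and the most-advanced
class; place the index lesion distal/proximal by the class- and
sex-specific fraction; give distal-CRC carriers a synchronous proximal AA
with a probability *derived* from the carrier-rate target (so the three
carrier sources — proximal CRC, proximal-AA-as-index, mixed CRC cases —
sum exactly to the target); add synchronous lesser lesions
(Poisson-distributed count, classes never exceeding the index class so
the intended most-advanced class round-trips through the classifier).
For women the derived mixed-case probability clamps at zero because the
first two sources already slightly exceed the target (by 0.03 percentage
points, well inside sampling error of the published counts themselves).
An odds-multiplier knob scales the mixed-case probability for
sensitivity studies of the distal–proximal association; the default 1.0
is the conditional-independence calibration.

Invented stand-ins (unpublished, chosen once as field-plausible and
documented as such): distal fractions of non-advanced adenomas (0.70),
hyperplastic (0.85) and other polyps (0.70); class-conditional size
distributions (non-advanced adenomas 2–9 mm; AAs a 55/45 mixture of
≥ 10 mm lesions and small villous/HGD lesions; cancers 15–60 mm);
multiplicity (Poisson mean 0.6 synchronous lesser lesions); site mixes
within the distal and proximal colon; and a rare (3%) many-hyperplastic
phenotype of 12–25 distal polyps that makes the UK ≥ 20-polyp arm
exercisable. Because synchronous advanced lesions beyond the index (plus
the mixed CRC case) are not generated, per-strategy referral counts and
proximal-AN yields of specific strategies are **not** reproduced by the
generator — only the calibrated marginals above are. Passing tests on
synthetic cohorts therefore validate the pipeline's logic and the
marginal calibration, not strategy-level performance on real data; the
published per-strategy counts are covered separately through counts mode.

## Numerical and procedural choices

- All randomness flows through `numpy.random.default_rng(seed)`;
  generation and evaluation are bit-reproducible given a seed, and CLI
  outputs embed a configuration hash.
- Problem sizes for the property checks: 100 cohorts of n = 2,000 for
  monotonicity along nested rule chains; 2,000 draws per (p, n) cell —
  plus the exact pmf sum — for interval coverage; n = 200,000 with a 3-SE
  band for parameter recovery. These sizes put sampling error well below
  the tested tolerances while keeping the default suite under a minute.
- Empty strata are omitted with a warning; empty denominators propagate
  as missing estimates.

## Limitations

Sessile serrated polyps are not modelled (not systematically recorded in
the source data). No colonoscopy miss rates, no per-segment partial FS
insertion, no costs, no FIT-combination strategies, and no
incidence/mortality projection — the outputs are cross-sectional
detection metrics. The synthetic joint distribution of distal findings
and proximal neoplasia is a conditional-independence stand-in; real
cohorts show positive association, which the odds knob can emulate but
not calibrate.
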