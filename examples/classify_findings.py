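"""Classify individual colonoscopy findings on the neoplasia hierarchy.

An adenoma is *advanced* if it is >= 10 mm, has (tubulo-)villous
components, or shows high-grade dysplasia; cancer outranks everything.
"""

from sigscreen import (
    Histology,
    Lesion,
    Participant,
    Sex,
    Site,
    classify_lesion,
    most_advanced_finding,
)

findings = [
    ("12 mm tubular adenoma, sigmoid",
     Lesion(Site.SIGMOID, 12, Histology.ADENOMA_TUBULAR)),
    ("5 mm tubular adenoma, rectum",
     Lesion(Site.RECTUM, 5, Histology.ADENOMA_TUBULAR)),
    ("4 mm villous adenoma, rectum",
     Lesion(Site.RECTUM, 4, Histology.ADENOMA_VILLOUS)),
    ("6 mm tubular adenoma with HGD, descending",
     Lesion(Site.DESCENDING, 6, Histology.ADENOMA_TUBULAR,
            high_grade_dysplasia=True)),
    ("carcinoma, cecum", Lesion(Site.CECUM, 30, Histology.CRC)),
    ("3 mm hyperplastic polyp, sigmoid",
     Lesion(Site.SIGMOID, 3, Histology.HYPERPLASTIC)),
]

for label, lesion in findings:
    print(f"{label:<45} -> {classify_lesion(lesion).name}")

carrier = Participant("demo", Sex.MALE, 64,
                      [lesion for _, lesion in findings[:2]])
print(f"\nmost advanced finding of the two-adenoma carrier: "
      f"{most_advanced_finding(carrier).name}")
# The participant-level category (here ADVANCED_ADENOMA) drives both the
# endpoint denominators and, via the distal subset, referral decisions.
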