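"""Published aggregate counts from the KolosSal screening-colonoscopy cohort.

The participant-level data of the KolosSal study (a statewide German
screening-colonoscopy cohort, N = 14,947 after eligibility exclusions)
are not publicly deposited, but the published per-strategy aggregate
counts are: number of colonoscopy referrals, endpoint carriers and
detections (CRC / advanced adenoma / any advanced neoplasia), and
proximal-AN detections, for each referral strategy and sex stratum under
the descending-colon reach assumption at full adherence. These counts
are the inputs to the counts-mode evaluator and let every published
ratio (sensitivity, CI, NCN, incremental NCN, NPV) be re-derived without
individual data.

Endpoint denominators: men CRC 140, AA 971, any-AN 1111, proximal AN 359
of 7323; women 73 / 544 / 617, proximal AN 222 of 7624; both sexes
213 / 1515 / 1728, proximal AN 581 of 14,947.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["reference_counts", "STRATUM_SIZES", "PROX_AN_TOTALS"]

STRATUM_SIZES = {"men": 7323, "women": 7624, "both": 14947}
PROX_AN_TOTALS = {"men": 359, "women": 222, "both": 581}
_ENDPOINT_TOTALS = {  # stratum -> (crc_total, aa_total, an_total)
    "men": (140, 971, 1111),
    "women": (73, 544, 617),
    "both": (213, 1515, 1728),
}

# strategy; per stratum: n_referred, crc_det, aa_det, an_det, prox_an_det
_COUNTS_CSV = """\
strategy,stratum,n_referred,crc_detected,aa_detected,an_detected,prox_an_detected
No referral,men,0,118,646,752,0
UK FS screening trial,men,965,126,740,866,114
SCORE,men,1146,126,751,877,125
NORCCAP,men,2004,127,787,914,162
US (PLCO),men,4167,135,887,1022,270
">=2 neoplasms, >=1 AN",men,395,122,686,808,56
>=2 neoplasms,men,630,123,703,826,74
Histology-defined AN,men,617,124,703,827,75
AN >= 1 cm,men,639,122,706,828,76
Any AN,men,854,125,729,854,102
Any neoplasm,men,1941,127,781,908,156
Any neoplasm or HPP,men,2737,127,816,943,191
No referral,women,0,51,345,395,0
UK FS screening trial,women,456,52,372,424,29
SCORE,women,586,52,377,429,34
NORCCAP,women,1216,57,396,453,58
US (PLCO),women,1062,57,388,445,50
">=2 neoplasms, >=1 AN",women,152,52,354,406,11
>=2 neoplasms,women,263,53,358,411,16
Histology-defined AN,women,307,52,363,415,20
AN >= 1 cm,women,314,52,359,411,16
Any AN,women,422,52,370,422,27
Any neoplasm,women,1186,57,394,451,56
Any neoplasm or HPP,women,1874,57,412,469,74
No referral,both,0,169,991,1147,0
UK FS screening trial,both,1421,178,1112,1290,143
SCORE,both,1732,178,1128,1306,159
NORCCAP,both,3220,184,1183,1367,220
US (PLCO),both,5229,192,1275,1467,320
">=2 neoplasms, >=1 AN",both,547,174,1040,1214,67
>=2 neoplasms,both,893,176,1061,1237,90
Histology-defined AN,both,924,176,1066,1242,95
AN >= 1 cm,both,953,174,1065,1239,92
Any AN,both,1276,177,1099,1276,129
Any neoplasm,both,3127,184,1175,1359,212
Any neoplasm or HPP,both,4611,184,1228,1412,265
"""


def reference_counts() -> pd.DataFrame:
    """Published per-strategy aggregate counts as a counts-mode table.

    One row per strategy x stratum with the columns expected by
    :func:`sigscreen.metrics.evaluate_counts`.
    """
    df = pd.read_csv(io.StringIO(_COUNTS_CSV))
    df["stratum_n"] = df["stratum"].map(STRATUM_SIZES)
    df["prox_an_total"] = df["stratum"].map(PROX_AN_TOTALS)
    totals = df["stratum"].map(_ENDPOINT_TOTALS)
    df["crc_total"] = [t[0] for t in totals]
    df["aa_total"] = [t[1] for t in totals]
    df["an_total"] = [t[2] for t in totals]
    return df
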