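"""Sigmoidoscope reach and detection bookkeeping.

Flexible sigmoidoscopy (FS) sees the distal bowel only. Two reach
assumptions are supported: the instrument visualizes up to and including
the descending colon (main analysis) or only up to the sigmoid colon
(sensitivity analysis). FS is assumed to detect, within reach, exactly
what colonoscopy detects; proximal lesions are found only if a referral
to full colonoscopy is made and attended, and that colonoscopy is assumed
to find everything.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal

from .cohort_model import (
    Lesion,
    NeoplasiaClass,
    Participant,
    Site,
    classify_lesion,
    most_advanced_finding,
)

__all__ = [
    "ReachAssumption",
    "DetectionMode",
    "Endpoint",
    "DetectionResult",
    "is_distal",
    "distal_lesions",
    "apply_screening",
    "endpoint_status",
]


class ReachAssumption(str, enum.Enum):
    DESCENDING_VISUALIZED = "descending_visualized"
    SIGMOID_ONLY = "sigmoid_only"

    @property
    def distal_sites(self) -> frozenset[Site]:
        return _DISTAL_SITES[self]


_DISTAL_SITES = {
    ReachAssumption.DESCENDING_VISUALIZED: frozenset(
        {Site.RECTUM, Site.SIGMOID, Site.DESCENDING}
    ),
    ReachAssumption.SIGMOID_ONLY: frozenset({Site.RECTUM, Site.SIGMOID}),
}


class DetectionMode(str, enum.Enum):
    """How a participant counts as 'detected' for an endpoint.

    ALL_LESIONS: every lesion of the endpoint class must be found (a
    participant with a distal cancer found at FS but an unexamined
    proximal advanced adenoma is *not* detected for the any-AN endpoint).
    ANY_LESION: one found lesion of the class suffices.
    """

    ALL_LESIONS = "all_lesions"
    ANY_LESION = "any_lesion"


class Endpoint(str, enum.Enum):
    CRC = "crc"
    AA = "aa"
    ANY_AN = "any_an"


#: Lesion classes belonging to each endpoint.
ENDPOINT_CLASSES = {
    Endpoint.CRC: frozenset({NeoplasiaClass.CRC}),
    Endpoint.AA: frozenset({NeoplasiaClass.ADVANCED_ADENOMA}),
    Endpoint.ANY_AN: frozenset(
        {NeoplasiaClass.CRC, NeoplasiaClass.ADVANCED_ADENOMA}
    ),
}


def is_distal(site: Site, reach: ReachAssumption) -> bool:
    """True if the segment is within FS reach under the given assumption."""
    if not isinstance(site, Site):
        raise ValueError(f"not a valid site: {site!r} (missing sites must be "
                         "resolved or excluded upstream)")
    return site in reach.distal_sites


def distal_lesions(participant: Participant, reach: ReachAssumption) -> list[Lesion]:
    return [l for l in participant.lesions if is_distal(l.site, reach)]


@dataclass
class DetectionResult:
    """Per-participant outcome of one FS screening round under one strategy."""

    participant_id: str
    referred: bool
    attended_colonoscopy: bool
    distal_detected: list[Lesion] = field(default_factory=list)
    proximal_detected: list[Lesion] = field(default_factory=list)

    @property
    def detected(self) -> list[Lesion]:
        return self.distal_detected + self.proximal_detected


def apply_screening(
    participant: Participant,
    referred: bool,
    reach: ReachAssumption,
    attends: bool = True,
) -> DetectionResult:
    """Compute what the screening episode detects for one participant.

    FS finds every distal lesion. If the (already computed) referral
    decision is positive and the participant attends, the follow-up
    colonoscopy additionally finds every proximal lesion.
    """
    distal = distal_lesions(participant, reach)
    attended = referred and attends
    proximal = (
        [l for l in participant.lesions if not is_distal(l.site, reach)]
        if attended
        else []
    )
    return DetectionResult(
        participant_id=participant.id,
        referred=referred,
        attended_colonoscopy=attended,
        distal_detected=distal,
        proximal_detected=proximal,
    )


def endpoint_status(
    participant: Participant,
    result: DetectionResult,
    endpoint: Endpoint | str,
    mode: DetectionMode | str = DetectionMode.ALL_LESIONS,
) -> tuple[bool, bool]:
    """(carries endpoint, endpoint detected) for one participant.

    Endpoint membership: CRC = at least one cancer; AA = advanced adenoma
    as the most advanced finding (cancer carriers are counted under CRC,
    not AA); any-AN = at least one advanced neoplasm. Under ALL_LESIONS a
    carrier is detected only if every lesion of the endpoint's class set
    was found; under ANY_LESION one found lesion suffices.
    """
    endpoint = Endpoint(endpoint)
    mode = DetectionMode(mode)
    if endpoint is Endpoint.AA:
        has = most_advanced_finding(participant) is NeoplasiaClass.ADVANCED_ADENOMA
    else:
        classes = ENDPOINT_CLASSES[endpoint]
        has = any(classify_lesion(l) in classes for l in participant.lesions)
    if not has:
        return (False, False)
    classes = ENDPOINT_CLASSES[endpoint]
    target = [l for l in participant.lesions if classify_lesion(l) in classes]
    found = result.detected
    if mode is DetectionMode.ALL_LESIONS:
        detected = all(l in found for l in target)
    else:
        detected = any(l in found for l in target)
    return (True, detected)
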