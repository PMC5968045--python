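import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

from sigscreen import (
    Cohort,
    Histology,
    Lesion,
    Participant,
    Sex,
    Site,
)


def lesion(site, histology, size=None, hgd=False):
    return Lesion(site=Site(site), size_mm=size, histology=Histology(histology),
                  high_grade_dysplasia=hgd)


@pytest.fixture
def toy_cohort():
    """Six hand-analysable participants covering the main case mix:
    distal cancer, proximal advanced adenoma behind a non-advanced distal
    finding, small villous adenoma, lesion-free, hyperplastic only, and a
    multi-adenoma carrier with a proximal advanced adenoma."""
    return Cohort(participants=[
        Participant("P1", Sex.MALE, 60, [lesion("sigmoid", "crc", 25)]),
        Participant("P2", Sex.MALE, 65, [
            lesion("ascending", "adenoma_tubular", 12),
            lesion("sigmoid", "adenoma_tubular", 5),
        ]),
        Participant("P3", Sex.FEMALE, 58, [lesion("rectum", "adenoma_villous", 6)]),
        Participant("P4", Sex.FEMALE, 70, []),
        Participant("P5", Sex.MALE, 57, [lesion("sigmoid", "hyperplastic", 3)]),
        Participant("P6", Sex.FEMALE, 62, [
            lesion("sigmoid", "adenoma_tubular", 4),
            lesion("rectum", "adenoma_tubular", 6),
            lesion("cecum", "adenoma_tubular", 15),
        ]),
    ], provenance="toy")
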