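"""Domain model for a screening-colonoscopy cohort.

A *lesion* is one colorectal finding (site, size, histology, dysplasia
grade); a *participant* carries zero or more lesions. Lesions are ranked
on the standard neoplasia hierarchy (colorectal cancer > advanced adenoma
> non-advanced adenoma > hyperplastic polyp > other polyp > none), where an
*advanced adenoma* (AA) is an adenoma with at least one of: size >= 10 mm,
(tubulo-)villous histology, or high-grade dysplasia. CRC or AA together
form *advanced neoplasia* (AN).
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Site",
    "Histology",
    "Sex",
    "NeoplasiaClass",
    "Lesion",
    "Participant",
    "Cohort",
    "CohortFormatError",
    "classify_lesion",
    "most_advanced_finding",
    "load_cohort",
    "write_cohort",
]


class Site(str, enum.Enum):
    """Anatomical segment, ordered anus -> cecum."""

    RECTUM = "rectum"
    SIGMOID = "sigmoid"
    DESCENDING = "descending"
    SPLENIC_FLEXURE = "splenic_flexure"
    TRANSVERSE = "transverse"
    HEPATIC_FLEXURE = "hepatic_flexure"
    ASCENDING = "ascending"
    CECUM = "cecum"


class Histology(str, enum.Enum):
    CRC = "crc"
    ADENOMA_VILLOUS = "adenoma_villous"
    ADENOMA_TUBULOVILLOUS = "adenoma_tubulovillous"
    ADENOMA_TUBULAR = "adenoma_tubular"
    HYPERPLASTIC = "hyperplastic"
    OTHER_POLYP = "other_polyp"

    @property
    def is_adenoma(self) -> bool:
        return self in _ADENOMAS


_ADENOMAS = {
    Histology.ADENOMA_VILLOUS,
    Histology.ADENOMA_TUBULOVILLOUS,
    Histology.ADENOMA_TUBULAR,
}

#: Adenoma histologies that are AA-defining on their own.
VILLOUS_HISTOLOGIES = {Histology.ADENOMA_VILLOUS, Histology.ADENOMA_TUBULOVILLOUS}


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class NeoplasiaClass(enum.IntEnum):
    """Most-advanced-finding hierarchy; larger value = more advanced."""

    NONE = 0
    OTHER_POLYP = 1
    HYPERPLASTIC_POLYP = 2
    NONADVANCED_ADENOMA = 3
    ADVANCED_ADENOMA = 4
    CRC = 5

    @property
    def is_neoplasm(self) -> bool:
        """Adenoma or carcinoma (hyperplastic/other polyps excluded)."""
        return self >= NeoplasiaClass.NONADVANCED_ADENOMA

    @property
    def is_advanced(self) -> bool:
        """Advanced neoplasia: CRC or advanced adenoma."""
        return self >= NeoplasiaClass.ADVANCED_ADENOMA


@dataclass(frozen=True)
class Lesion:
    """A single colorectal finding.

    size_mm is the greatest diameter in whole millimetres; ``None`` means
    not recorded. The >= 1 cm size criterion is evaluated as
    ``size_mm >= 10`` (integer millimetres, no unit mixing).
    """

    site: Site
    size_mm: Optional[int]
    histology: Histology
    high_grade_dysplasia: bool = False

    def __post_init__(self) -> None:
        if self.size_mm is not None and self.size_mm < 0:
            raise ValueError(f"negative lesion size: {self.size_mm}")

    @property
    def is_adenoma(self) -> bool:
        return self.histology.is_adenoma


def classify_lesion(lesion: Lesion) -> NeoplasiaClass:
    """Rank a lesion on the neoplasia hierarchy.

    An adenoma is advanced if size >= 10 mm, (tubulo-)villous, or
    high-grade dysplastic. An adenoma with missing size and no other
    advanced feature cannot be asserted advanced and is classified
    non-advanced (a warning is logged for audit).
    """
    if lesion.histology is Histology.CRC:
        return NeoplasiaClass.CRC
    if lesion.is_adenoma:
        if lesion.histology in VILLOUS_HISTOLOGIES or lesion.high_grade_dysplasia:
            return NeoplasiaClass.ADVANCED_ADENOMA
        if lesion.size_mm is None:
            logger.warning(
                "adenoma with missing size and no other advanced feature "
                "classified as non-advanced"
            )
            return NeoplasiaClass.NONADVANCED_ADENOMA
        if lesion.size_mm >= 10:
            return NeoplasiaClass.ADVANCED_ADENOMA
        return NeoplasiaClass.NONADVANCED_ADENOMA
    if lesion.histology is Histology.HYPERPLASTIC:
        return NeoplasiaClass.HYPERPLASTIC_POLYP
    return NeoplasiaClass.OTHER_POLYP


@dataclass
class Participant:
    id: str
    sex: Sex
    age_years: int
    lesions: list[Lesion] = field(default_factory=list)


def most_advanced_finding(participant: Participant) -> NeoplasiaClass:
    """Maximum lesion class; NONE for a participant without findings."""
    if not participant.lesions:
        return NeoplasiaClass.NONE
    return max(classify_lesion(l) for l in participant.lesions)


@dataclass
class Cohort:
    participants: list[Participant]
    provenance: str = ""
    exclusion_log: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.participants)

    def stratum(self, which: str) -> list[Participant]:
        """Participants in a stratum: 'men', 'women' or 'both'."""
        if which == "both":
            return self.participants
        sex = {"men": Sex.MALE, "women": Sex.FEMALE}[which]
        return [p for p in self.participants if p.sex == sex]


class CohortFormatError(ValueError):
    """Malformed cohort input (unknown token, duplicate id, bad header)."""


_SEX_TOKENS = {"M": Sex.MALE, "F": Sex.FEMALE}
_MISSING_SITE = "missing"

#: Optional per-participant boolean flags handled as upstream exclusions.
EXCLUSION_FLAG_COLUMNS = (
    "history_crc_ibd",
    "recent_colonoscopy",
    "inadequate_prep",
    "incomplete_colonoscopy",
)


def _parse_lesion_row(row: pd.Series, row_no: int) -> Optional[Lesion]:
    """Parse one lesion table row; None signals a missing-location lesion."""
    site_token = str(row["site"]).strip()
    if site_token in ("", "nan", _MISSING_SITE):
        return None
    try:
        site = Site(site_token)
    except ValueError:
        raise CohortFormatError(
            f"lesions row {row_no}: unknown site token {site_token!r}"
        ) from None
    hist_token = str(row["histology"]).strip()
    try:
        histology = Histology(hist_token)
    except ValueError:
        raise CohortFormatError(
            f"lesions row {row_no}: unknown histology token {hist_token!r}"
        ) from None
    raw_size = row["size_mm"]
    size_mm = None if pd.isna(raw_size) or str(raw_size).strip() == "" else int(raw_size)
    hgd = bool(int(row["hgd"]))
    return Lesion(site=site, size_mm=size_mm, histology=histology,
                  high_grade_dysplasia=hgd)


def load_cohort(
    participants_file: str | Path,
    lesions_file: str | Path,
    *,
    min_age: int = 55,
    max_age: int = 79,
    drop_missing_location: bool = True,
    provenance: str = "",
) -> Cohort:
    """Read and validate the participant and lesion CSV tables.

    Participants outside [min_age, max_age] are excluded, as are rows
    flagged by any of the optional upstream-exclusion columns
    (``history_crc_ibd``, ``recent_colonoscopy``, ``inadequate_prep``,
    ``incomplete_colonoscopy``). A participant with any missing-location
    lesion is dropped entirely when ``drop_missing_location`` (the analysis
    cannot place such a lesion relative to sigmoidoscope reach); with
    ``drop_missing_location=False`` only the lesion is discarded. All
    exclusions are tallied per rule in ``Cohort.exclusion_log``.
    """
    pdf = pd.read_csv(participants_file, dtype={"id": str})
    required = {"id", "sex", "age"}
    if not required.issubset(pdf.columns):
        raise CohortFormatError(
            f"participants file must have columns {sorted(required)}, "
            f"got {list(pdf.columns)}"
        )
    dupes = pdf["id"][pdf["id"].duplicated()]
    if len(dupes):
        raise CohortFormatError(f"duplicate participant id(s): {sorted(set(dupes))}")

    ldf = pd.read_csv(lesions_file, dtype={"participant_id": str})
    lesion_required = {"participant_id", "site", "size_mm", "histology", "hgd"}
    if len(ldf) and not lesion_required.issubset(ldf.columns):
        raise CohortFormatError(
            f"lesions file must have columns {sorted(lesion_required)}, "
            f"got {list(ldf.columns)}"
        )

    known_ids = set(pdf["id"])
    lesions_by_pid: dict[str, list[Optional[Lesion]]] = {}
    for i, row in enumerate(ldf.itertuples(index=False), start=2):
        row = pd.Series(row._asdict())
        pid = row["participant_id"]
        if pid not in known_ids:
            raise CohortFormatError(
                f"lesions row {i}: unknown participant_id {pid!r}"
            )
        lesions_by_pid.setdefault(pid, []).append(_parse_lesion_row(row, i))

    log: Counter = Counter()
    participants: list[Participant] = []
    for row in pdf.itertuples(index=False):
        sex_token = str(row.sex).strip()
        if sex_token not in _SEX_TOKENS:
            raise CohortFormatError(
                f"participant {row.id}: unknown sex token {sex_token!r}"
            )
        flagged = False
        for col in EXCLUSION_FLAG_COLUMNS:
            if hasattr(row, col) and bool(getattr(row, col)):
                log[col] += 1
                flagged = True
                break
        if flagged:
            continue
        age = int(row.age)
        if not (min_age <= age <= max_age):
            log["age"] += 1
            continue
        raw_lesions = lesions_by_pid.get(row.id, [])
        if any(l is None for l in raw_lesions):
            if drop_missing_location:
                log["missing_location"] += 1
                continue
            log["missing_location_lesion_only"] += sum(
                1 for l in raw_lesions if l is None
            )
            raw_lesions = [l for l in raw_lesions if l is not None]
        participants.append(
            Participant(id=row.id, sex=_SEX_TOKENS[sex_token], age_years=age,
                        lesions=[l for l in raw_lesions if l is not None])
        )
    return Cohort(participants=participants, provenance=provenance,
                  exclusion_log=log)


def write_cohort(cohort: Cohort, participants_file: str | Path,
                 lesions_file: str | Path) -> None:
    """Write a cohort back out in the two-CSV dialect read by load_cohort."""
    prows = [
        {"id": p.id, "sex": "M" if p.sex is Sex.MALE else "F", "age": p.age_years}
        for p in cohort.participants
    ]
    lrows = [
        {
            "participant_id": p.id,
            "site": l.site.value,
            "size_mm": "" if l.size_mm is None else l.size_mm,
            "histology": l.histology.value,
            "hgd": int(l.high_grade_dysplasia),
        }
        for p in cohort.participants
        for l in p.lesions
    ]
    pd.DataFrame(prows, columns=["id", "sex", "age"]).to_csv(
        participants_file, index=False
    )
    pd.DataFrame(
        lrows, columns=["participant_id", "site", "size_mm", "histology", "hgd"]
    ).to_csv(lesions_file, index=False)
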