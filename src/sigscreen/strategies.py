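"""Colonoscopy referral criteria applied to sigmoidoscopy findings.

Twelve built-in strategies: the referral rules of the four landmark FS
screening trials (UK, SCORE, NORCCAP, US/PLCO), seven further
recommended or conceivable rules defined over distal findings, and a
no-referral baseline. Each strategy is a predicate over the FS-visible
(distal) lesions plus age and sex (age/sex are used only by the PLCO
score). Proximal findings can never influence a referral decision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

from .cohort_model import (
    Histology,
    Lesion,
    NeoplasiaClass,
    Participant,
    Sex,
    Site,
    VILLOUS_HISTOLOGIES,
    classify_lesion,
)
from .reach import ReachAssumption, distal_lesions

__all__ = [
    "ReferralStrategy",
    "PlcoScore",
    "plco_score",
    "decide_referral",
    "builtin_strategies",
    "strategy_by_name",
    "expression_strategy",
    "NO_REFERRAL",
    "REFERENCE_STRATEGY_NAME",
]

Predicate = Callable[[Sequence[Lesion], int, Sex], bool]


@dataclass(frozen=True)
class ReferralStrategy:
    """A named referral rule over distal findings (plus demographics).

    auto_refers_any_distal_AN is False for rules that can leave a
    participant with a distal advanced neoplasm unreferred (in which case
    the advanced lesion is assumed removed during sigmoidoscopy itself).
    """

    name: str
    predicate: Predicate
    auto_refers_any_distal_AN: bool = True

    def __call__(self, distal: Sequence[Lesion], age_years: int, sex: Sex) -> bool:
        return self.predicate(distal, age_years, sex)


# --- helpers over the distal lesion list ------------------------------------

def _classes(lesions: Sequence[Lesion]) -> list[NeoplasiaClass]:
    return [classify_lesion(l) for l in lesions]


def _any_crc(lesions: Sequence[Lesion]) -> bool:
    return any(c is NeoplasiaClass.CRC for c in _classes(lesions))


def _n_adenomas(lesions: Sequence[Lesion]) -> int:
    return sum(1 for l in lesions if l.is_adenoma)


def _any_advanced_adenoma(lesions: Sequence[Lesion]) -> bool:
    return any(c is NeoplasiaClass.ADVANCED_ADENOMA for c in _classes(lesions))


def _any_villous_or_hgd(lesions: Sequence[Lesion]) -> bool:
    return any(
        l.is_adenoma
        and (l.histology in VILLOUS_HISTOLOGIES or l.high_grade_dysplasia)
        for l in lesions
    )


def _size_ge(lesion: Lesion, mm: int) -> bool:
    return lesion.size_mm is not None and lesion.size_mm >= mm


def _size_gt(lesion: Lesion, mm: int) -> bool:
    return lesion.size_mm is not None and lesion.size_mm > mm


def _n_hyperplastic_above_rectum(lesions: Sequence[Lesion]) -> int:
    return sum(
        1
        for l in lesions
        if l.histology is Histology.HYPERPLASTIC and l.site is not Site.RECTUM
    )


# --- trial criteria ---------------------------------------------------------

def _uk(distal: Sequence[Lesion], age: int, sex: Sex, *,
        large_polyp_strict: bool = False) -> bool:
    """UK trial: CRC, a polyp or adenoma >= 1 cm, (tubulo-)villous
    histology, HGD, >= 3 adenomas, or >= 20 hyperplastic polyps above the
    rectum. The trial's published size convention (>= 1 cm) is the
    default; ``large_polyp_strict`` switches to a strictly-greater read.
    """
    size_hit = _size_gt if large_polyp_strict else _size_ge
    return (
        _any_crc(distal)
        or any(size_hit(l, 10) for l in distal)
        or _any_villous_or_hgd(distal)
        or _n_adenomas(distal) >= 3
        or _n_hyperplastic_above_rectum(distal) >= 20
    )


def _score(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
    """SCORE trial: polyp(s) > 5 mm, (tubulo-)villous histology, HGD,
    >= 3 adenomas, or CRC."""
    return (
        _any_crc(distal)
        or any(_size_gt(l, 5) for l in distal)
        or _any_villous_or_hgd(distal)
        or _n_adenomas(distal) >= 3
    )


def _norccap(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
    """NORCCAP trial: CRC, any polyp >= 1 cm, or any adenoma."""
    return (
        _any_crc(distal)
        or any(_size_ge(l, 10) for l in distal)
        or _n_adenomas(distal) >= 1
    )


@dataclass(frozen=True)
class PlcoScore:
    """Additive PLCO referral score: age band + male sex + worst distal finding."""

    age_points: int
    sex_points: int
    finding_points: int

    @property
    def total(self) -> int:
        return self.age_points + self.sex_points + self.finding_points

    @property
    def refer(self) -> bool:
        return self.total >= 4


def plco_score(age_years: int, sex: Sex, distal: Sequence[Lesion]) -> PlcoScore:
    """Score the PLCO referral rule.

    Age points: 50-54: 0, 55-59: 1, 60-64: 2, 65-70: 3. The published
    bands stop at 70; older ages keep 3 points (monotone extension, the
    screening population here spans 55-79). Sex: male 1, female 0.
    Most advanced distal finding: no polyps 0; non-neoplastic polyp 1;
    tubular adenoma < 10 mm 2; advanced lesion (tubular adenoma >= 10 mm,
    villous histology, HGD, or CRC) 3.
    """
    if age_years < 50:
        raise ValueError(f"PLCO score undefined below age 50 (got {age_years})")
    if age_years < 55:
        age_points = 0
    elif age_years < 60:
        age_points = 1
    elif age_years < 65:
        age_points = 2
    else:
        age_points = 3
    sex_points = 1 if sex is Sex.MALE else 0

    finding_points = 0
    for lesion in distal:
        cls = classify_lesion(lesion)
        if cls.is_advanced:
            points = 3
        elif cls is NeoplasiaClass.NONADVANCED_ADENOMA:
            points = 2
        else:  # hyperplastic or other non-neoplastic polyp
            points = 1
        finding_points = max(finding_points, points)
    return PlcoScore(age_points, sex_points, finding_points)


def _plco(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
    return plco_score(age, sex, distal).refer


# --- further strategies (distal findings only) ------------------------------

def _two_neoplasms_one_an(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
    """At least two distal adenomas of which at least one advanced, or CRC."""
    return _any_crc(distal) or (
        _n_adenomas(distal) >= 2 and _any_advanced_adenoma(distal)
    )


def _two_neoplasms(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
    """At least two distal adenomas, or CRC."""
    return _any_crc(distal) or _n_adenomas(distal) >= 2


def _histology_an(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
    """(Tubulo-)villous adenoma, HGD, or CRC (size plays no role)."""
    return _any_crc(distal) or _any_villous_or_hgd(distal)


def _an_ge_1cm(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
    """Large (>= 1 cm) distal adenoma, or CRC (histology plays no role)."""
    return _any_crc(distal) or any(
        l.is_adenoma and _size_ge(l, 10) for l in distal
    )


def _any_an(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
    return _any_crc(distal) or _any_advanced_adenoma(distal)


def _any_neoplasm(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
    return _any_crc(distal) or _n_adenomas(distal) >= 1


def _any_neoplasm_or_hpp(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
    return (
        _any_crc(distal)
        or _n_adenomas(distal) >= 1
        or any(l.histology is Histology.HYPERPLASTIC for l in distal)
    )


NO_REFERRAL = ReferralStrategy(
    "No referral", lambda distal, age, sex: False, auto_refers_any_distal_AN=False
)

#: Reference strategy for incremental NCN (the most restrictive rule studied).
REFERENCE_STRATEGY_NAME = ">=2 neoplasms, >=1 AN"


def builtin_strategies(*, uk_large_polyp_strict: bool = False) -> list[ReferralStrategy]:
    """The 12 built-in strategies, in report row order.

    ``uk_large_polyp_strict`` reads the UK rule's large-polyp criterion as
    strictly > 10 mm instead of the default >= 10 mm.
    """
    uk = lambda d, a, s: _uk(d, a, s, large_polyp_strict=uk_large_polyp_strict)
    return [
        NO_REFERRAL,
        ReferralStrategy("UK FS screening trial", uk),
        ReferralStrategy("SCORE", _score),
        ReferralStrategy("NORCCAP", _norccap),
        ReferralStrategy("US (PLCO)", _plco, auto_refers_any_distal_AN=False),
        ReferralStrategy(REFERENCE_STRATEGY_NAME, _two_neoplasms_one_an,
                         auto_refers_any_distal_AN=False),
        ReferralStrategy(">=2 neoplasms", _two_neoplasms,
                         auto_refers_any_distal_AN=False),
        ReferralStrategy("Histology-defined AN", _histology_an,
                         auto_refers_any_distal_AN=False),
        ReferralStrategy("AN >= 1 cm", _an_ge_1cm,
                         auto_refers_any_distal_AN=False),
        ReferralStrategy("Any AN", _any_an),
        ReferralStrategy("Any neoplasm", _any_neoplasm),
        ReferralStrategy("Any neoplasm or HPP", _any_neoplasm_or_hpp),
    ]


def strategy_by_name(name: str,
                     strategies: Sequence[ReferralStrategy] | None = None
                     ) -> ReferralStrategy:
    pool = builtin_strategies() if strategies is None else strategies
    for s in pool:
        if s.name == name:
            return s
    raise KeyError(
        f"unknown strategy {name!r}; valid names: {[s.name for s in pool]}"
    )


def decide_referral(
    strategy: ReferralStrategy,
    participant: Participant,
    reach: ReachAssumption,
) -> bool:
    """Apply a strategy to the FS-visible findings of one participant."""
    distal = distal_lesions(participant, reach)
    return strategy(distal, participant.age_years, participant.sex)


# --- user-defined strategies ------------------------------------------------

_EXPRESSION_VARS = (
    "n_lesions", "n_adenomas", "n_neoplasms", "n_an", "n_aa", "n_crc",
    "n_hpp", "n_hpp_above_rectum", "max_size_mm", "any_villous", "any_hgd",
    "age", "male",
)


def expression_strategy(name: str, expression: str,
                        auto_refers_any_distal_AN: bool = False
                        ) -> ReferralStrategy:
    """Build a custom strategy from a boolean expression.

    The expression is evaluated with Python syntax over the variables
    ``n_lesions, n_adenomas, n_neoplasms, n_an, n_aa, n_crc, n_hpp,
    n_hpp_above_rectum, max_size_mm, any_villous, any_hgd, age, male``
    (counts taken over distal lesions; ``max_size_mm`` is 0 when no size
    is recorded). Example: ``"n_an >= 1 or (n_adenomas >= 3 and age >= 65)"``.
    """
    code = compile(expression, f"<strategy {name!r}>", "eval")
    for var in code.co_names:
        if var not in _EXPRESSION_VARS:
            raise ValueError(
                f"strategy {name!r}: unknown variable {var!r}; "
                f"allowed: {_EXPRESSION_VARS}"
            )

    def predicate(distal: Sequence[Lesion], age: int, sex: Sex) -> bool:
        classes = _classes(distal)
        env = {
            "n_lesions": len(distal),
            "n_adenomas": _n_adenomas(distal),
            "n_neoplasms": sum(1 for c in classes if c.is_neoplasm),
            "n_an": sum(1 for c in classes if c.is_advanced),
            "n_aa": sum(1 for c in classes if c is NeoplasiaClass.ADVANCED_ADENOMA),
            "n_crc": sum(1 for c in classes if c is NeoplasiaClass.CRC),
            "n_hpp": sum(1 for l in distal if l.histology is Histology.HYPERPLASTIC),
            "n_hpp_above_rectum": _n_hyperplastic_above_rectum(distal),
            "max_size_mm": max((l.size_mm or 0 for l in distal), default=0),
            "any_villous": any(l.histology in VILLOUS_HISTOLOGIES for l in distal),
            "any_hgd": any(l.high_grade_dysplasia for l in distal),
            "age": age,
            "male": sex is Sex.MALE,
        }
        return bool(eval(code, {"__builtins__": {}}, env))

    return ReferralStrategy(name, predicate, auto_refers_any_distal_AN)
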