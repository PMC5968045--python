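"""Seeded synthetic screening-colonoscopy cohorts.

The generator emulates the marginal structure published for the KolosSal
screening population: sex ratio, per-sex age-band distribution, per-sex
prevalence of the most advanced finding (CRC, advanced adenoma,
non-advanced adenoma, hyperplastic polyp, other polyp, none), the per-sex
share of CRC and advanced-adenoma carriers whose advanced lesions all lie
within sigmoidoscope reach, and the per-sex prevalence of proximal
advanced neoplasia. The joint distribution of distal findings and
proximal advanced neoplasia is not published; proximal-AN carriage is
modelled as conditionally independent of distal non-index findings given
sex and most-advanced class, with an odds-multiplier knob for sensitivity
studies. Lesion multiplicity, sizes within class, and site mixes within
the distal/proximal split are likewise unpublished; the defaults here are
invented stand-ins, documented as such.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cohort_model import (
    Cohort,
    Histology,
    Lesion,
    NeoplasiaClass,
    Participant,
    Sex,
    Site,
    classify_lesion,
    most_advanced_finding,
)
from .reach import ReachAssumption, is_distal

__all__ = ["CohortParams", "default_params", "generate", "calibration_report"]

_CLASS_ORDER = (
    NeoplasiaClass.CRC,
    NeoplasiaClass.ADVANCED_ADENOMA,
    NeoplasiaClass.NONADVANCED_ADENOMA,
    NeoplasiaClass.HYPERPLASTIC_POLYP,
    NeoplasiaClass.OTHER_POLYP,
    NeoplasiaClass.NONE,
)

_DISTAL_SITES = (Site.RECTUM, Site.SIGMOID, Site.DESCENDING)
_PROXIMAL_SITES = (Site.SPLENIC_FLEXURE, Site.TRANSVERSE, Site.HEPATIC_FLEXURE,
                   Site.ASCENDING, Site.CECUM)


@dataclass(frozen=True)
class CohortParams:
    """Calibration targets and shape parameters for cohort generation.

    Probabilities calibrated to published marginals are stored as exact
    count ratios (e.g. male CRC prevalence 140/7323 ~= 0.019) so that the
    per-sex class vectors sum to one exactly.
    """

    n_participants: int = 14947
    male_fraction: float = 0.490
    #: inclusive (low, high) age bands and per-sex band probabilities
    age_bands: tuple[tuple[int, int], ...] = (
        (55, 59), (60, 64), (65, 69), (70, 74), (75, 79)
    )
    age_band_probs: dict = field(default_factory=lambda: {
        Sex.MALE: (2680 / 7323, 1608 / 7323, 1527 / 7323,
                   1045 / 7323, 463 / 7323),
        Sex.FEMALE: (2992 / 7624, 1655 / 7624, 1522 / 7624,
                     1032 / 7624, 423 / 7624),
    })
    #: per-sex probability of the most advanced finding, in _CLASS_ORDER
    class_probs: dict = field(default_factory=lambda: {
        Sex.MALE: (140 / 7323, 985 / 7323, 1721 / 7323,
                   796 / 7323, 192 / 7323, 3489 / 7323),
        Sex.FEMALE: (73 / 7624, 554 / 7624, 1267 / 7624,
                     772 / 7624, 170 / 7624, 4788 / 7624),
    })
    #: per-class, per-sex probability that the index lesion(s) are distal;
    #: CRC and AA values are published, the remainder are stand-ins
    distal_fraction: dict = field(default_factory=lambda: {
        NeoplasiaClass.CRC: {Sex.MALE: 118 / 140, Sex.FEMALE: 51 / 73},
        NeoplasiaClass.ADVANCED_ADENOMA: {Sex.MALE: 646 / 971,
                                          Sex.FEMALE: 345 / 544},
        NeoplasiaClass.NONADVANCED_ADENOMA: {Sex.MALE: 0.70, Sex.FEMALE: 0.70},
        NeoplasiaClass.HYPERPLASTIC_POLYP: {Sex.MALE: 0.85, Sex.FEMALE: 0.85},
        NeoplasiaClass.OTHER_POLYP: {Sex.MALE: 0.70, Sex.FEMALE: 0.70},
    })
    #: per-sex target prevalence of proximal advanced neoplasia
    prox_an_carrier: dict = field(default_factory=lambda: {
        Sex.MALE: 359 / 7323, Sex.FEMALE: 222 / 7624,
    })
    #: odds multiplier on proximal-AA carriage among distal-CRC carriers
    #: (1.0 = the conditional-independence calibration)
    association_odds: float = 1.0
    #: mean number of synchronous lesser lesions (Poisson)
    extras_mean: float = 0.6
    extras_class_weights: dict = field(default_factory=lambda: {
        NeoplasiaClass.NONADVANCED_ADENOMA: 0.40,
        NeoplasiaClass.HYPERPLASTIC_POLYP: 0.40,
        NeoplasiaClass.OTHER_POLYP: 0.20,
    })
    #: rare many-hyperplastic-polyps phenotype (exercises the UK >=20 rule)
    hpp_many_prob: float = 0.03
    hpp_many_count: tuple[int, int] = (12, 25)
    distal_site_probs: tuple[float, float, float] = (0.35, 0.45, 0.20)
    proximal_site_probs: tuple[float, ...] = (0.05, 0.30, 0.05, 0.40, 0.20)

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError(
                f"n_participants must be positive, got {self.n_participants}"
            )
        for name, vec in (
            ("male_fraction", (self.male_fraction, 1 - self.male_fraction)),
            ("distal_site_probs", self.distal_site_probs),
            ("proximal_site_probs", self.proximal_site_probs),
        ):
            if any(not (0 <= p <= 1) for p in vec):
                raise ValueError(f"{name} outside [0, 1]")
        for sex in Sex:
            for label, vec in (("age_band_probs", self.age_band_probs[sex]),
                               ("class_probs", self.class_probs[sex])):
                if abs(sum(vec) - 1.0) > 1e-9:
                    raise ValueError(
                        f"{label}[{sex.value}] sums to {sum(vec)!r}, not 1"
                    )
        for cls, by_sex in self.distal_fraction.items():
            for sex, p in by_sex.items():
                if not (0 <= p <= 1):
                    raise ValueError(f"distal_fraction[{cls}][{sex}] = {p}")
        if not abs(sum(self.proximal_site_probs) - 1.0) < 1e-9:
            raise ValueError("proximal_site_probs must sum to 1")

    def mixed_case_prob(self, sex: Sex) -> float:
        """P(synchronous proximal AA | distal CRC as most advanced finding).

        Derived so that the overall proximal-AN carrier rate matches the
        per-sex target: carriers are CRC cases with a proximal cancer,
        AA cases with a proximal advanced adenoma, and distal-CRC cases
        with a synchronous proximal AA (this term). Clamped at 0 when the
        other two sources already meet the target; the association-odds
        knob rescales the resulting probability on the odds scale.
        """
        p_crc, p_aa = self.class_probs[sex][0], self.class_probs[sex][1]
        d_crc = self.distal_fraction[NeoplasiaClass.CRC][sex]
        d_aa = self.distal_fraction[NeoplasiaClass.ADVANCED_ADENOMA][sex]
        residual = (self.prox_an_carrier[sex]
                    - p_crc * (1 - d_crc)
                    - p_aa * (1 - d_aa))
        base = max(0.0, residual / (p_crc * d_crc)) if p_crc * d_crc > 0 else 0.0
        if base >= 1.0:
            raise ValueError("proximal-AN carrier target unreachable: "
                             f"derived mixed-case probability {base:.3f} >= 1")
        if self.association_odds == 1.0 or base == 0.0:
            return base
        odds = self.association_odds * base / (1 - base)
        return odds / (1 + odds)


def default_params() -> CohortParams:
    """Parameter set calibrated to the published cohort marginals."""
    return CohortParams()


def _sample_site(rng: np.random.Generator, distal: bool,
                 params: CohortParams) -> Site:
    if distal:
        idx = rng.choice(len(_DISTAL_SITES), p=params.distal_site_probs)
        return _DISTAL_SITES[idx]
    idx = rng.choice(len(_PROXIMAL_SITES), p=params.proximal_site_probs)
    return _PROXIMAL_SITES[idx]


def _make_crc(rng: np.random.Generator, distal: bool,
              params: CohortParams) -> Lesion:
    return Lesion(site=_sample_site(rng, distal, params),
                  size_mm=int(rng.integers(15, 61)),
                  histology=Histology.CRC)


def _make_aa(rng: np.random.Generator, distal: bool,
             params: CohortParams) -> Lesion:
    """An advanced adenoma: either large (>= 10 mm) or a small adenoma
    with villous histology and/or high-grade dysplasia."""
    site = _sample_site(rng, distal, params)
    if rng.random() < 0.55:
        hist = (Histology.ADENOMA_TUBULAR if rng.random() < 0.70
                else Histology.ADENOMA_TUBULOVILLOUS)
        return Lesion(site=site, size_mm=int(rng.integers(10, 31)),
                      histology=hist,
                      high_grade_dysplasia=bool(rng.random() < 0.15))
    u = rng.random()
    if u < 0.50:
        hist, hgd = Histology.ADENOMA_TUBULOVILLOUS, rng.random() < 0.15
    elif u < 0.70:
        hist, hgd = Histology.ADENOMA_VILLOUS, rng.random() < 0.15
    else:
        hist, hgd = Histology.ADENOMA_TUBULAR, True
    return Lesion(site=site, size_mm=int(rng.integers(3, 10)),
                  histology=hist, high_grade_dysplasia=bool(hgd))


def _make_lesser(rng: np.random.Generator, cls: NeoplasiaClass, distal: bool,
                 params: CohortParams) -> Lesion:
    site = _sample_site(rng, distal, params)
    if cls is NeoplasiaClass.NONADVANCED_ADENOMA:
        return Lesion(site=site, size_mm=int(rng.integers(2, 10)),
                      histology=Histology.ADENOMA_TUBULAR)
    if cls is NeoplasiaClass.HYPERPLASTIC_POLYP:
        return Lesion(site=site, size_mm=int(rng.integers(1, 9)),
                      histology=Histology.HYPERPLASTIC)
    return Lesion(site=site, size_mm=int(rng.integers(2, 13)),
                  histology=Histology.OTHER_POLYP)


#: classes a synchronous lesser lesion may take, per most-advanced class
_EXTRA_CLASSES = {
    NeoplasiaClass.CRC: (NeoplasiaClass.NONADVANCED_ADENOMA,
                         NeoplasiaClass.HYPERPLASTIC_POLYP,
                         NeoplasiaClass.OTHER_POLYP),
    NeoplasiaClass.ADVANCED_ADENOMA: (NeoplasiaClass.NONADVANCED_ADENOMA,
                                      NeoplasiaClass.HYPERPLASTIC_POLYP,
                                      NeoplasiaClass.OTHER_POLYP),
    NeoplasiaClass.NONADVANCED_ADENOMA: (NeoplasiaClass.NONADVANCED_ADENOMA,
                                         NeoplasiaClass.HYPERPLASTIC_POLYP,
                                         NeoplasiaClass.OTHER_POLYP),
    NeoplasiaClass.HYPERPLASTIC_POLYP: (NeoplasiaClass.HYPERPLASTIC_POLYP,
                                        NeoplasiaClass.OTHER_POLYP),
    NeoplasiaClass.OTHER_POLYP: (NeoplasiaClass.OTHER_POLYP,),
}


def _extras(rng: np.random.Generator, sex: Sex, index_cls: NeoplasiaClass,
            params: CohortParams) -> list[Lesion]:
    allowed = _EXTRA_CLASSES.get(index_cls, ())
    if not allowed:
        return []
    weights = np.array([params.extras_class_weights[c] for c in allowed])
    weights = weights / weights.sum()
    out = []
    for _ in range(rng.poisson(params.extras_mean)):
        cls = allowed[rng.choice(len(allowed), p=weights)]
        distal = rng.random() < params.distal_fraction[cls][sex]
        out.append(_make_lesser(rng, cls, distal, params))
    return out


def _participant_lesions(rng: np.random.Generator, sex: Sex,
                         cls: NeoplasiaClass, params: CohortParams
                         ) -> list[Lesion]:
    lesions: list[Lesion] = []
    if cls is NeoplasiaClass.NONE:
        return lesions
    if cls is NeoplasiaClass.CRC:
        distal = rng.random() < params.distal_fraction[cls][sex]
        lesions.append(_make_crc(rng, distal, params))
        if distal and rng.random() < params.mixed_case_prob(sex):
            lesions.append(_make_aa(rng, distal=False, params=params))
    elif cls is NeoplasiaClass.ADVANCED_ADENOMA:
        distal = rng.random() < params.distal_fraction[cls][sex]
        lesions.append(_make_aa(rng, distal, params))
    elif cls is NeoplasiaClass.HYPERPLASTIC_POLYP and (
            rng.random() < params.hpp_many_prob):
        lo, hi = params.hpp_many_count
        for _ in range(int(rng.integers(lo, hi + 1))):
            site = Site.SIGMOID if rng.random() < 0.7 else Site.DESCENDING
            lesions.append(Lesion(site=site, size_mm=int(rng.integers(1, 7)),
                                  histology=Histology.HYPERPLASTIC))
        return lesions
    else:
        distal = rng.random() < params.distal_fraction[cls][sex]
        lesions.append(_make_lesser(rng, cls, distal, params))
    lesions.extend(_extras(rng, sex, cls, params))
    return lesions


def generate(params: Optional[CohortParams] = None,
             seed: Optional[int] = None) -> Cohort:
    """Generate a seeded synthetic cohort.

    Each participant gets sex, an age drawn uniformly within a sampled
    age band, and a most-advanced-finding class; the index lesion is
    placed distal or proximal with the class- and sex-specific published
    fraction, distal-CRC carriers additionally carry a proximal advanced
    adenoma with the derived mixed-case probability, and synchronous
    lesser lesions are added from the multiplicity distribution. Fully
    reproducible for a given seed.
    """
    params = default_params() if params is None else params
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_participants
    bands = params.age_bands
    participants = []
    sexes = rng.random(n) < params.male_fraction
    for i in range(n):
        sex = Sex.MALE if sexes[i] else Sex.FEMALE
        band = bands[rng.choice(len(bands), p=params.age_band_probs[sex])]
        age = int(rng.integers(band[0], band[1] + 1))
        cls = _CLASS_ORDER[rng.choice(len(_CLASS_ORDER),
                                      p=params.class_probs[sex])]
        lesions = _participant_lesions(rng, sex, cls, params)
        participants.append(
            Participant(id=f"S{i:06d}", sex=sex, age_years=age, lesions=lesions)
        )
    return Cohort(participants=participants,
                  provenance=f"synthetic(seed={seed}, n={n})")


def calibration_report(cohort: Cohort, params: Optional[CohortParams] = None,
                       flag_se: float = 4.0) -> pd.DataFrame:
    """Realized vs. target marginals for a generated cohort.

    One row per calibrated marginal with the binomial standard error of
    the realized value and the deviation in SE units; deviations beyond
    ``flag_se`` standard errors are flagged.
    """
    params = default_params() if params is None else params
    reach = ReachAssumption.DESCENDING_VISUALIZED
    rows = []

    def add(target_name: str, target: float, hits: int, denom: int) -> None:
        realized = hits / denom if denom else float("nan")
        se = (math.sqrt(target * (1 - target) / denom) if denom else
              float("nan"))
        dev = (realized - target) / se if denom and se > 0 else float("nan")
        rows.append({
            "target": target_name, "expected": target, "realized": realized,
            "n": denom, "se": se, "deviation_se": dev,
            "flagged": bool(denom and se > 0 and abs(dev) > flag_se),
        })

    by_sex = {Sex.MALE: cohort.stratum("men"),
              Sex.FEMALE: cohort.stratum("women")}
    n = len(cohort)
    add("male_fraction", params.male_fraction, len(by_sex[Sex.MALE]), n)
    for sex, members in by_sex.items():
        tag = sex.value
        classes = [most_advanced_finding(p) for p in members]
        for cls, target in zip(_CLASS_ORDER, params.class_probs[sex]):
            add(f"{tag}_prevalence_{cls.name.lower()}", target,
                sum(1 for c in classes if c is cls), len(members))
        for cls in (NeoplasiaClass.CRC, NeoplasiaClass.ADVANCED_ADENOMA):
            carriers = [p for p, c in zip(members, classes) if c is cls]
            all_distal = sum(
                1 for p in carriers
                if all(is_distal(l.site, reach) for l in p.lesions
                       if classify_lesion(l) is cls)
            )
            add(f"{tag}_{cls.name.lower()}_all_distal",
                params.distal_fraction[cls][sex], all_distal, len(carriers))
        prox_an = sum(
            1 for p in members
            if any(classify_lesion(l).is_advanced
                   and not is_distal(l.site, reach) for l in p.lesions)
        )
        add(f"{tag}_proximal_an_carrier", params.prox_an_carrier[sex],
            prox_an, len(members))
    return pd.DataFrame(rows)
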