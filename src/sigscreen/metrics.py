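"""Outcome measures for FS-based screening strategies.

For each referral strategy and stratum (men, women, both) the evaluator
reports: number and rate of colonoscopy referrals; per-endpoint
sensitivity (CRC, advanced adenoma, any advanced neoplasia) with exact
95% Clopper-Pearson confidence intervals; the number of participants in
whom a proximal advanced neoplasm (AN) is detected; the number of
colonoscopies needed per proximal AN detected (NCN); the incremental NCN
relative to a reference strategy; and the negative predictive value
(probability that a non-referred participant harbours no proximal lesion
of the endpoint class).

Displayed percentages are rounded half-up to whole percent and ratios to
one decimal; internal values keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .cohort_model import Cohort, NeoplasiaClass, Participant, classify_lesion
from .reach import (
    DetectionMode,
    Endpoint,
    ENDPOINT_CLASSES,
    ReachAssumption,
    apply_screening,
    endpoint_status,
    is_distal,
)
from .strategies import (
    ReferralStrategy,
    REFERENCE_STRATEGY_NAME,
    builtin_strategies,
    decide_referral,
)

__all__ = [
    "BinomialEstimate",
    "StrategyOutcome",
    "MetricTable",
    "clopper_pearson",
    "sensitivity",
    "ncn",
    "incremental_ncn",
    "npv_from_flags",
    "adherence_adjusted_gain",
    "evaluate",
    "evaluate_counts",
    "round_half_up",
]

STRATA = ("men", "women", "both")
ENDPOINTS = (Endpoint.CRC, Endpoint.AA, Endpoint.ANY_AN)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (2.5 -> 3), as used in the printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BinomialEstimate:
    """A proportion with its exact binomial confidence interval."""

    numerator: float
    denominator: float
    proportion: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95

    @property
    def pct(self) -> float:
        """Proportion as whole percent, half-up."""
        return round_half_up(100.0 * self.proportion)

    @property
    def ci_pct(self) -> tuple[float, float]:
        return (round_half_up(100.0 * self.ci_low),
                round_half_up(100.0 * self.ci_high))

    def __str__(self) -> str:
        lo, hi = self.ci_pct
        return f"{self.pct:.0f}% ({lo:.0f}-{hi:.0f}%)"


def clopper_pearson(x: float, n: float, conf_level: float = 0.95
                    ) -> Optional[BinomialEstimate]:
    """Exact (beta-quantile) binomial confidence interval.

    Returns None for an empty denominator (propagated as missing). x and
    n may be non-integral expectations under partial adherence; the beta
    quantiles extend continuously.
    """
    if n <= 0:
        return None
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    alpha = 1.0 - conf_level
    lo = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return BinomialEstimate(x, n, x / n, lo, hi, conf_level)


def sensitivity(detected: float, total: float,
                conf_level: float = 0.95) -> Optional[BinomialEstimate]:
    """Share of endpoint carriers detected by FS itself or via referral."""
    if total < detected:
        raise ValueError(f"detected ({detected}) exceeds total ({total})")
    return clopper_pearson(detected, total, conf_level)


def ncn(n_referred: float, prox_an_detected: float) -> Optional[float]:
    """Colonoscopies per proximal AN detected; None when nothing is detected."""
    if prox_an_detected <= 0:
        return None
    return n_referred / prox_an_detected


def incremental_ncn(n_referred: float, prox_an_detected: float,
                    ref_referred: float, ref_detected: float) -> Optional[float]:
    """Additional colonoscopies per additional proximal AN detected,
    comparing a more extensive strategy to a more restrictive reference."""
    d_referred = n_referred - ref_referred
    d_detected = prox_an_detected - ref_detected
    if d_detected <= 0:
        return None
    return d_referred / d_detected


def npv_from_flags(referred: Sequence[bool], has_proximal: Sequence[bool],
                   conf_level: float = 0.95) -> Optional[BinomialEstimate]:
    """Negative predictive value from per-participant flags:
    P(no proximal endpoint lesion | not referred)."""
    if len(referred) != len(has_proximal):
        raise ValueError("flag vectors differ in length")
    not_ref = [h for r, h in zip(referred, has_proximal) if not r]
    if not not_ref:
        return None
    return clopper_pearson(sum(1 for h in not_ref if not h), len(not_ref),
                           conf_level)


def adherence_adjusted_gain(sens_no_referral: float, sens_full: float,
                            adherence: float) -> float:
    """Expected sensitivity gain (percentage points) over no referral when
    only a fraction of referred participants attend colonoscopy.

    The gain over no referral comes entirely from attended follow-up
    colonoscopies, so its expectation scales linearly with adherence.
    """
    if not (0.0 <= adherence <= 1.0):
        raise ValueError(f"adherence must be in [0, 1], got {adherence}")
    return adherence * (sens_full - sens_no_referral)


@dataclass
class StrategyOutcome:
    """One strategy x stratum cell of the results grid."""

    strategy: str
    stratum: str
    n: int
    n_referred: float
    prox_an_total: int
    prox_an_detected: float
    sens: dict[Endpoint, Optional[BinomialEstimate]]
    npv: dict[Endpoint, Optional[BinomialEstimate]]

    @property
    def referral_rate(self) -> float:
        return self.n_referred / self.n if self.n else float("nan")

    @property
    def ncn(self) -> Optional[float]:
        return ncn(self.n_referred, self.prox_an_detected)

    def delta_ncn(self, reference: "StrategyOutcome") -> Optional[float]:
        return incremental_ncn(self.n_referred, self.prox_an_detected,
                               reference.n_referred, reference.prox_an_detected)


@dataclass
class MetricTable:
    """Full strategy x stratum grid plus run metadata."""

    outcomes: list[StrategyOutcome]
    reference_strategy: str
    metadata: dict = field(default_factory=dict)

    def get(self, strategy: str, stratum: str) -> StrategyOutcome:
        for o in self.outcomes:
            if o.strategy == strategy and o.stratum == stratum:
                return o
        raise KeyError(f"no outcome for {strategy!r} / {stratum!r}")

    def strata(self) -> list[str]:
        seen = dict.fromkeys(o.stratum for o in self.outcomes)
        return list(seen)

    def to_tidy(self) -> pd.DataFrame:
        """One row per strategy x stratum x endpoint, full precision."""
        rows = []
        for o in self.outcomes:
            try:
                ref = self.get(self.reference_strategy, o.stratum)
            except KeyError:
                ref = None
            for ep in ENDPOINTS:
                est = o.sens.get(ep)
                npv = o.npv.get(ep)
                rows.append({
                    "strategy": o.strategy,
                    "stratum": o.stratum,
                    "endpoint": ep.value,
                    "stratum_n": o.n,
                    "n_referred": o.n_referred,
                    "referral_rate": o.referral_rate,
                    "prox_an_total": o.prox_an_total,
                    "prox_an_detected": o.prox_an_detected,
                    "ncn": o.ncn,
                    "delta_ncn": o.delta_ncn(ref) if ref is not None else None,
                    "endpoint_detected": None if est is None else est.numerator,
                    "endpoint_total": None if est is None else est.denominator,
                    "sensitivity": None if est is None else est.proportion,
                    "sens_ci_low": None if est is None else est.ci_low,
                    "sens_ci_high": None if est is None else est.ci_high,
                    "npv": None if npv is None else npv.proportion,
                })
        return pd.DataFrame(rows)


def _participant_flags(participant: Participant, reach: ReachAssumption,
                       strategy: ReferralStrategy, mode: DetectionMode
                       ) -> dict:
    """Deterministic per-participant quantities for one strategy.

    Returns endpoint carrier flags, detection flags with and without an
    attended follow-up colonoscopy, the referral flag, and proximal
    endpoint-carrier flags (for NPV).
    """
    referred = decide_referral(strategy, participant, reach)
    res_attend = apply_screening(participant, referred, reach, attends=True)
    res_no = apply_screening(participant, referred, reach, attends=False)
    flags = {"referred": referred}
    for ep in ENDPOINTS:
        has, det_a = endpoint_status(participant, res_attend, ep, mode)
        _, det_n = endpoint_status(participant, res_no, ep, mode)
        flags[ep] = (has, det_a, det_n)
    prox = {}
    for ep in ENDPOINTS:
        classes = ENDPOINT_CLASSES[ep]
        prox[ep] = any(
            classify_lesion(l) in classes and not is_distal(l.site, reach)
            for l in participant.lesions
        )
    flags["proximal"] = prox
    return flags


def _aggregate(stratum: str, participants: list[Participant],
               strategy: ReferralStrategy, reach: ReachAssumption,
               mode: DetectionMode, adherence: float,
               attends_draws: Optional[np.ndarray],
               conf_level: float) -> StrategyOutcome:
    """Aggregate one strategy over one stratum.

    With full adherence the counts are exact integers. With partial
    adherence, counts are either closed-form expectations
    (attends_draws is None) or means over seeded Monte-Carlo replicates
    of the per-participant attendance coin (attends_draws has shape
    (replicates, n_participants), aligned with ``participants``).
    """
    n = len(participants)
    n_referred = 0.0
    prox_an_total = 0
    prox_an_detected = 0.0
    ep_total = {ep: 0 for ep in ENDPOINTS}
    ep_detected = {ep: 0.0 for ep in ENDPOINTS}
    npv_flags = {ep: ([], []) for ep in ENDPOINTS}  # (referred, has proximal)

    for j, p in enumerate(participants):
        f = _participant_flags(p, reach, strategy, mode)
        referred = f["referred"]
        has_prox_an = f["proximal"][Endpoint.ANY_AN]
        if has_prox_an:
            prox_an_total += 1
        if referred:
            n_referred += 1
            if attends_draws is not None:
                attend_w = float(attends_draws[:, j].mean())
            else:
                attend_w = adherence
        else:
            attend_w = 0.0
        if has_prox_an and referred:
            prox_an_detected += attend_w
        for ep in ENDPOINTS:
            has, det_a, det_n = f[ep]
            if has:
                ep_total[ep] += 1
                if referred:
                    ep_detected[ep] += attend_w * det_a + (1 - attend_w) * det_n
                else:
                    ep_detected[ep] += float(det_n)
            npv_flags[ep][0].append(referred)
            npv_flags[ep][1].append(f["proximal"][ep])

    return StrategyOutcome(
        strategy=strategy.name,
        stratum=stratum,
        n=n,
        n_referred=n_referred,
        prox_an_total=prox_an_total,
        prox_an_detected=prox_an_detected,
        sens={ep: sensitivity(ep_detected[ep], ep_total[ep], conf_level)
              for ep in ENDPOINTS},
        npv={ep: npv_from_flags(*npv_flags[ep], conf_level)
             for ep in ENDPOINTS},
    )


def evaluate(
    cohort: Cohort,
    strategies: Sequence[ReferralStrategy] | None = None,
    *,
    reach: ReachAssumption | str = ReachAssumption.DESCENDING_VISUALIZED,
    mode: DetectionMode | str = DetectionMode.ALL_LESIONS,
    adherence: float = 1.0,
    adherence_method: str = "expectation",
    replicates: int = 200,
    seed: Optional[int] = None,
    reference_strategy: str = REFERENCE_STRATEGY_NAME,
    strata: Sequence[str] = STRATA,
    conf_level: float = 0.95,
) -> MetricTable:
    """Evaluate referral strategies on a cohort, sex-stratified.

    adherence is the probability that a referred participant attends the
    follow-up colonoscopy. With adherence < 1, ``adherence_method``
    selects either the closed-form expectation over the attendance coin
    ("expectation") or the mean over seeded Monte-Carlo replicates
    ("simulate", ``replicates`` draws of one coin per referred
    participant). Referral decisions themselves are deterministic.
    """
    reach = ReachAssumption(reach)
    mode = DetectionMode(mode)
    if strategies is None:
        strategies = builtin_strategies()
    if not (0.0 <= adherence <= 1.0):
        raise ValueError(f"adherence must be in [0, 1], got {adherence}")
    if adherence_method not in ("expectation", "simulate"):
        raise ValueError(f"unknown adherence_method {adherence_method!r}")

    outcomes: list[StrategyOutcome] = []
    rng = np.random.default_rng(seed)
    for stratum in strata:
        participants = cohort.stratum(stratum)
        if not participants:
            import warnings

            warnings.warn(f"stratum {stratum!r} is empty; omitted")
            continue
        draws = None
        if adherence < 1.0 and adherence_method == "simulate":
            draws = rng.random((replicates, len(participants))) < adherence
        for strategy in strategies:
            outcomes.append(
                _aggregate(stratum, participants, strategy, reach, mode,
                           adherence if adherence < 1.0 else 1.0,
                           draws, conf_level)
            )
    return MetricTable(
        outcomes=outcomes,
        reference_strategy=reference_strategy,
        metadata={
            "reach": reach.value,
            "detection_mode": mode.value,
            "adherence": adherence,
            "adherence_method": adherence_method if adherence < 1.0 else None,
            "replicates": replicates if adherence < 1.0 else None,
            "seed": seed,
            "provenance": cohort.provenance,
            "conf_level": conf_level,
        },
    )


#: Columns required in a pre-aggregated counts table.
COUNTS_COLUMNS = (
    "strategy", "stratum", "stratum_n", "n_referred",
    "prox_an_total", "prox_an_detected",
    "crc_detected", "crc_total", "aa_detected", "aa_total",
    "an_detected", "an_total",
)


def evaluate_counts(
    counts: pd.DataFrame,
    *,
    reference_strategy: str = REFERENCE_STRATEGY_NAME,
    conf_level: float = 0.95,
) -> MetricTable:
    """Compute the full metric grid from pre-aggregated counts.

    ``counts`` has one row per strategy x stratum with the columns in
    COUNTS_COLUMNS. This is the entry point for re-deriving every
    published ratio (sensitivity, CI, NCN, incremental NCN, NPV for the
    any-AN endpoint) without participant-level data. Counts assume full
    adherence, so the any-AN NPV follows from
    (not referred) - (proximal-AN carriers not detected).
    """
    missing = set(COUNTS_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"counts table lacks columns {sorted(missing)}")
    outcomes = []
    for row in counts.itertuples(index=False):
        sens = {
            Endpoint.CRC: sensitivity(row.crc_detected, row.crc_total, conf_level),
            Endpoint.AA: sensitivity(row.aa_detected, row.aa_total, conf_level),
            Endpoint.ANY_AN: sensitivity(row.an_detected, row.an_total, conf_level),
        }
        not_referred = row.stratum_n - row.n_referred
        prox_missed = row.prox_an_total - row.prox_an_detected
        npv_an = (clopper_pearson(not_referred - prox_missed, not_referred,
                                  conf_level)
                  if not_referred > 0 else None)
        outcomes.append(StrategyOutcome(
            strategy=row.strategy,
            stratum=row.stratum,
            n=int(row.stratum_n),
            n_referred=float(row.n_referred),
            prox_an_total=int(row.prox_an_total),
            prox_an_detected=float(row.prox_an_detected),
            sens=sens,
            npv={Endpoint.CRC: None, Endpoint.AA: None, Endpoint.ANY_AN: npv_an},
        ))
    return MetricTable(outcomes=outcomes, reference_strategy=reference_strategy,
                       metadata={"source": "counts"})
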