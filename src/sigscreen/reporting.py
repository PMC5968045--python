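"""Rendering and serialization of strategy-evaluation results.

Produces the two report layouts: a sensitivity table (strategy x
endpoint, whole-percent sensitivities with 95% CIs) and a burden table
(referrals, referral rate, proximal AN detected, NCN, incremental NCN),
per stratum with strategies sorted by the number of colonoscopies. Also
builds mixed-policy summaries where men and women follow different
referral rules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .metrics import ENDPOINTS, MetricTable, StrategyOutcome, ncn, round_half_up
from .reach import Endpoint

__all__ = [
    "fmt_ratio",
    "render_sensitivity_table",
    "render_burden_table",
    "mixed_policy_summary",
    "write_outputs",
    "config_hash",
]

MISSING = "NA"

_ENDPOINT_LABEL = {Endpoint.CRC: "CRC", Endpoint.AA: "AA",
                   Endpoint.ANY_AN: "Any AN"}


def fmt_ratio(x: Optional[float]) -> str:
    """One-decimal half-up ratio, or the missing token."""
    return MISSING if x is None else f"{round_half_up(x, 1):.1f}"


def _fmt_sens(est) -> str:
    if est is None:
        return MISSING
    lo, hi = est.ci_pct
    return f"{est.pct:3.0f} ({lo:.0f}-{hi:.0f})"


def _sorted_stratum(table: MetricTable, stratum: str) -> list[StrategyOutcome]:
    rows = [o for o in table.outcomes if o.stratum == stratum]
    return sorted(rows, key=lambda o: o.n_referred)


def render_sensitivity_table(table: MetricTable) -> str:
    """Fixed-width sensitivity report: strategy x endpoint with 95% CIs,
    strategies sorted by colonoscopy count within each stratum."""
    lines = []
    for stratum in table.strata():
        rows = _sorted_stratum(table, stratum)
        lines.append(f"== {stratum} ==")
        header = f"{'Referral criterion':<28}{'Colos':>7}"
        for ep in ENDPOINTS:
            lines_n = rows[0].sens.get(ep)
            total = "" if lines_n is None else f" (N={lines_n.denominator:.0f})"
            header += f"  {_ENDPOINT_LABEL[ep] + total:>18}"
        lines.append(header)
        for o in rows:
            line = f"{o.strategy:<28}{o.n_referred:>7.0f}"
            for ep in ENDPOINTS:
                line += f"  {_fmt_sens(o.sens.get(ep)):>18}"
            lines.append(line)
        lines.append("")
    return "\n".join(lines)


def render_burden_table(table: MetricTable) -> str:
    """Fixed-width burden report: referrals, %, proximal AN detected, NCN
    and incremental NCN vs. the reference strategy."""
    lines = []
    for stratum in table.strata():
        rows = _sorted_stratum(table, stratum)
        try:
            ref = table.get(table.reference_strategy, stratum)
        except KeyError:
            ref = None
        n = rows[0].n if rows else 0
        prox = rows[0].prox_an_total if rows else 0
        lines.append(f"== {stratum} (N={n}, incl. {prox} with prox. AN) ==")
        lines.append(
            f"{'Referral criterion':<28}{'Colos':>7}{'%':>5}"
            f"{'ProxAN':>8}{'%':>5}{'NCN':>7}{'dNCN':>7}"
        )
        for o in rows:
            pct_ref = round_half_up(100 * o.referral_rate)
            pct_det = (round_half_up(100 * o.prox_an_detected / o.prox_an_total)
                       if o.prox_an_total else None)
            dncn = None
            if ref is not None and o.strategy != ref.strategy:
                dncn = o.delta_ncn(ref)
            dncn_s = ("Ref." if ref is not None and o.strategy == ref.strategy
                      else fmt_ratio(dncn))
            lines.append(
                f"{o.strategy:<28}{o.n_referred:>7.0f}{pct_ref:>5.0f}"
                f"{o.prox_an_detected:>8.0f}"
                f"{(MISSING if pct_det is None else f'{pct_det:.0f}'):>5}"
                f"{fmt_ratio(o.ncn):>7}{dncn_s:>7}"
            )
        lines.append("")
    return "\n".join(lines)


@dataclass(frozen=True)
class MixedPolicySummary:
    """Sex-specific policy pair: men and women follow different rules."""

    men_strategy: str
    women_strategy: str
    colonoscopies: float
    prox_an_detected: float
    ncn_men: Optional[float]
    ncn_women: Optional[float]
    ncn_combined: Optional[float]

    def render(self) -> str:
        return (
            f"men: {self.men_strategy} / women: {self.women_strategy}\n"
            f"  colonoscopies        {self.colonoscopies:.0f}\n"
            f"  proximal AN detected {self.prox_an_detected:.0f}\n"
            f"  NCN men/women        {fmt_ratio(self.ncn_men)}"
            f"/{fmt_ratio(self.ncn_women)}\n"
            f"  NCN combined         {fmt_ratio(self.ncn_combined)}"
        )


def mixed_policy_summary(table: MetricTable, men_strategy: str,
                         women_strategy: str) -> MixedPolicySummary:
    """Combine the men's outcome under one strategy with the women's
    under another into a single screening policy."""
    men = table.get(men_strategy, "men")
    women = table.get(women_strategy, "women")
    colos = men.n_referred + women.n_referred
    detected = men.prox_an_detected + women.prox_an_detected
    return MixedPolicySummary(
        men_strategy=men_strategy,
        women_strategy=women_strategy,
        colonoscopies=colos,
        prox_an_detected=detected,
        ncn_men=men.ncn,
        ncn_women=women.ncn,
        ncn_combined=ncn(colos, detected),
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_outputs(table: MetricTable, outdir: str | Path,
                  config: Optional[dict] = None) -> dict[str, Path]:
    """Write tidy CSV, both rendered tables, and run-metadata JSON.

    Every file is annotated with the configuration hash so that reruns
    are verifiably identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dict(table.metadata)
    if config is not None:
        meta["config_hash"] = config_hash(config)
    paths = {
        "tidy": outdir / "metrics.csv",
        "sensitivity": outdir / "sensitivity_table.txt",
        "burden": outdir / "burden_table.txt",
        "metadata": outdir / "run_metadata.json",
    }
    tidy = table.to_tidy()
    tidy.to_csv(paths["tidy"], index=False, na_rep=MISSING)
    stamp = f"# config_hash={meta.get('config_hash', 'none')}\n"
    paths["sensitivity"].write_text(stamp + render_sensitivity_table(table))
    paths["burden"].write_text(stamp + render_burden_table(table))
    paths["metadata"].write_text(json.dumps(meta, indent=2, default=str))
    return paths
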