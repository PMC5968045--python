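"""Outcome measures: exact binomial CIs, NCN, NPV, adherence, evaluation."""

import math

import numpy as np
import pytest

from sigscreen import (
    DetectionMode,
    Endpoint,
    ReachAssumption,
    adherence_adjusted_gain,
    builtin_strategies,
    clopper_pearson,
    decide_referral,
    evaluate,
    evaluate_counts,
    incremental_ncn,
    ncn,
    npv_from_flags,
    round_half_up,
    sensitivity,
)
from sigscreen.published import reference_counts
from sigscreen.synthetic import CohortParams, generate

DESC = ReachAssumption.DESCENDING_VISUALIZED


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (2.5, 0, 3.0),      # half-up, not banker's
        (66.529, 0, 67.0),
        (8.164, 1, 8.2),
        (11.758, 1, 11.8),
        (0.15, 1, 0.2),
        (-2.5, 0, -3.0),    # halves round away from zero
    ])
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected


class TestClopperPearson:
    def test_moderate_proportion(self):
        est = clopper_pearson(118, 140)
        assert est.pct == 84.0
        assert est.ci_pct == (77.0, 90.0)

    def test_zero_numerator_boundary(self):
        est = clopper_pearson(0, 10)
        assert est.ci_low == 0.0 and est.proportion == 0.0

    def test_full_numerator_closed_form(self):
        # x = n: lower bound is (alpha/2)^(1/n), upper bound 1
        est = clopper_pearson(10, 10)
        assert est.ci_high == 1.0
        assert est.ci_low == pytest.approx(0.025 ** (1 / 10), abs=1e-12)

    def test_empty_denominator_is_missing(self):
        assert clopper_pearson(0, 0) is None

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)

    @pytest.mark.parametrize("x,n", [(0, 7), (3, 7), (7, 7), (50, 200)])
    def test_matches_statsmodels_beta_interval(self, x, n):
        """Independent cross-check against statsmodels' exact interval."""
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
        est = clopper_pearson(x, n)
        assert est.ci_low == pytest.approx(0.0 if x == 0 else lo, abs=1e-10)
        assert est.ci_high == pytest.approx(1.0 if x == n else hi, abs=1e-10)

    def test_interval_brackets_the_proportion(self):
        for x, n in [(1, 30), (15, 30), (29, 30), (400, 1000)]:
            est = clopper_pearson(x, n)
            assert est.ci_low <= est.proportion <= est.ci_high
            assert 0.0 <= est.ci_low and est.ci_high <= 1.0


class TestSensitivity:
    @pytest.mark.parametrize("det,total,pct", [
        (646, 971, 67.0),
        (51, 73, 70.0),
        (0, 5, 0.0),
    ])
    def test_whole_percent(self, det, total, pct):
        assert sensitivity(det, total).pct == pct

    def test_ci_for_women_crc(self):
        assert sensitivity(51, 73).ci_pct == (58.0, 80.0)

    def test_detected_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            sensitivity(6, 5)


class TestNcn:
    def test_reference_strategy_value(self):
        assert round_half_up(ncn(547, 67), 1) == 8.2

    def test_extensive_strategy_value(self):
        assert round_half_up(ncn(1874, 74), 1) == 25.3

    def test_undefined_when_nothing_detected(self):
        assert ncn(0, 0) is None

    def test_incremental_examples(self):
        assert round_half_up(incremental_ncn(1276, 129, 547, 67), 1) == 11.8
        assert round_half_up(incremental_ncn(3127, 212, 547, 67), 1) == 17.8

    def test_incremental_undefined_for_zero_gain(self):
        assert incremental_ncn(547, 67, 547, 67) is None


class TestNpv:
    def test_direct_count(self):
        referred = [False] * 10 + [True] * 3
        prox = [True] + [False] * 12
        est = npv_from_flags(referred, prox)
        assert est.proportion == pytest.approx(0.9)

    def test_all_lesion_free(self):
        est = npv_from_flags([False] * 20, [False] * 20)
        assert est.proportion == 1.0

    def test_everyone_referred_is_missing(self):
        assert npv_from_flags([True] * 5, [False] * 5) is None


class TestAdherenceGain:
    def test_partial_adherence_scales_the_gain(self):
        assert adherence_adjusted_gain(68, 92, 0.75) == pytest.approx(18.0)

    def test_no_gain_when_sensitivities_equal(self):
        assert adherence_adjusted_gain(70, 70, 0.5) == 0.0

    def test_identity_at_full_adherence(self):
        assert adherence_adjusted_gain(60, 80, 1.0) == pytest.approx(20.0)

    def test_adherence_bounds(self):
        with pytest.raises(ValueError):
            adherence_adjusted_gain(60, 80, 1.2)


class TestEvaluateToyCohort:
    """Hand-computed grid for the six-participant fixture."""

    def test_any_an_strategy(self, toy_cohort):
        table = evaluate(toy_cohort)
        men = table.get("Any AN", "men")
        # P1 (distal cancer) is the only referred man
        assert men.n_referred == 1 and men.n == 3
        assert men.sens[Endpoint.CRC].proportion == 1.0        # P1 found
        assert men.sens[Endpoint.AA].proportion == 0.0         # P2 missed
        assert men.sens[Endpoint.ANY_AN].proportion == 0.5
        assert men.prox_an_total == 1 and men.prox_an_detected == 0
        assert men.ncn is None
        # NPV for any-AN among unreferred men: P2 carries proximal AN
        assert men.npv[Endpoint.ANY_AN].proportion == pytest.approx(0.5)
        women = table.get("Any AN", "women")
        assert women.n_referred == 1
        assert women.sens[Endpoint.AA].proportion == pytest.approx(0.5)
        assert women.sens[Endpoint.CRC] is None  # no female cancer carriers

    def test_any_neoplasm_strategy_detects_proximal(self, toy_cohort):
        table = evaluate(toy_cohort)
        men = table.get("Any neoplasm", "men")
        assert men.n_referred == 2                  # P1, P2
        assert men.prox_an_detected == 1            # P2's proximal AA
        assert men.ncn == pytest.approx(2.0)
        assert men.sens[Endpoint.AA].proportion == 1.0
        women = table.get("Any neoplasm", "women")
        assert women.n_referred == 2                # P3, P6
        assert women.prox_an_detected == 1          # P6's cecal AA
        assert women.sens[Endpoint.AA].proportion == 1.0

    def test_no_referral_row(self, toy_cohort):
        table = evaluate(toy_cohort)
        for stratum in ("men", "women", "both"):
            o = table.get("No referral", stratum)
            assert o.n_referred == 0 and o.prox_an_detected == 0
            assert o.ncn is None

    def test_both_stratum_is_sum_of_sexes(self, toy_cohort):
        table = evaluate(toy_cohort)
        for s in builtin_strategies():
            men = table.get(s.name, "men")
            women = table.get(s.name, "women")
            both = table.get(s.name, "both")
            assert both.n_referred == men.n_referred + women.n_referred
            assert both.prox_an_detected == (men.prox_an_detected
                                             + women.prox_an_detected)
            for ep in Endpoint:
                m = men.sens[ep]; w = women.sens[ep]; b = both.sens[ep]
                num = (0 if m is None else m.numerator) + \
                      (0 if w is None else w.numerator)
                den = (0 if m is None else m.denominator) + \
                      (0 if w is None else w.denominator)
                assert (b.denominator if b else 0) == den
                assert (b.numerator if b else 0) == num


class TestAdherence:
    def test_expectation_interpolates_linearly(self, toy_cohort):
        full = evaluate(toy_cohort).get("Any neoplasm", "men")
        none = evaluate(toy_cohort, adherence=0.0).get("Any neoplasm", "men")
        part = evaluate(toy_cohort, adherence=0.75).get("Any neoplasm", "men")
        for ep in Endpoint:
            f = full.sens[ep].numerator
            z = none.sens[ep].numerator
            p = part.sens[ep].numerator
            assert p == pytest.approx(z + 0.75 * (f - z))
        assert part.prox_an_detected == pytest.approx(
            0.75 * full.prox_an_detected)
        # referral counts are unaffected by attendance
        assert part.n_referred == full.n_referred

    def test_monte_carlo_agrees_with_expectation(self):
        cohort = generate(CohortParams(n_participants=1500), seed=9)
        exp = evaluate(cohort, adherence=0.75, strata=("both",))
        sim = evaluate(cohort, adherence=0.75, adherence_method="simulate",
                       replicates=300, seed=42, strata=("both",))
        for name in ("Any AN", "Any neoplasm"):
            e = exp.get(name, "both")
            s = sim.get(name, "both")
            assert s.prox_an_detected == pytest.approx(
                e.prox_an_detected, rel=0.15)
            assert s.sens[Endpoint.ANY_AN].proportion == pytest.approx(
                e.sens[Endpoint.ANY_AN].proportion, abs=0.03)

    def test_simulated_runs_reproducible_under_seed(self):
        cohort = generate(CohortParams(n_participants=400), seed=2)
        a = evaluate(cohort, adherence=0.6, adherence_method="simulate",
                     replicates=50, seed=7, strata=("both",))
        b = evaluate(cohort, adherence=0.6, adherence_method="simulate",
                     replicates=50, seed=7, strata=("both",))
        for oa, ob in zip(a.outcomes, b.outcomes):
            assert oa.prox_an_detected == ob.prox_an_detected


class TestCountsMode:
    def test_counts_table_reproduces_published_sensitivities(self):
        table = evaluate_counts(reference_counts())
        nr = table.get("No referral", "men")
        assert str(nr.sens[Endpoint.CRC]) == "84% (77-90%)"
        plco = table.get("US (PLCO)", "both")
        assert plco.sens[Endpoint.ANY_AN].pct == 85.0

    def test_counts_table_npv(self):
        table = evaluate_counts(reference_counts())
        npv = table.get("No referral", "both").npv[Endpoint.ANY_AN]
        # (14947 - 581) / 14947: everyone unreferred, carriers undetected
        assert npv.proportion == pytest.approx((14947 - 581) / 14947)
        assert round_half_up(100 * npv.proportion, 1) == 96.1

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="lacks columns"):
            evaluate_counts(pd.DataFrame({"strategy": [], "stratum": []}))


def test_tidy_export_shape(toy_cohort):
    table = evaluate(toy_cohort)
    tidy = table.to_tidy()
    # 12 strategies x 3 strata x 3 endpoints
    assert len(tidy) == 12 * 3 * 3
    assert set(tidy["endpoint"]) == {"crc", "aa", "any_an"}
    cell = tidy[(tidy.strategy == "Any neoplasm") & (tidy.stratum == "men")
                & (tidy.endpoint == "aa")].iloc[0]
    assert cell["ncn"] == pytest.approx(2.0)
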