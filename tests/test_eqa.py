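import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sstats

from labqc import (
    EQARuleConfig,
    IndicatorName,
    acceptability,
    compare_proportions,
    indicator,
    multirule_analyze,
    percent_deviation,
)

from conftest import make_eqa_series
from oracles import brute_eqa_rules, fisher_two_sided, yates_chi2


class TestPercentDeviation:
    @pytest.mark.parametrize(
        "measured, group_mean, expected",
        [(5.0, 5.0, 0.0), (5.5, 5.0, 10.0), (4.5, 5.0, -10.0)],
    )
    def test_definition(self, measured, group_mean, expected):
        assert percent_deviation(measured, group_mean) == pytest.approx(expected)

    def test_zero_group_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_deviation(5.0, 0.0)


class TestAcceptability:
    @pytest.mark.parametrize(
        "pd_val, tea, expected",
        [(5.0, 10.0, "acceptable"), (-12.0, 10.0, "unacceptable"),
         (10.0, 10.0, "acceptable")],  # boundary is strict
    )
    def test_grading(self, pd_val, tea, expected):
        assert acceptability(pd_val, tea) == expected

    @given(pd_val=st.floats(0, 50), bump=st.floats(0, 50), tea=st.floats(0.1, 30))
    def test_monotone_in_deviation_magnitude(self, pd_val, bump, tea):
        """Growing |pd| can only move a result towards unacceptable."""
        if acceptability(pd_val, tea) == "unacceptable":
            assert acceptability(pd_val + bump, tea) == "unacceptable"


class TestMultirule:
    def test_one_sided_series_flags_potential_systematic(self):
        events = make_eqa_series([3, 2, 4, 1, 2], tea=8.0)
        analysis = multirule_analyze(events)
        rules = {v.rule_id for v in analysis.violations}
        assert "same_side" in rules
        assert "1_75pTEa" not in rules  # max |pd| = 4 < 0.75 * 8
        assert analysis.classification == "potential_systematic"

    def test_alternating_small_deviations_are_clean(self):
        events = make_eqa_series([1, -1, 1, -1, 1], tea=8.0)
        analysis = multirule_analyze(events)
        assert analysis.violations == ()
        assert analysis.classification == "no_flag"

    def test_75_percent_tea_threshold(self):
        events = make_eqa_series([1, -6.5, 1, -1, 1], tea=8.0)
        analysis = multirule_analyze(events)
        assert [(v.rule_id, v.indices) for v in analysis.violations] == [
            ("1_75pTEa", (1,))
        ]

    def test_unacceptable_event_rejected_unless_allowed(self):
        events = make_eqa_series([9, 1, -1, 1, -1], tea=8.0)
        with pytest.raises(ValueError, match="unacceptable"):
            multirule_analyze(events)
        analysis = multirule_analyze(events, EQARuleConfig(allow_unacceptable=True))
        assert ("1_TEa", (0,)) in [(v.rule_id, v.indices) for v in analysis.violations]

    def test_sdi_range_rule_flags_potential_random(self):
        # pd of +-3% with group CV 2% gives SDI +-1.5 -> range 3; widen one
        events = make_eqa_series([4.5, -4.5, 1, -1, 1], tea=8.0, group_sd=0.1)
        analysis = multirule_analyze(events)
        assert analysis.sdi[0] == pytest.approx(2.25)
        assert "R_range" in {v.rule_id for v in analysis.violations}
        assert "random" in analysis.classification or analysis.classification == "both"

    def test_date_sorting_makes_analysis_permutation_covariant(self):
        pds = [3, 2, 4, 1, 2]
        events = make_eqa_series(pds, tea=8.0)
        rng = np.random.default_rng(0)
        shuffled = list(events)
        rng.shuffle(shuffled)
        a = multirule_analyze(events)
        b = multirule_analyze(shuffled)
        assert a.pd == b.pd
        assert [(v.rule_id, v.indices) for v in a.violations] == [
            (v.rule_id, v.indices) for v in b.violations
        ]

    def test_matches_brute_force_oracle_exhaustively(self):
        """Engine agrees with the independent checker on every sign pattern
        of length 5 crossed with deviation magnitudes {1, 6.5, 9}% at
        TEa = 8% (covers clean, warning-only and rejection regimes)."""
        config = EQARuleConfig(allow_unacceptable=True)
        for mags in itertools.product((1.0, 6.5, 9.0), repeat=5):
            for signs in itertools.product((1, -1), repeat=5):
                pds = [s * m for s, m in zip(signs, mags)]
                events = make_eqa_series(pds, tea=8.0, group_sd=0.25)
                analysis = multirule_analyze(events, config)
                engine = [(v.rule_id, v.indices) for v in analysis.violations]
                oracle = brute_eqa_rules(
                    list(analysis.pd), list(analysis.sdi), 8.0
                )
                assert engine == oracle, f"mismatch on pds={pds}"

    def test_same_side_null_rate_is_two_to_the_minus_four(self):
        """Null series of 5 symmetric deviations: all-one-side has
        probability 2 * (1/2)^5 = 6.25%."""
        rng = np.random.default_rng(31)
        reps = 2000
        hits = 0
        config = EQARuleConfig(enabled_rules=("same_side",))
        for _ in range(reps):
            pds = rng.normal(0, 2.0, size=5)
            events = make_eqa_series(list(pds), tea=8.0 * 10)  # huge TEa: all acceptable
            analysis = multirule_analyze(events, config)
            hits += bool(analysis.violations)
        p = 0.0625
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(hits / reps - p) < 3 * se


class TestIndicator:
    def test_implementation_rate(self):
        value = indicator(IndicatorName.IQC_IMPLEMENTATION_RATE, 97, 100, "2024")
        assert value.rate == pytest.approx(97.0)

    def test_zero_numerator_is_zero_percent(self):
        value = indicator("eqa_unacceptable_rate", 0, 340)
        assert value.rate == 0.0

    def test_zero_denominator_is_indeterminate(self):
        value = indicator("eqa_coverage_rate", 0, 0)
        assert value.rate is None

    def test_numerator_cannot_exceed_denominator(self):
        with pytest.raises(ValueError):
            indicator("eqa_coverage_rate", 5, 3)

    def test_accepts_collections(self):
        value = indicator("iqc_cv_failure_rate", ["a"], ["a", "b", "c", "d"])
        assert value.rate == pytest.approx(25.0)


class TestCompareProportions:
    def test_identical_proportions_give_p_one(self):
        res = compare_proportions(100, 50, 100, 50, method="chisq")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        oracle = fisher_two_sided(10, 1, 10, 9)
        assert oracle == pytest.approx(202 / 184756)  # frozen from the oracle
        res = compare_proportions(10, 1, 10, 9, method="fisher")
        assert res.p_value == pytest.approx(oracle, rel=1e-6)

    def test_yates_matches_hand_formula(self):
        stat = yates_chi2(30, 100, 60, 100)
        res = compare_proportions(100, 30, 100, 60, method="chisq_yates")
        assert res.statistic == pytest.approx(stat, rel=1e-9)
        assert res.p_value == pytest.approx(sstats.chi2.sf(stat, 1), rel=1e-9)

    def test_auto_picks_fisher_for_sparse_tables(self):
        assert compare_proportions(10, 1, 10, 0, method="auto").method == "fisher"
        assert compare_proportions(100, 30, 100, 60, method="auto").method == "chisq_yates"

    def test_zero_sample_size_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions(0, 0, 10, 1)
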