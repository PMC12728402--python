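import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sstats

from labqc import (
    LJStatistics,
    RuleConfig,
    Severity,
    SimConfig,
    cv_failure,
    evaluate_rules,
    fit_control_spec,
    lj_statistics,
    monthly_summary,
    simulate_network,
    zscores,
)
from labqc.simulate import AnalyteSim, Injection

from oracles import brute_westgard

Z_GRID = (-3.5, -2.5, -2.1, -1.0, 0.0, 1.0, 2.1, 2.5, 3.5)


class TestZScores:
    @pytest.mark.parametrize(
        "values, expected",
        [([5.0], [0.0]), ([5.3], [3.0]), ([4.8, 5.2], [-2.0, 2.0])],
    )
    def test_standardization(self, potassium_spec, values, expected):
        assert zscores(values, potassium_spec) == pytest.approx(expected)


class TestRuleEngine:
    def _fired(self, z, **kw):
        return [(v.rule_id, v.indices) for v in evaluate_rules(z, **kw)]

    def test_single_extreme_point_fires_1_3s(self):
        fired = self._fired([0.1, -0.5, 3.2])
        assert ("1_3s", (2,)) in fired
        assert all(rule != "2_2s" for rule, _ in fired)

    def test_consecutive_pair_beyond_2s_fires_2_2s_and_warnings(self):
        fired = self._fired([2.5, 2.5])
        assert ("2_2s", (0, 1)) in fired
        assert fired.count(("1_2s", (0,))) == 1 and fired.count(("1_2s", (1,))) == 1

    def test_opposite_pair_with_wide_span_fires_r_4s(self):
        assert ("R_4s", (0, 1)) in self._fired([2.5, -2.1])

    def test_point_exactly_on_limit_does_not_fire(self):
        assert self._fired([2.0, 2.0]) == []  # strict: 2.0 is not beyond 2s
        assert self._fired([3.0]) == [("1_2s", (0,))]  # beyond 2s, not 3s

    def test_four_consecutive_beyond_1s_and_ten_same_side(self):
        z = [1.5] * 4 + [0.5] * 6
        fired = self._fired(z)
        assert ("4_1s", (0, 1, 2, 3)) in fired
        assert ("10_x", tuple(range(10))) in fired

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown rule"):
            RuleConfig(enabled_rules=("1_3s", "7_7s"))

    def test_matches_brute_force_oracle_on_random_grid_series(self):
        """Spot equivalence with the independent checker on 2,000 random
        grid series (the exhaustive sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(42)
        for _ in range(2000):
            n = rng.integers(1, 7)
            z = [Z_GRID[i] for i in rng.integers(0, len(Z_GRID), n)]
            engine = [(v.rule_id, v.indices) for v in evaluate_rules(z)]
            assert engine == brute_westgard(z), f"mismatch on {z}"

    def test_false_rejection_rate_matches_normal_theory(self):
        """On N(0,1) data the per-point 1_3s rate is 2*Phi(-3) ~ 0.27%."""
        rng = np.random.default_rng(2024)
        z = rng.standard_normal(10_000)
        fired = evaluate_rules(z, RuleConfig(enabled_rules=("1_3s",)))
        rate = len(fired) / z.size
        p = 2 * sstats.norm.cdf(-3)
        se = np.sqrt(p * (1 - p) / z.size)
        assert abs(rate - p) < 3 * se

    def test_detection_power_is_monotone_in_shift_size(self):
        """P(any rejection) must not decrease as an injected shift grows."""
        rng = np.random.default_rng(7)
        reps, length = 1000, 20
        power = []
        for shift in (0, 1, 2, 3):
            hits = 0
            for _ in range(reps):
                z = rng.standard_normal(length) + shift
                if any(
                    v.severity is Severity.REJECTION for v in evaluate_rules(z)
                ):
                    hits += 1
            power.append(hits / reps)
        assert all(a <= b + 1e-12 for a, b in zip(power, power[1:]))
        assert power[-1] > 0.99  # a 3 SD shift is essentially always caught


class TestLJStatistics:
    def test_two_point_closed_form(self):
        stats = lj_statistics([4.9, 5.1])
        assert stats.mean == pytest.approx(5.0)
        assert stats.sd == pytest.approx(np.sqrt(0.02))
        assert stats.cv == pytest.approx(100 * np.sqrt(0.02) / 5.0)

    def test_constant_series_has_zero_sd(self):
        stats = lj_statistics([5, 5, 5, 5])
        assert stats.sd == 0.0 and stats.cv == 0.0

    def test_single_point_has_absent_sd_not_zero(self):
        stats = lj_statistics([5.0])
        assert stats.n == 1 and stats.mean == 5.0
        assert stats.sd is None and stats.cv is None

    def test_cv_recovers_generating_cv(self):
        rng = np.random.default_rng(123)
        values = rng.normal(100.0, 2.0, size=1000)
        stats = lj_statistics(values)
        se = 2.0 / np.sqrt(2 * 1000)  # asymptotic SE of the CV in percent
        assert abs(stats.cv - 2.0) < 3 * se

    def test_bias_versus_target(self, potassium_spec):
        stats = lj_statistics([5.1, 5.1], potassium_spec)
        assert stats.bias == pytest.approx(2.0)


class TestCvFailure:
    @pytest.mark.parametrize("cv, expected", [(3.1, True), (3.0, False), (2.0, False)])
    def test_strict_threshold(self, potassium_spec, cv, expected):
        stats = LJStatistics(n=10, mean=5.0, sd=cv / 20, cv=cv)
        assert cv_failure(stats, potassium_spec) is expected

    def test_absent_cv_is_indeterminate(self, potassium_spec):
        stats = LJStatistics(n=1, mean=5.0, sd=None, cv=None)
        assert cv_failure(stats, potassium_spec) is None


class TestMonthlySummary:
    def _network(self, injections=()):
        return simulate_network(
            SimConfig(
                seed=5,
                n_labs=1,
                days=60,
                points_per_day=1,
                analytes=(
                    AnalyteSim(name="potassium", true_means=(4.0,), true_cv=2.0),
                    AnalyteSim(name="urea", true_means=(5.0,), true_cv=2.0),
                ),
                injections=tuple(injections),
            )
        )

    def test_empty_month_yields_empty_summary(self):
        net = self._network()
        assert monthly_summary(net.observations, net.specs, "2030-01") == []

    def test_in_control_month_has_no_rejections(self):
        net = self._network()
        items = monthly_summary(net.observations, net.specs, "2024-01")
        assert [(i.analyte, i.level) for i in items] == [("potassium", 1), ("urea", 1)]
        assert not any(i.out_of_control for i in items)

    def test_injected_shift_flags_exactly_the_shifted_analyte(self):
        net = self._network(
            [Injection(lab=0, analyte="urea", level=1, mode="shift",
                       magnitude=2.0, start_day=0)]
        )
        items = monthly_summary(net.observations, net.specs, "2024-01")
        flagged = {i.analyte for i in items if i.out_of_control}
        assert flagged == {"urea"}


class TestFitControlSpec:
    def test_fits_limits_from_baseline(self):
        rng = np.random.default_rng(3)
        spec = fit_control_spec(
            rng.normal(5.0, 0.1, 50), analyte="potassium", level=1,
            lot_id="LOT-1", cv_requirement=3.0, tea=10.0, unit="mmol/L",
        )
        assert spec.target_mean == pytest.approx(5.0, abs=0.06)
        assert spec.target_sd == pytest.approx(0.1, rel=0.4)

    def test_requires_twenty_points(self):
        with pytest.raises(ValueError, match=">= 20"):
            fit_control_spec([5.0] * 10, analyte="a", level=1, lot_id="L",
                             cv_requirement=3, tea=10, unit="u")


@given(st.lists(st.sampled_from(Z_GRID), min_size=1, max_size=12))
def test_rule_engine_indices_always_within_bounds(z):
    for v in evaluate_rules(z):
        assert 0 <= v.indices[0] <= v.indices[-1] < len(z)
        assert list(v.indices) == sorted(set(v.indices))
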