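"""Retail marketing indicators, healthfulness ratios and smoothing."""

import numpy as np
import pandas as pd
import pytest

from gxecohort.retail import (
    build_exposures,
    compute_indicators,
    exponential_smooth,
    healthfulness_ratio,
)


def make_panel(obs):
    """obs: list of (fsa, quarter, week, store, cat, sku, price, servings,
    promoted, on_display, available)."""
    cols = ["fsa", "quarter", "week", "store", "category", "sku",
            "price", "servings", "promoted", "on_display", "available"]
    return pd.DataFrame(obs, columns=cols)


class TestIndicators:
    def test_variety_counts_distinct_available_skus(self):
        panel = make_panel([
            ("H3A", "2011Q1", 1, "s1", "vegetables", f"v{i}", 3.0, 4,
             False, False, True) for i in range(5)
        ])
        out = compute_indicators(panel, "H3A", "2011Q1")
        assert out["vegetables"]["variety"] == 5.0

    def test_discount_frequency_count_oracle(self):
        panel = make_panel([
            ("H3A", "2011Q1", 1, "s1", "soft_drinks", f"c{i}", 2.5, 6,
             i < 3, False, True) for i in range(12)
        ])
        out = compute_indicators(panel, "H3A", "2011Q1")
        assert out["soft_drinks"]["discount_frequency"] == pytest.approx(3 / 12)

    def test_regular_price_per_serving(self):
        panel = make_panel([
            ("H3A", "2011Q1", 1, "s1", "vegetables", "v1", 3.00, 6,
             False, False, True),
        ])
        out = compute_indicators(panel, "H3A", "2011Q1")
        assert out["vegetables"]["regular_price_per_serving"] == pytest.approx(0.50)

    def test_all_promoted_cell_has_undefined_price(self):
        panel = make_panel([
            ("H3A", "2011Q1", 1, "s1", "vegetables", "v1", 3.0, 4,
             True, False, True),
        ])
        out = compute_indicators(panel, "H3A", "2011Q1")
        assert np.isnan(out["vegetables"]["regular_price_per_serving"])

    def test_display_share_is_on_display_over_available(self):
        panel = make_panel([
            ("H3A", "2011Q1", 1, "s1", "vegetables", f"v{i}", 3.0, 4,
             False, i < 1, True) for i in range(4)
        ])
        out = compute_indicators(panel, "H3A", "2011Q1")
        assert out["vegetables"]["display_share"] == pytest.approx(0.25)

    def test_empty_cell_rejected(self):
        panel = make_panel([("H3A", "2011Q1", 1, "s1", "vegetables", "v1",
                             3.0, 4, False, False, True)])
        with pytest.raises(KeyError):
            compute_indicators(panel, "ZZZ", "2011Q1")


class TestHealthfulnessRatio:
    def test_veg_twice_soda_is_healthful_for_display(self):
        ratio, flag = healthfulness_ratio(2.0, 1.0, "display_share")
        assert ratio == pytest.approx(2.0) and flag == "healthful"

    def test_price_interpretation_is_inverted(self):
        ratio, flag = healthfulness_ratio(2.0, 1.0, "regular_price_per_serving")
        assert ratio == pytest.approx(2.0) and flag == "unhealthful"
        _, flag_low = healthfulness_ratio(0.5, 1.0, "regular_price_per_serving")
        assert flag_low == "healthful"

    def test_swap_maps_ratio_to_reciprocal(self, rng):
        for _ in range(10):
            a, b = rng.uniform(0.1, 5, size=2)
            r1, _ = healthfulness_ratio(a, b)
            r2, _ = healthfulness_ratio(b, a)
            assert r1 == pytest.approx(1 / r2)

    def test_zero_denominator_is_missing(self):
        ratio, flag = healthfulness_ratio(2.0, 0.0)
        assert np.isnan(ratio) and "denominator" in flag


class TestSmoothing:
    def test_constant_series_returns_the_constant(self):
        s = pd.Series([3.3] * 5, index=[f"2011Q{i}" for i in range(1, 5)] + ["2012Q1"])
        for decay in (0.1, 0.5, 0.9):
            assert exponential_smooth(s, decay) == pytest.approx(3.3)

    def test_single_quarter_returns_that_value(self):
        assert exponential_smooth(pd.Series({"2011Q1": 7.0}), 0.3) == 7.0

    def test_two_quarter_geometric_weight_oracle(self):
        s = pd.Series({"2011Q1": 1.0, "2011Q2": 4.0})
        # weights proportional to (0.5, 1) -> (x1 + 2*x2) / 3
        assert exponential_smooth(s, 0.5) == pytest.approx((1.0 + 2 * 4.0) / 3)

    def test_recent_quarters_weigh_more(self):
        s = pd.Series({"2011Q1": 0.0, "2011Q2": 0.0, "2011Q3": 1.0})
        assert exponential_smooth(s, 0.3) > 1 / 3

    def test_monotone_in_each_value(self):
        s = pd.Series({"2011Q1": 1.0, "2011Q2": 2.0, "2011Q3": 0.5})
        base = exponential_smooth(s, 0.3)
        for q in s.index:
            bumped = s.copy()
            bumped[q] += 1.0
            assert exponential_smooth(bumped, 0.3) > base

    def test_missing_quarters_skipped_all_missing_is_nan(self):
        s = pd.Series({"2011Q1": np.nan, "2011Q2": 5.0})
        assert exponential_smooth(s, 0.4) == 5.0
        assert np.isnan(exponential_smooth(pd.Series({"a": np.nan}), 0.4))

    @pytest.mark.parametrize("decay", [0.0, 1.0, -0.2])
    def test_invalid_decay_rejected(self, decay):
        with pytest.raises(ValueError):
            exponential_smooth(pd.Series({"a": 1.0}), decay)


class TestBuildExposures:
    def test_singleton_quarter_equals_direct_ratio(self, toy_panel):
        single = toy_panel[(toy_panel["fsa"] == "J4B")]
        exp = build_exposures(single, decay=0.3)
        cell = compute_indicators(single, "J4B", "2011Q1")
        want = cell["vegetables"]["discount_frequency"] / \
            cell["soft_drinks"]["discount_frequency"]
        assert exp.loc["J4B", "discount_ratio"] == pytest.approx(want)

    def test_row_order_invariance(self, toy_panel):
        a = build_exposures(toy_panel, decay=0.3)
        b = build_exposures(toy_panel.sample(frac=1, random_state=0), decay=0.3)
        pd.testing.assert_frame_equal(a, b)

    def test_multi_quarter_compositional_oracle(self, toy_panel):
        exp = build_exposures(toy_panel, decay=0.5)
        ratios = {}
        for q in ("2011Q1", "2011Q2"):
            cell = compute_indicators(toy_panel, "H3A", q)
            ratios[q] = (cell["vegetables"]["variety"]
                         / cell["soft_drinks"]["variety"])
        want = exponential_smooth(pd.Series(ratios), 0.5)
        assert exp.loc["H3A", "variety_ratio"] == pytest.approx(want)

    def test_price_scale_invariance(self, toy_panel):
        scaled = toy_panel.copy()
        scaled["price"] = scaled["price"] * 17.0
        a = build_exposures(toy_panel, decay=0.3)["price_ratio"]
        b = build_exposures(scaled, decay=0.3)["price_ratio"]
        pd.testing.assert_series_equal(a, b)

    def test_ratio_then_smooth_differs_from_smooth_then_ratio(self):
        # asymmetric toy: veg discount falls while soda discount rises
        rows = []
        for q, (veg_promo, soda_promo) in {
            "2011Q1": (4, 1), "2011Q2": (1, 4),
        }.items():
            for i in range(5):
                rows.append(("H3A", q, 1, "s1", "vegetables", f"v{i}", 3.0, 4,
                             i < veg_promo, False, True))
                rows.append(("H3A", q, 1, "s1", "soft_drinks", f"c{i}", 2.5, 6,
                             i < soda_promo, False, True))
        panel = make_panel(rows)
        exp = build_exposures(panel, decay=0.5)
        per_q = {q: compute_indicators(panel, "H3A", q) for q in ("2011Q1", "2011Q2")}
        ratio_then_smooth = exponential_smooth(pd.Series({
            q: c["vegetables"]["discount_frequency"]
            / c["soft_drinks"]["discount_frequency"] for q, c in per_q.items()
        }), 0.5)
        smooth_then_ratio = (
            exponential_smooth(pd.Series({
                q: c["vegetables"]["discount_frequency"] for q, c in per_q.items()
            }), 0.5)
            / exponential_smooth(pd.Series({
                q: c["soft_drinks"]["discount_frequency"] for q, c in per_q.items()
            }), 0.5)
        )
        assert exp.loc["H3A", "discount_ratio"] == pytest.approx(ratio_then_smooth)
        assert ratio_then_smooth != pytest.approx(smooth_then_ratio)

    def test_share_indicators_bounded(self, small_study):
        exp = small_study.retail
        from gxecohort.retail import compute_indicators as ci
        fsa = exp["fsa"].iloc[0]
        q = exp["quarter"].iloc[0]
        cell = ci(exp, fsa, q)
        for cat in cell:
            assert 0 <= cell[cat]["discount_frequency"] <= 1
            assert 0 <= cell[cat]["display_share"] <= 1
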