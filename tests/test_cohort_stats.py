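from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lymphmorph import cohort_stats as cs


class TestDichotomize:
    def test_simple_split(self):
        labels, median = cs.dichotomize_at_median([1, 2, 3, 4])
        assert median == 2.5
        assert labels.tolist() == [False, False, True, True]

    def test_all_equal_all_low(self):
        labels, _ = cs.dichotomize_at_median([7, 7, 7, 7])
        assert not labels.any()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            cs.dichotomize_at_median([1.0])

    @given(st.lists(st.floats(0.1, 1e6), min_size=5, max_size=60, unique=True))
    @settings(deadline=None, derandomize=True)
    def test_balanced_split_without_ties(self, values):
        labels, _ = cs.dichotomize_at_median(values)
        n_high, n_low = labels.sum(), (~labels).sum()
        assert abs(n_high - n_low) <= 1


class TestCompareGroups:
    def test_identical_groups(self):
        v = list(range(10)) * 2
        g = [0] * 10 + [1] * 10
        out = cs.compare_groups(v, g)
        assert out.p == pytest.approx(1.0, abs=0.05)
        assert out.direction == "none"

    def test_extreme_small_groups_exact_p(self):
        """Exact p for (1,2,3) vs (10,11,12), checked against full
        enumeration of all rank arrangements."""
        values = np.array([1, 2, 3, 10, 11, 12], float)
        out = cs.compare_groups(values, [0, 0, 0, 1, 1, 1])
        # oracle: enumerate all C(6,3) group assignments, two-sided
        ranks = values.argsort().argsort() + 1
        observed = ranks[3:].sum()
        stats = [sum(ranks[list(c)]) for c in combinations(range(6), 3)]
        mu = np.mean(stats)
        p_oracle = np.mean([abs(s - mu) >= abs(observed - mu) for s in stats])
        assert p_oracle == pytest.approx(0.1)
        assert out.p == pytest.approx(p_oracle)
        assert out.direction == "up"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cs.compare_groups([1, 2, 3], [0, 0, 0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        v = rng.lognormal(0, 1, 40)
        g = rng.integers(0, 2, 40).astype(bool)
        if g.all() or not g.any():
            g[0] = ~g[0]
        p0 = cs.compare_groups(v, g).p
        for f in (np.log, np.sqrt, lambda x: 3 * x + 7):
            assert cs.compare_groups(f(v), g).p == pytest.approx(p0)

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            v = rng.standard_normal(40)
            g = np.repeat([False, True], 20)
            if cs.compare_groups(v, g).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestCoefficientArithmetic:
    def test_exp_identity(self):
        assert cs.exp_coefficient(0.0) == 1.0

    def test_wald_zero(self):
        w, p = cs.wald_statistic(0.0, 1.0)
        assert w == 0.0 and p == 1.0

    def test_wald_recompute_from_rounded_inputs(self):
        w, p = cs.wald_statistic(-1.310, 0.647)
        assert w == pytest.approx(4.10, abs=0.01)
        assert p == pytest.approx(0.043, abs=0.002)

    def test_wald_requires_positive_se(self):
        with pytest.raises(ValueError):
            cs.wald_statistic(1.0, 0.0)


class TestRiskModel:
    def test_null_feature_eliminated(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"f": rng.integers(0, 2, 500)})
        y = rng.integers(0, 2, 500)
        model = cs.fit_risk_model(X, y)
        assert model.coefficients == []
        assert model.eliminated == ["f"]

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        n = 1000
        X = pd.DataFrame({f"f{i}": rng.integers(0, 2, n) for i in range(6)})
        logit = -0.4 + 1.5 * X.f1 - 1.5 * X.f4
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        model = cs.fit_risk_model(X, y)
        by_var = {c.variable: c for c in model.coefficients}
        assert "f1" in by_var and "f4" in by_var
        assert by_var["f1"].B == pytest.approx(1.5, abs=0.3)
        assert by_var["f4"].B == pytest.approx(-1.5, abs=0.3)

    def test_internal_consistency(self):
        rng = np.random.default_rng(3)
        n = 400
        X = pd.DataFrame({"a": rng.integers(0, 2, n), "b": rng.integers(0, 2, n)})
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.8 * X.a - 0.8 * X.b)))).astype(int)
        model = cs.fit_risk_model(X, y, stay_p=1.1)  # keep everything
        for c in model.coefficients:
            assert c.wald == pytest.approx((c.B / c.SE) ** 2)
            assert c.exp_b == pytest.approx(np.exp(c.B))

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"f": np.zeros(20)})
        with pytest.raises(ValueError):
            cs.fit_risk_model(X, np.r_[np.zeros(10), np.ones(10)])


class TestOddsProduct:
    # printed coefficient rows of the published logistic risk table
    MODEL = [
        cs.RiskCoefficient("small_cap_rel_sa", -2.173, 0.810, 7.197, 0.007, 0.114),
        cs.RiskCoefficient("intermediate_width", -1.706, 0.810, 4.435, 0.035, 0.182),
        cs.RiskCoefficient("intermediate_rel_sa", -1.778, 0.687, 6.700, 0.010, 5.916),
        cs.RiskCoefficient("intermediate_rel_density", 0.966, 0.537, 3.23, 0.072, 2.628),
        cs.RiskCoefficient("large_width", -1.644, 0.652, 6.349, 0.012, 0.193),
        cs.RiskCoefficient("large_roundness", -1.404, 0.508, 7.644, 0.006, 4.072),
        cs.RiskCoefficient("large_rel_density", -1.310, 0.647, 4.096, 0.043, 0.270),
        cs.RiskCoefficient("total_branching", -1.509, 0.646, 5.454, 0.020, 0.221),
    ]

    def test_all_low_is_unity(self):
        assert cs.risk_odds_product({}, self.MODEL) == 1.0

    def test_single_high_indicator(self):
        out = cs.risk_odds_product({"intermediate_rel_sa": "high"}, self.MODEL)
        assert out == pytest.approx(5.916)

    def test_two_high_indicators_multiply(self):
        out = cs.risk_odds_product(
            {"small_cap_rel_sa": "high", "total_branching": "high"}, self.MODEL
        )
        assert out == pytest.approx(0.114 * 0.221)
        assert out == pytest.approx(0.0252, abs=5e-4)

    def test_bad_indicator_value(self):
        with pytest.raises(ValueError):
            cs.risk_odds_product({"total_branching": "maybe"}, self.MODEL)


class TestHistograms:
    @pytest.mark.parametrize("n,expected", [(1, 2), (3, 3), (27, 6), (332, 14), (1000, 20)])
    def test_rice_rule(self, n, expected):
        assert cs.rice_bins(n) == expected

    def test_rice_requires_positive(self):
        with pytest.raises(ValueError):
            cs.rice_bins(0)

    def test_discard_zeros_changes_binning(self):
        spec = cs.normalized_histogram([0, 0, 1, 2, 3], discard_zeros=True)
        assert spec.n == 3
        assert spec.n_bins == 3
        assert spec.zeros_discarded

    def test_counts_normalized(self):
        rng = np.random.default_rng(0)
        spec = cs.normalized_histogram(rng.lognormal(0, 1, 500))
        assert spec.normalized_counts.sum() == pytest.approx(1.0)
        assert spec.n_bins == cs.rice_bins(500)

    def test_degenerate_single_value(self):
        spec = cs.normalized_histogram([4.0, 4.0, 4.0])
        assert spec.normalized_counts.sum() == pytest.approx(1.0)
        assert spec.normalized_counts.max() == pytest.approx(1.0)


class TestKurtosis:
    def test_standard_normal_is_normal(self):
        rng = np.random.default_rng(12)
        rep = cs.excess_kurtosis(rng.standard_normal(100_000))
        assert abs(rep.G2) < 0.05
        assert rep.verdict == "normal"

    def test_sek_at_cohort_size(self):
        rep = cs.excess_kurtosis(np.random.default_rng(0).standard_normal(207))
        assert rep.SEK == pytest.approx(0.34, abs=0.005)

    def test_laplace_is_leptokurtic(self):
        """Excess kurtosis of the Laplace distribution is exactly 3."""
        rng = np.random.default_rng(9)
        rep = cs.excess_kurtosis(rng.laplace(size=200_000))
        assert rep.G2 == pytest.approx(3.0, abs=0.15)
        assert rep.verdict == "leptokurtic"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cs.excess_kurtosis([2.0, 2.0, 2.0, 2.0])

    def test_verdict_thresholds(self):
        rng = np.random.default_rng(4)
        uniform = cs.excess_kurtosis(rng.uniform(size=50_000))
        assert uniform.verdict == "platykurtic"  # G2 of U(0,1) is -1.2
        assert uniform.Zg2 < -2
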