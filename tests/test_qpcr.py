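"""ΔCt normalisation, tissue promotion, Welch testing and fold changes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirpost.qpcr import (
    analyze_differential_expression,
    assign_target_tissues,
    bonferroni_alpha,
    correlate_platforms,
    delta_ct,
    fold_change,
    seq_fold_estimate,
    welch_test,
)


class TestDeltaCt:
    def test_geometric_mean_closed_form(self):
        target = pd.Series({"s1": 25.0})
        refs = pd.DataFrame({"s1": [20.0, 22.0]}, index=["r1", "r2"])
        # geometric mean of (20, 22) = sqrt(440) = 20.976...
        assert delta_ct(target, refs)["s1"] == pytest.approx(25.0 - math.sqrt(440))

    def test_single_reference_is_identity(self):
        target = pd.Series({"s1": 25.0})
        refs = pd.DataFrame({"s1": [20.0]}, index=["r1"])
        assert delta_ct(target, refs)["s1"] == pytest.approx(5.0)

    def test_equal_references(self):
        target = pd.Series({"s1": 25.0})
        refs = pd.DataFrame({"s1": [21.0, 21.0]}, index=["r1", "r2"])
        assert delta_ct(target, refs)["s1"] == pytest.approx(4.0)

    def test_missing_reference_drops_sample(self):
        target = pd.Series({"s1": 25.0, "s2": 26.0})
        refs = pd.DataFrame({"s1": [20.0, 22.0], "s2": [20.0, np.nan]}, index=["r1", "r2"])
        with pytest.warns(UserWarning, match="missing reference"):
            out = delta_ct(target, refs)
        assert list(out.index) == ["s1"]

    def test_matches_scipy_gmean(self, rng):
        samples = [f"s{i}" for i in range(6)]
        target = pd.Series(rng.uniform(20, 30, 6), index=samples)
        refs = pd.DataFrame(rng.uniform(18, 26, (3, 6)), columns=samples)
        expected = target - stats.gmean(refs, axis=0)
        assert np.allclose(delta_ct(target, refs), expected)

    def test_arithmetic_mode(self):
        target = pd.Series({"s1": 25.0})
        refs = pd.DataFrame({"s1": [20.0, 22.0]}, index=["r1", "r2"])
        assert delta_ct(target, refs, mode="arithmetic")["s1"] == pytest.approx(4.0)


class TestTargetPromotion:
    def dct(self, values_by_tissue, n=4):
        data, tissue = {}, {}
        for t, vals in values_by_tissue.items():
            for i, v in enumerate(vals):
                s = f"{t}_{i}"
                data[s] = v
                tissue[s] = t
        return pd.Series(data), tissue

    def test_clear_separation_no_promotion(self):
        dct, tm = self.dct({"liver": [4, 5, 6], "brain": [10, 11], "gills": [12, 14]})
        assert assign_target_tissues(dct, tm, {"liver"}) == {"liver"}

    def test_overlapping_tissue_promoted(self):
        dct, tm = self.dct({"liver": [4, 5, 6], "brain": [5, 5.5], "gills": [12, 14]})
        assert assign_target_tissues(dct, tm, {"liver"}) == {"liver", "brain"}

    def test_promotion_cascade_fixed_point(self):
        # brain overlaps liver; once brain is target its max pulls in skin
        dct, tm = self.dct(
            {"liver": [4.0, 5.0], "brain": [4.0, 4.5, 7.0], "skin": [6.5, 6.8], "gills": [12, 14]}
        )
        final = assign_target_tissues(dct, tm, {"liver"})
        # oracle: iterate the rule by hand to its fixed point
        expected = {"liver"}
        while True:
            thr = dct[[s for s in dct.index if tm[s] in expected]].max()
            add = {
                t
                for t in set(tm.values()) - expected
                if dct[[s for s in dct.index if tm[s] == t]].median() < thr
            }
            if not add:
                break
            expected |= add
        assert final == expected == {"liver", "brain", "skin"}

    def test_all_promoted_is_error(self):
        dct, tm = self.dct({"liver": [4, 8], "brain": [5, 5.5], "gills": [5, 6]})
        with pytest.raises(ValueError, match="no reference group"):
            assign_target_tissues(dct, tm, {"liver"})

    def test_empty_initial_target_is_error(self):
        dct, tm = self.dct({"liver": [4], "brain": [10]})
        with pytest.raises(ValueError):
            assign_target_tissues(dct, tm, set())


class TestWelch:
    def test_textbook_toy(self):
        t, df, p = welch_test([10.0, 10.5, 11.0], [15.0, 16.0, 17.0, 18.0])
        assert t == pytest.approx(-8.49, abs=0.01)
        assert df == pytest.approx(4.08, abs=0.01)

    def test_identical_groups(self):
        t, df, p = welch_test([5.0, 5.0, 5.0], [5.0, 5.0])
        assert t == 0.0 and p == 1.0

    def test_large_shift_tiny_p(self):
        a = [10.0, 10.01, 10.02, 9.99]
        b = [x + 50 for x in a]
        _, _, p = welch_test(a, b)
        assert p < 1e-6

    def test_agrees_with_scipy_reference(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = r.normal(0, r.uniform(0.5, 3), size=r.integers(3, 20))
            b = r.normal(r.uniform(-2, 2), r.uniform(0.5, 3), size=r.integers(3, 20))
            t, df, p = welch_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_too_small_group_is_error(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [2.0, 3.0])


class TestBonferroni:
    def test_study_battery(self):
        # 76 tests at alpha 0.05: threshold prints as 6.6E-04
        assert f"{bonferroni_alpha(0.05, 76):.1E}" == "6.6E-04"

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 10, 0.005)])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_zero_tests_is_error(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestFoldChange:
    def test_powers_of_two(self):
        ddct, fold = fold_change(5.0, 10.0)
        assert ddct == 5.0 and fold == 32.0

    def test_equal_means_fold_one(self):
        assert fold_change(7.0, 7.0) == (0.0, 1.0)

    def test_fractional(self):
        _, fold = fold_change(8.2, 10.7)
        assert fold == pytest.approx(2**2.5)

    @given(
        a=st.floats(-10, 10, allow_nan=False),
        b=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True)
    def test_antisymmetry(self, a, b):
        ddct, fold = fold_change(a, b)
        rddct, rfold = fold_change(b, a)
        assert ddct == -rddct
        assert fold * rfold == pytest.approx(1.0)


class TestSeqFoldAndCorrelation:
    def test_simple_ratio(self):
        nm = pd.DataFrame(
            [[50.0, 50.0, 5.0, 5.0]], index=["m1"], columns=["a", "b", "c", "d"]
        )
        tm = {"a": "liver", "b": "liver", "c": "brain", "d": "skin"}
        folds = seq_fold_estimate(nm, tm, {"m1": {"liver"}})
        assert folds["m1"] == pytest.approx(10.0)

    def test_zero_sample_excluded(self):
        nm = pd.DataFrame(
            [[50.0, 0.0, 5.0, 5.0]], index=["m1"], columns=["a", "b", "c", "d"]
        )
        tm = {"a": "liver", "b": "liver", "c": "brain", "d": "skin"}
        assert "m1" not in seq_fold_estimate(nm, tm, {"m1": {"liver"}})

    def test_proportional_folds_correlate_perfectly(self):
        q = pd.Series({f"m{i}": 2.0**i for i in range(5)})
        assert correlate_platforms(q, q * 3.7) == pytest.approx(1.0)

    def test_antiproportional_on_log_scale(self):
        q = pd.Series({f"m{i}": 2.0**i for i in range(5)})
        assert correlate_platforms(q, 1.0 / q) == pytest.approx(-1.0)

    def test_formula_oracle_on_fixed_table(self, rng):
        q = pd.Series(2.0 ** rng.uniform(0, 6, 10), index=[f"m{i}" for i in range(10)])
        s = pd.Series(2.0 ** rng.uniform(0, 6, 10), index=q.index)
        x, y = np.log2(q.to_numpy()), np.log2(s.to_numpy())
        # hand product-moment formula
        r = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert correlate_platforms(q, s) == pytest.approx(r, abs=1e-12)

    def test_constant_vector_reports_missing(self):
        q = pd.Series({"a": 2.0, "b": 2.0, "c": 2.0})
        s = pd.Series({"a": 1.0, "b": 2.0, "c": 4.0})
        assert math.isnan(correlate_platforms(q, s))

    def test_too_few_pairs_is_error(self):
        q = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            correlate_platforms(q, q)


class TestEndToEndCalls:
    def simulate_dct(self, rng, shift, n_target=8, n_ref=28, sigma=0.5):
        """ΔCt values with a planted expression shift in the target tissue."""
        target = rng.normal(10.0 - shift, sigma, n_target)
        ref = rng.normal(10.0, sigma, n_ref)
        samples = [f"t_{i}" for i in range(n_target)] + [f"r_{i}" for i in range(n_ref)]
        tissue = {f"t_{i}": "liver" for i in range(n_target)}
        # 7 reference tissues x 4 samples
        for i in range(n_ref):
            tissue[f"r_{i}"] = f"ref{i % 7}"
        return pd.Series(np.concatenate([target, ref]), index=samples), tissue

    def test_power_on_planted_shift(self):
        """Planted 5-cycle shifts are detected in ≥95% of replicates."""
        alpha, m = 0.05, 76
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            dct, tm = self.simulate_dct(rng, shift=5.0)
            res = analyze_differential_expression(
                dct, tm, {"liver"}, alpha=alpha, n_tests=m
            )
            hits += res.significant
        assert hits / 200 >= 0.95

    def test_type_one_error_on_nulls(self):
        """Null genes reach the Bonferroni threshold essentially never."""
        alpha, m = 0.05, 76
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            dct, tm = self.simulate_dct(rng, shift=0.0)
            res = analyze_differential_expression(
                dct, tm, {"liver"}, alpha=alpha, n_tests=m, promotion_rule="none"
            )
            hits += res.significant
        # expected rate alpha/m = 6.6e-4; allow the 5%*(alpha/0.05) bound
        assert hits / 200 <= 0.05 * (alpha / 0.05)

    def test_planted_fold_recovered(self):
        folds = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            dct, tm = self.simulate_dct(rng, shift=3.0)
            res = analyze_differential_expression(dct, tm, {"liver"}, n_tests=76)
            folds.append(res.fold)
        assert np.mean(folds) == pytest.approx(8.0, rel=0.15)

    def test_design_sample_counts(self, rng):
        dct, tm = self.simulate_dct(rng, shift=5.0)
        res = analyze_differential_expression(dct, tm, {"liver"}, n_tests=76)
        assert res.n_target == 8 and 20 <= res.n_reference <= 32
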