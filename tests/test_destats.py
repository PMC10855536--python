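from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ervamp.destats import (NbFitParams, bh_adjust, compare_groups,
                            fold_change, nb_wald_test, relative_fold_change,
                            size_factors, summarize_rfc)

from _oracles import brute_force_bh


class TestFoldChange:
    def test_ratio_of_medians(self):
        assert fold_change([2.0, 2.0, 2.0], [1.0, 1.0, 1.0]) == 2.0

    def test_identical_groups(self):
        assert fold_change([1.5, 2.5], [1.5, 2.5]) == 1.0

    def test_zero_case_median(self):
        assert fold_change([0, 0, 0], [0.5, 0.7, 0.9]) == 0.0

    def test_zero_control_median_is_inf(self):
        assert fold_change([1.0, 2.0], [0.0, 0.0]) == math.inf

    def test_both_zero(self):
        assert fold_change([0.0], [0.0]) == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fold_change([], [1.0])

    def test_swap_inverts(self, rng):
        a, b = rng.uniform(0.1, 5, 4), rng.uniform(0.1, 5, 4)
        assert fold_change(a, b) == pytest.approx(1 / fold_change(b, a))


class TestRelativeFoldChange:
    @pytest.mark.parametrize("x,expected", [
        (2.0, 1.0), (0.5, 1.0), (1.0, 0.0), (0.0, 0.0), (4.0, 3.0),
        (0.25, 3.0)])
    def test_piecewise(self, x, expected):
        assert relative_fold_change(x) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_fold_change(-0.1)

    @given(st.floats(min_value=1e-6, max_value=1e6,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_under_inversion(self, x):
        assert relative_fold_change(x) == pytest.approx(
            relative_fold_change(1.0 / x), rel=1e-9)


class TestSummarizeRfc:
    def _df(self, xs):
        return pd.DataFrame({"fold_change": xs,
                             "rfc": [relative_fold_change(x)
                                     if np.isfinite(x) else math.inf
                                     for x in xs]})

    def test_all_unchanged_centers_at_zero(self):
        s = summarize_rfc(self._df([1.0, 1.0, 1.0]))
        assert s["median_signed_rfc"] == 0.0

    def test_opposite_signs_same_magnitude(self):
        s = summarize_rfc(self._df([2.0, 0.5]))
        assert s["median_abs_rfc"] == 1.0
        assert s["median_signed_rfc"] == 0.0  # +1 and -1 average out

    def test_changed_only_drops_window(self):
        s = summarize_rfc(self._df([1.1, 0.9, 3.0, 0.25]),
                          subset="changed_only")
        assert s["n"] == 2
        assert s["median_abs_rfc"] == pytest.approx(2.5)  # {2, 3} -> 2.5

    def test_window_boundaries_are_kept(self):
        # exactly 0.8 / 1.2 are not strictly inside the window
        s = summarize_rfc(self._df([0.8, 1.2]), subset="changed_only")
        assert s["n"] == 2

    def test_infinite_excluded_and_counted(self):
        s = summarize_rfc(self._df([math.inf, 2.0]))
        assert s["n_infinite"] == 1 and s["n"] == 1


class TestSizeFactors:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_exact_doubling(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        sf = size_factors(counts)
        assert np.allclose(sf["b"] / sf["a"], 2.0)
        assert np.allclose(np.exp(np.log(sf).mean()), 1.0)

    def test_recovers_planted_depth_ratios(self, rng):
        truth = np.array([1.0, 2.0, 0.5, 1.5])
        mu = rng.uniform(50, 500, 300)
        m = mu[:, None] * truth[None, :]
        counts = pd.DataFrame(rng.poisson(m),
                              columns=["a", "b", "c", "d"])
        sf = size_factors(counts)
        expected = truth / np.exp(np.log(truth).mean())
        assert np.allclose(sf, expected, rtol=0.05)

    def test_fallback_on_all_zero_rows(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        sf = size_factors(counts, allow_fallback=True)
        assert np.allclose(sf, [1.0, 1.0])
        with pytest.raises(ValueError):
            size_factors(counts, allow_fallback=False)


class TestNbWaldTest:
    def _groups(self, n=4):
        return {f"s{i}": ("case" if i < n else "control")
                for i in range(2 * n)}

    def test_identical_groups_are_null(self):
        counts = pd.DataFrame(
            {f"s{i}": [10, 40, 100] for i in range(8)})
        res = nb_wald_test(counts, self._groups(), "case", "control")
        assert np.allclose(res["log2_fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_group_symmetric_counts_give_zero_stat(self, rng):
        block = rng.integers(5, 200, (6, 4))
        counts = pd.DataFrame(np.hstack([block, block]),
                              columns=[f"s{i}" for i in range(8)])
        res = nb_wald_test(counts, self._groups(), "case", "control")
        assert np.allclose(res["stat"], 0.0)

    def test_planted_effect_recovered_with_low_bias(self, rng):
        """log2FC estimates of a planted 4-fold effect are biased by less
        than 0.25 log2 units on average."""
        estimates = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            mu = np.full(60, 100.0)
            m = np.tile(mu[:, None], (1, 8))
            m[10, :4] *= 4.0
            shape = 1 / 0.05
            counts = pd.DataFrame(r.negative_binomial(shape, shape / (shape + m)),
                                  columns=[f"s{i}" for i in range(8)])
            res = nb_wald_test(counts, self._groups(), "case", "control")
            estimates.append(res["log2_fc"].iloc[10])
        assert abs(np.mean(estimates) - 2.0) < 0.25

    def test_zero_group_mean_uses_pseudocount(self):
        counts = pd.DataFrame(
            {f"s{i}": ([0, 50] if i < 4 else [40, 50]) for i in range(8)})
        res = nb_wald_test(counts, self._groups(), "case", "control")
        assert np.isfinite(res["log2_fc"]).all()
        assert res["log2_fc"].iloc[0] < 0

    def test_missing_group_rejected(self):
        counts = pd.DataFrame({"s0": [1], "s1": [2]})
        with pytest.raises(ValueError):
            nb_wald_test(counts, {"s0": "case", "s1": "case"},
                         "case", "control")


class TestBhAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.7]).tolist() == [0.7]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 50)
        assert (bh_adjust(p) >= p).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=20))
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_definition(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 1, 200)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), expected)


class TestCompareGroups:
    def test_table_contract(self, rng):
        counts = pd.DataFrame(rng.integers(1, 300, (5, 8)),
                              index=[f"L{i}" for i in range(5)],
                              columns=[f"s{i}" for i in range(8)])
        freqs = 100 * counts / counts.sum(axis=0)
        groups = {f"s{i}": ("case" if i < 4 else "control") for i in range(8)}
        out = compare_groups(counts, freqs, groups, "case", "control")
        assert list(out.index) == [f"L{i}" for i in range(5)]
        assert {"fold_change", "rfc", "log2_fc", "p", "p_adj"} <= set(out.columns)
        assert ((out["p_adj"] >= out["p"]) | out["p"].isna()).all()
        assert (out["rfc"] >= 0).all()
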