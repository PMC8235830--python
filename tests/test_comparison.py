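import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itscompare import (align_direction, bland_altman, categorize_p,
                        ci_width_comparison, concordance)
from itscompare.comparison import (ComparisonError, autocorrelation_summary,
                                   kappa_adjective, standardize_fit)

import pandas as pd


class TestStandardize:
    def test_divides_by_rmse(self, noisy_dataset, noisy_design):
        from itscompare import fit_ols
        fit = fit_ols(noisy_design, noisy_dataset.y)
        s = standardize_fit(fit, 2.0, noisy_design)
        i = noisy_design.roles["level_change"]
        assert s.level_change == pytest.approx(fit.beta[i] / 2.0)
        assert s.level_se == pytest.approx(fit.se[i] / 2.0)
        assert s.level_p == fit.p[i]  # p-values pass through untouched

    def test_zero_rmse_excluded(self, noisy_dataset, noisy_design):
        from itscompare import fit_ols
        fit = fit_ols(noisy_design, noisy_dataset.y)
        with pytest.raises(ComparisonError):
            standardize_fit(fit, 0.0, noisy_design)


class TestAlignDirection:
    @pytest.mark.parametrize("pair,anchor,expected", [
        ((-2.0, -3.0), "first", (2.0, 3.0)),
        ((2.0, -3.0), "first", (2.0, -3.0)),
        ((0.0, -3.0), "first", (0.0, -3.0)),  # zero anchor: unchanged
        ((2.0, -3.0), "second", (-2.0, 3.0)),
    ])
    def test_examples(self, pair, anchor, expected):
        assert align_direction(*pair, anchor=anchor) == expected

    @given(a=st.floats(-10, 10), b=st.floats(-10, 10))
    @settings(deadline=None, derandomize=True)
    def test_anchor_never_negative_after_alignment(self, a, b):
        out_a, _ = align_direction(a, b, "first")
        assert out_a >= 0 or a == 0


class TestBlandAltman:
    def test_unit_sd_differences(self):
        # differences -1, 0, 1 -> sd = 1 (n-1 divisor), limits +-1.96
        summ, _ = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert summ.mean_difference == pytest.approx(0.0)
        assert summ.loa_low == pytest.approx(-1.96)
        assert summ.loa_high == pytest.approx(1.96)

    def test_identical_vectors(self):
        summ, _ = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert summ.mean_difference == 0 and summ.loa_low == 0 == summ.loa_high

    def test_log_scale_geometric_ratio(self):
        summ, _ = bland_altman([2.0, 2.0, 2.0], [1.0, 1.0, 1.0], log_scale=True)
        assert summ.geometric_mean_ratio == pytest.approx(2.0)
        assert summ.gmr_loa_low == pytest.approx(2.0)
        assert summ.gmr_loa_high == pytest.approx(2.0)

    def test_nonpositive_pairs_dropped_under_log(self):
        summ, table = bland_altman([2.0, -1.0, 2.0], [1.0, 1.0, 1.0],
                                   log_scale=True)
        assert summ.n_pairs == 2 and len(table) == 2

    def test_limits_cover_nominal_share_of_gaussian_pairs(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 500)
        y = x + rng.normal(0, 0.5, 500)
        summ, table = bland_altman(x, y)
        inside = ((table["difference"] >= summ.loa_low)
                  & (table["difference"] <= summ.loa_high)).mean()
        assert inside >= 0.90


class TestCIWidth:
    def test_affine_map_example(self):
        cw = ci_width_comparison((2, 6), (3, 7), 4.0, 5.0)
        assert cw.scaled_other == pytest.approx((-0.25, 0.75))
        assert cw.width_ratio == pytest.approx(1.0)

    def test_identical_intervals(self):
        cw = ci_width_comparison((0, 1), (0, 1), 0.5, 0.5)
        assert cw.scaled_other == pytest.approx((-0.5, 0.5))
        assert cw.width_ratio == pytest.approx(1.0)
        assert not cw.other_wider

    def test_narrower_interval(self):
        cw = ci_width_comparison((0, 1), (0.25, 0.75), 0.5, 0.5)
        assert cw.scaled_other == pytest.approx((-0.25, 0.25))
        assert cw.width_ratio == pytest.approx(0.5)
        assert not cw.other_wider

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20),
           data=st.data())
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_invariant_under_common_affine_maps(self, shift, scale, data):
        lo_r = data.draw(st.floats(-5, 5))
        w_r = data.draw(st.floats(0.5, 5))
        lo_o = data.draw(st.floats(-5, 5))
        w_o = data.draw(st.floats(0.5, 5))
        ref, oth = (lo_r, lo_r + w_r), (lo_o, lo_o + w_o)
        pr, po = lo_r + w_r / 2, lo_o + w_o / 2
        base = ci_width_comparison(ref, oth, pr, po)
        f = lambda v: scale * v + shift
        mapped = ci_width_comparison((f(ref[0]), f(ref[1])),
                                     (f(oth[0]), f(oth[1])), f(pr), f(po))
        assert mapped.width_ratio == pytest.approx(base.width_ratio, rel=1e-9)
        assert mapped.scaled_other == pytest.approx(base.scaled_other, rel=1e-6,
                                                    abs=1e-9)
        assert mapped.other_wider == base.other_wider

    def test_zero_width_reference_rejected(self):
        with pytest.raises(ComparisonError):
            ci_width_comparison((1, 1), (0, 2), 1.0, 1.0)


class TestCategorizeP:
    @pytest.mark.parametrize("p,scheme,expected", [
        (0.04, "binary", "significant"),
        (0.05, "binary", "significant"),   # boundary counts as significant
        (0.051, "binary", "not significant"),
        (0.007, "fine", "p<=0.01"),
        (0.05, "fine", "0.01<p<=0.05"),
        (0.07, "fine", "0.05<p<=0.10"),
        (0.5, "fine", "p>0.10"),
    ])
    def test_examples(self, p, scheme, expected):
        assert categorize_p(p, scheme) == expected

    def test_strict_convention(self):
        assert categorize_p(0.05, "binary", strict_less=True) == "not significant"
        assert categorize_p(0.049, "binary", strict_less=True) == "significant"

    def test_out_of_range_rejected(self):
        with pytest.raises(ComparisonError):
            categorize_p(1.5)


class TestConcordance:
    def test_hand_worked_table(self):
        # contingency [[40, 10], [5, 45]]: p_o = 0.85, p_e = 0.5, kappa = 0.7
        a = ["s"] * 50 + ["n"] * 50
        b = ["s"] * 40 + ["n"] * 10 + ["s"] * 5 + ["n"] * 45
        tab = concordance(a, b, labels=["s", "n"])
        np.testing.assert_array_equal(tab.counts, [[40, 10], [5, 45]])
        assert tab.percent_agreement == pytest.approx(85.0)
        assert tab.kappa == pytest.approx(0.70)
        assert tab.kappa_band == "substantial"

    def test_identical_vectors(self):
        tab = concordance(["a", "b", "a"], ["a", "b", "a"])
        assert tab.percent_agreement == 100.0 and tab.kappa == 1.0

    def test_independent_vectors_kappa_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.choice(["x", "y"], 10000)
        b = rng.choice(["x", "y"], 10000)
        tab = concordance(a, b)
        assert abs(tab.kappa) < 0.05

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        a = list(rng.choice(list("abc"), 300))
        b = list(rng.choice(list("abc"), 300))
        tab = concordance(a, b)
        assert tab.kappa == pytest.approx(sk.cohen_kappa_score(a, b), abs=1e-12)

    def test_recomputable_from_emitted_table(self):
        rng = np.random.default_rng(3)
        a = list(rng.choice(["s", "n"], 200))
        b = list(rng.choice(["s", "n"], 200))
        tab = concordance(a, b)
        counts = tab.counts
        n = counts.sum()
        p_o = np.trace(counts) / n
        p_e = float((counts.sum(1) / n) @ (counts.sum(0) / n))
        assert tab.percent_agreement == 100 * p_o
        assert tab.kappa == (p_o - p_e) / (1 - p_e)

    def test_empty_rejected(self):
        with pytest.raises(ComparisonError):
            concordance([], [])

    def test_adjective_bands(self):
        assert kappa_adjective(0.59) == "moderate"
        assert kappa_adjective(0.7) == "substantial"
        assert kappa_adjective(0.94) == "almost perfect"


class TestAutocorrSummary:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["method", "series_id", "rho_hat",
                                           "series_length", "valid"])

    def test_identical_estimates_identical_summaries(self):
        rows = []
        for m in ("PW", "REML", "ARIMA"):
            for i, r in enumerate([0.1, 0.2, 0.3]):
                rows.append((m, f"s{i}", r, 30, True))
        out = autocorrelation_summary(self.make_table(rows))
        med = out[out.stratum == "all"].set_index("method")["median"]
        assert med.nunique() == 1

    def test_empty_stratum_reported_not_error(self):
        rows = [("PW", "s0", 0.1, 30, True), ("PW", "s1", 0.2, 40, True)]
        out = autocorrelation_summary(self.make_table(rows))
        row = out[(out.method == "PW") & (out.stratum == ">=100")].iloc[0]
        assert row["n"] == 0 and np.isnan(row["median"])

    def test_invalid_rows_excluded(self):
        rows = [("PW", "s0", 0.1, 30, True), ("PW", "s1", 5.0, 40, False),
                ("PW", "s2", 0.3, 50, True)]
        out = autocorrelation_summary(self.make_table(rows))
        assert out[(out.method == "PW") & (out.stratum == "all")].iloc[0]["n"] == 2
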