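"""Tests for the four agreement indices and their intervals."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import retest as rt

from .conftest import anova_oracle, simulate_pairs

Z975 = stats.norm.ppf(0.975)


def vc(mu=10.0, sigma_s=1.0, sigma_e=0.5, n=10, truncated=False):
    """Hand-build variance components (msb/msw consistent with the SDs)."""
    msw = sigma_e**2
    msb = msw + 2 * sigma_s**2
    return rt.VarianceComponents(
        mu=mu, sigma_s=sigma_s, sigma_e=sigma_e, msb=msb, msw=msw,
        n_subjects=n, truncated=truncated,
    )


class TestWscv:
    def test_zero_for_perfect_repeatability(self):
        assert rt.wscv(vc(mu=12.0, sigma_e=0.0)) == 0.0

    def test_published_magnitude(self):
        # a poorly identified kinetic fit: sigma_e 8.596 on a mean of 12.28
        assert rt.wscv(vc(mu=12.28, sigma_e=8.596)) == pytest.approx(0.70, abs=0.005)

    def test_matches_oracle_ratio(self, toy_table, toy_pairs):
        mu, _, _, _, sigma_e, _ = anova_oracle(toy_pairs)
        assert rt.wscv(rt.fit_anova(toy_table)) == pytest.approx(
            sigma_e / mu, rel=1e-12
        )

    def test_rejects_non_positive_mean(self):
        with pytest.raises(rt.UndefinedRatioError):
            rt.wscv(vc(mu=0.0))


class TestIcc:
    @pytest.mark.parametrize(
        "sigma_s, sigma_e, expected",
        [(2.0, 0.0, 1.0), (1.5, 1.5, 0.5), (0.0, 1.0, 0.0)],
    )
    def test_limiting_values(self, sigma_s, sigma_e, expected):
        assert rt.icc(vc(sigma_s=sigma_s, sigma_e=sigma_e)) == pytest.approx(expected)

    def test_undefined_when_all_identical(self):
        with pytest.raises(rt.DegenerateDesignError):
            rt.icc(vc(sigma_s=0.0, sigma_e=0.0))

    def test_strictly_increasing_in_variance_ratio(self):
        ratios = np.linspace(0.1, 10, 25)
        vals = [rt.icc(vc(sigma_s=r, sigma_e=1.0)) for r in ratios]
        assert np.all(np.diff(vals) > 0)


class TestIccCi:
    def test_brackets_point_estimate(self, toy_table):
        c = rt.fit_anova(toy_table)
        lo, hi = rt.icc_ci(c, 0.05)
        assert lo <= rt.icc(c) <= hi

    def test_matches_independent_rederivation(self):
        """4-subject toy table vs. the F formulas typed out independently."""
        t = rt.TestRetestTable([("a", 8, 9), ("b", 12, 11), ("c", 15, 16), ("d", 20, 19)])
        c = rt.fit_anova(t)
        n = 4
        f0 = c.msb / c.msw
        f_low = f0 / stats.f.ppf(0.975, n - 1, n)
        f_high = f0 * stats.f.ppf(0.975, n, n - 1)
        expected = ((f_low - 1) / (f_low + 1), (f_high - 1) / (f_high + 1))
        got = rt.icc_ci(c, 0.05)
        assert got[0] == pytest.approx(max(expected[0], 0.0), abs=1e-10)
        assert got[1] == pytest.approx(min(expected[1], 1.0), abs=1e-10)

    def test_matches_pingouin_one_way_icc(self):
        """Independent implementation check: pingouin's ICC(1,1) and its
        F-based CI on a 6-subject table."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        t = rt.TestRetestTable(
            [("a", 8, 9), ("b", 12, 11), ("c", 15, 16),
             ("d", 20, 19), ("e", 9, 10), ("f", 14, 13)]
        )
        rows = []
        for p in t.pairs:
            rows += [{"s": p.subject_id, "r": 1, "v": p.y1},
                     {"s": p.subject_id, "r": 2, "v": p.y2}]
        ref = pg.intraclass_corr(pd.DataFrame(rows), targets="s", raters="r",
                                 ratings="v")
        ref1 = ref[ref["Type"] == "ICC(1,1)"].iloc[0]
        c = rt.fit_anova(t)
        assert rt.icc(c) == pytest.approx(float(ref1["ICC"]), abs=1e-9)
        lo, hi = rt.icc_ci(c, 0.05)
        ref_lo, ref_hi = ref1["CI95"]
        assert lo == pytest.approx(float(ref_lo), abs=0.005)
        assert hi == pytest.approx(float(ref_hi), abs=0.005)

    def test_interval_shrinks_with_n(self):
        """Width decreases toward 0 as n grows, fixed components."""
        rng = np.random.default_rng(77)
        widths = []
        for n in (10, 100, 1000):
            t = simulate_pairs(rng, n, 12.0, 2.0, 0.6)
            lo, hi = rt.icc_ci(rt.fit_anova(t), 0.05)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < 0.1


class TestRc:
    def test_zero_noise_gives_zero(self):
        assert rt.rc(vc(sigma_e=0.0)) == 0.0

    def test_multiplier_at_alpha_05(self):
        # with the conventional two-decimal z = 1.96 the multiplier is
        # sqrt(2) * 1.96 = 2.7719; the exact quantile gives 2.77181
        assert np.sqrt(2) * 1.96 == pytest.approx(2.7719, abs=5e-5)
        assert rt.rc(vc(sigma_e=1.0), 0.05) == pytest.approx(2.7719, abs=1.5e-4)
        assert rt.rc(vc(sigma_e=1.0), 0.05) == pytest.approx(
            np.sqrt(2) * Z975, rel=1e-12
        )

    def test_published_rc_from_rounded_components(self):
        # WSCV 0.70 of a 12.28 mean -> RC near the printed 23.87; the
        # two-decimal rounding of WSCV implies about +/-0.25 of slack
        value = rt.rc(vc(mu=12.28, sigma_e=0.70 * 12.28), 0.05)
        assert value == pytest.approx(23.87, abs=0.25)


class TestPtrt:
    def test_identical_pairs_give_zero(self):
        t = rt.TestRetestTable([("a", 5, 5), ("b", 7, 7)])
        assert rt.ptrt(t) == 0.0
        assert rt.ptrt(t, signed=True) == 0.0

    def test_two_pair_enumeration(self):
        # per-pair terms: |2*2/22| and |2*(-2)/38|
        t = rt.TestRetestTable([("a", 10, 12), ("b", 20, 18)])
        assert rt.ptrt(t) == pytest.approx((4 / 22 + 4 / 38) / 2, rel=1e-12)
        assert rt.ptrt(t, signed=True) == pytest.approx(
            (4 / 22 - 4 / 38) / 2, rel=1e-12
        )
        assert rt.ptrt(t) == pytest.approx(0.143541, abs=1e-6)
        assert rt.ptrt(t, signed=True) == pytest.approx(0.038278, abs=1e-6)

    def test_swap_symmetry(self):
        t = rt.TestRetestTable([("a", 10, 12), ("b", 20, 18), ("c", 30, 33)])
        swapped = rt.TestRetestTable([("a", 12, 10), ("b", 18, 20), ("c", 33, 30)])
        assert rt.ptrt(swapped) == pytest.approx(rt.ptrt(t), rel=1e-12)
        assert rt.ptrt(swapped, signed=True) == pytest.approx(
            -rt.ptrt(t, signed=True), rel=1e-12
        )

    def test_rejects_non_positive_pair_sum(self):
        t = rt.TestRetestTable([("a", 1, -1), ("b", 2, 3)])
        with pytest.raises(rt.UndefinedRatioError):
            rt.ptrt(t)

    @given(st.floats(1.0, 100.0), st.floats(1e-5, 0.01))
    def test_log_transform_equivalence_for_small_differences(self, y1, rel):
        """|2(y2-y1)/(y2+y1)| matches |log(y2/y1)| to first order: for
        relative differences <= 1% they differ by < 1e-4 relative."""
        y2 = y1 * (1 + rel)
        t = rt.TestRetestTable([("a", y1, y2), ("b", y1, y2)])
        ptrt_term = rt.ptrt(t)
        log_term = abs(np.log(y2 / y1))
        assert abs(ptrt_term - log_term) / log_term < 1e-4


class TestWscvCi:
    def test_brackets_point_estimate(self, toy_table):
        c = rt.fit_anova(toy_table)
        lo, hi = rt.wscv_ci(c, 0.05)
        assert lo <= rt.wscv(c) <= hi

    def test_width_decreases_with_n(self):
        rng = np.random.default_rng(11)
        widths = []
        for n in (10, 50, 250):
            t = simulate_pairs(rng, n, 12.0, 2.0, 0.6)
            lo, hi = rt.wscv_ci(rt.fit_anova(t), 0.05)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_sigma_e_interval_coverage(self):
        """The chi-square interval on sigma_e covers the truth ~95% of
        the time (1,000 reps, n = 50)."""
        rng = np.random.default_rng(5)
        mu, sigma_s, sigma_e = 12.0, 2.0, 0.6
        n, reps, hits = 50, 1000, 0
        for _ in range(reps):
            t = simulate_pairs(rng, n, mu, sigma_s, sigma_e)
            c = rt.fit_anova(t)
            lo, hi = rt.wscv_ci(c, 0.05)
            # undo the mu scaling to isolate the sigma_e interval
            if lo * c.mu <= sigma_e <= hi * c.mu:
                hits += 1
        assert hits / reps == pytest.approx(0.95, abs=0.02)


class TestEvaluate:
    def test_matches_componentwise_computation(self, toy_table):
        idx = rt.evaluate(toy_table, alpha=0.05)
        c = rt.fit_anova(toy_table)
        assert idx.wscv == pytest.approx(rt.wscv(c), rel=1e-12)
        assert idx.icc == pytest.approx(rt.icc(c), rel=1e-12)
        assert idx.rc == pytest.approx(rt.rc(c, 0.05), rel=1e-12)
        assert idx.ptrt_abs == pytest.approx(rt.ptrt(toy_table), rel=1e-12)
        assert idx.ptrt_signed == pytest.approx(
            rt.ptrt(toy_table, signed=True), rel=1e-12
        )
        assert idx.grand_mean == pytest.approx(c.mu, rel=1e-12)
        assert abs(idx.ptrt_signed) <= idx.ptrt_abs

    def test_rc_mean_ratio_is_scaled_wscv(self, toy_table):
        """RC / grand mean = sqrt(2) * z * WSCV exactly (the estimators'
        algebraic identity)."""
        idx = rt.evaluate(toy_table, alpha=0.05)
        assert idx.rc / idx.grand_mean == pytest.approx(
            np.sqrt(2) * Z975 * idx.wscv, abs=1e-10
        )

    def test_outlier_hits_wscv_harder_than_ptrt(self):
        """Inflating one retest x3 moves WSCV by a larger factor than
        the locally scaled PTRT."""
        rng = np.random.default_rng(42)
        t = simulate_pairs(rng, 7, 12.0, 2.0, 0.6)
        y = t.values.copy()
        y[0, 1] *= 3.0
        t_out = rt.TestRetestTable.from_arrays(y[:, 0], y[:, 1])
        clean, dirty = rt.evaluate(t), rt.evaluate(t_out)
        assert dirty.wscv / clean.wscv > dirty.ptrt_abs / clean.ptrt_abs
        assert dirty.icc < clean.icc

    @given(st.floats(0.1, 50.0))
    def test_scale_invariance(self, c):
        """ICC, WSCV, PTRT unchanged under y -> c*y; RC and mean scale."""
        base = rt.TestRetestTable([("a", 10, 12), ("b", 20, 18), ("c", 30, 33)])
        scaled = rt.TestRetestTable([("a", 10 * c, 12 * c), ("b", 20 * c, 18 * c),
                                     ("c", 30 * c, 33 * c)])
        i0, i1 = rt.evaluate(base), rt.evaluate(scaled)
        assert i1.wscv == pytest.approx(i0.wscv, rel=1e-9)
        assert i1.icc == pytest.approx(i0.icc, rel=1e-9)
        assert i1.ptrt_abs == pytest.approx(i0.ptrt_abs, rel=1e-9)
        assert i1.rc == pytest.approx(i0.rc * c, rel=1e-9)
        assert i1.grand_mean == pytest.approx(i0.grand_mean * c, rel=1e-9)

    def test_ptrt_monte_carlo_mean_matches_closed_form(self):
        """Under the clean model with small WSCV, E[PTRT] converges to
        (2/sqrt(pi)) * sigma_e / mu (mean absolute normal difference)."""
        rng = np.random.default_rng(7)
        # small WSCV and small relative between-subject spread, so the
        # first-order expansion of the pair-mean denominator applies
        mu, sigma_s, sigma_e, n, reps = 100.0, 2.0, 2.0, 10, 10_000
        vals = np.empty(reps)
        for r in range(reps):
            vals[r] = rt.ptrt(simulate_pairs(rng, n, mu, sigma_s, sigma_e))
        target = (2 / np.sqrt(np.pi)) * sigma_e / mu
        mc_se = vals.std(ddof=1) / np.sqrt(reps)
        # allow 4 MC standard errors plus the O(wscv^2) Taylor remainder
        assert abs(vals.mean() - target) < 4 * mc_se + 0.01 * target
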