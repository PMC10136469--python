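"""Statistical engine: t-tests, BH-FDR, mixed ANCOVA, simple effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hyperdyad.stats import (fdr_bh, mixed_ancova, rm_anova_2x2,
                             simple_effects, t_test)
from oracles import brute_bh, brute_mixed_anova


class TestTTest:
    def test_identical_paired_samples(self):
        r = t_test([1, 2, 3], [1, 2, 3], "paired")
        assert (r.t, r.p, r.cohens_d) == (0.0, 1.0, 0.0)

    def test_constant_nonzero_difference_flagged(self):
        r = t_test([2, 3, 4, 5], [1, 2, 3, 4], "paired")
        assert r.degenerate and r.p == 0.0 and np.isinf(r.t)

    def test_matches_direct_formula(self):
        x = np.array([1.2, 2.3, 3.1, 4.5, 2.2, 3.3])
        y = np.array([2.0, 2.1, 2.9, 5.0, 1.0, 2.5])
        d = x - y
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        r = t_test(x, y, "paired")
        assert r.t == pytest.approx(t_expect, abs=1e-10)
        assert r.cohens_d == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-10)
        # independent mode against pooled-sd formula
        sp = np.sqrt(((5) * x.var(ddof=1) + (5) * y.var(ddof=1)) / 10)
        t_ind = (x.mean() - y.mean()) / (sp * np.sqrt(2 / 6))
        ri = t_test(x, y, "independent")
        assert ri.t == pytest.approx(t_ind, abs=1e-10)
        assert ri.cohens_d == pytest.approx((x.mean() - y.mean()) / sp, abs=1e-10)

    def test_matches_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 12))
        r = t_test(x, y, "independent")
        t_ref, p_ref = sps.ttest_ind(x, y)
        assert r.t == pytest.approx(t_ref) and r.p == pytest.approx(p_ref)


class TestFdrBH:
    def test_all_extremes(self):
        m, _ = fdr_bh([0.0, 0.0, 0.0], 0.05)
        assert m.all()
        m, _ = fdr_bh([1.0, 1.0], 0.05)
        assert not m.any()
        m, adj = fdr_bh([], 0.05)
        assert m.size == 0 and adj.size == 0

    def test_worked_25_value_list(self):
        # step-up BH rejects the 6 smallest here: the 6th sorted p (0.06)
        # exactly equals its threshold 6/25 * 0.25
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212,
             0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341, 0.384, 0.569,
             0.594, 0.696, 0.762, 0.94, 0.942, 0.975, 0.986]
        m, _ = fdr_bh(p, 0.25)
        assert m[:6].all() and not m[6:].any()
        assert m.sum() == sum(brute_bh(p, 0.25))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_brute_force_stepup(self, p, q):
        m, _ = fdr_bh(p, q)
        assert list(m) == brute_bh(p, q)

    def test_mask_monotone_in_q(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30) ** 2
        prev = np.zeros(30, dtype=bool)
        for q in (0.01, 0.05, 0.1, 0.2, 0.4):
            m, _ = fdr_bh(p, q)
            assert (prev <= m).all()
            prev = m

    def test_adjusted_p_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        m, adj = fdr_bh(p, 0.1)
        ref_m, ref_adj, *_ = multipletests(p, 0.1, method="fdr_bh")
        assert np.array_equal(m, ref_m)
        assert np.allclose(adj, ref_adj)


def _long_table(y, groups, covs=None):
    rows = []
    for i in range(y.shape[0]):
        for w in (0, 1):
            row = {"unit": f"u{i}", "grp": groups[i], "blk": w + 1,
                   "y": y[i, w]}
            if covs is not None:
                row["c"] = covs[i]
            rows.append(row)
    return pd.DataFrame(rows)


class TestMixedAncova:
    def test_constant_dv_gives_zero_f(self):
        y = np.full((10, 2), 3.0)
        tbl = _long_table(y, ["a"] * 5 + ["b"] * 5)
        ft = mixed_ancova(tbl, "y", "grp", "blk")
        assert np.allclose(ft.table["F"], 0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_balanced_no_covariate_equals_textbook_mixed_anova(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        y = rng.standard_normal((2 * n, 2)) + rng.standard_normal((2 * n, 1))
        groups = np.array(["a"] * n + ["b"] * n)
        ft = mixed_ancova(_long_table(y, groups), "y", "grp", "blk")
        oracle = brute_mixed_anova(y, groups)
        assert ft.row("grp")["F"] == pytest.approx(oracle["between"][0], abs=1e-8)
        assert ft.row("blk")["F"] == pytest.approx(oracle["within"][0], abs=1e-8)
        assert ft.row("grp:blk")["F"] == pytest.approx(
            oracle["interaction"][0], abs=1e-8)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        y = rng.standard_normal((16, 2)) + rng.standard_normal((16, 1))
        tbl = _long_table(y, ["a"] * 8 + ["b"] * 8)
        ft = mixed_ancova(tbl, "y", "grp", "blk")
        ref = pg.mixed_anova(tbl, dv="y", within="blk", subject="unit",
                             between="grp").set_index("Source")
        assert ft.row("grp")["F"] == pytest.approx(ref.loc["grp", "F"])
        assert ft.row("blk")["F"] == pytest.approx(ref.loc["blk", "F"])
        assert ft.row("grp:blk")["F"] == pytest.approx(
            ref.loc["Interaction", "F"])
        assert ft.row("grp:blk")["eta_p2"] == pytest.approx(
            ref.loc["Interaction", "np2"])

    def test_uncorrelated_covariate_barely_moves_f(self):
        rng = np.random.default_rng(4)
        ratios = []
        for _ in range(200):
            y = rng.standard_normal((20, 2)) + 0.5 * rng.standard_normal((20, 1))
            y[10:, 1] += 0.8
            covs = rng.standard_normal(20)
            tbl0 = _long_table(y, ["a"] * 10 + ["b"] * 10)
            tbl1 = _long_table(y, ["a"] * 10 + ["b"] * 10, covs)
            f0 = mixed_ancova(tbl0, "y", "grp", "blk").row("grp:blk")["F"]
            f1 = mixed_ancova(tbl1, "y", "grp", "blk",
                              covariates=("c",)).row("grp:blk")["F"]
            ratios.append(f1 / f0)
        # ratios are heavy-tailed when the no-covariate F is near zero, so
        # the typical (median) change is the meaningful summary
        assert abs(np.median(ratios) - 1.0) < 0.1

    def test_collinear_covariate_rejected(self):
        y = np.random.default_rng(5).standard_normal((10, 2))
        covs = np.array([1.0] * 5 + [0.0] * 5)  # identical to the group split
        tbl = _long_table(y, ["a"] * 5 + ["b"] * 5, covs)
        with pytest.raises(ValueError, match="collinear"):
            mixed_ancova(tbl, "y", "grp", "blk", covariates=("c",))

    def test_interaction_type_one_error_calibrated(self):
        # pure-noise simulation: rejection rate at alpha = .05 must sit in
        # the binomial interval
        rng = np.random.default_rng(8)
        rej = 0
        n_rep = 2000
        for _ in range(n_rep):
            y = rng.standard_normal((12, 2))
            tbl = _long_table(y, ["a"] * 6 + ["b"] * 6)
            rej += mixed_ancova(tbl, "y", "grp", "blk").row("grp:blk")["p"] < 0.05
        lo, hi = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n_rep), \
            0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert lo <= rej / n_rep <= hi


class TestRm2x2AndSimpleEffects:
    def test_identical_cells_zero_f(self):
        y = np.ones(8)
        ft = rm_anova_2x2(y, y, y, y)
        assert np.allclose(ft.table["F"], 0.0)

    def test_matches_pingouin_two_way_rm(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        y11, y12, y21, y22 = rng.standard_normal((4, 10))
        ft = rm_anova_2x2(y11, y12, y21, y22, names=("A", "B"))
        rows = []
        for i in range(10):
            for a, (b1, b2) in (("a1", (y11, y12)), ("a2", (y21, y22))):
                rows += [(f"u{i}", a, "b1", b1[i]), (f"u{i}", a, "b2", b2[i])]
        ld = pd.DataFrame(rows, columns=["unit", "A", "B", "y"])
        ref = pg.rm_anova(ld, dv="y", within=["A", "B"],
                          subject="unit").set_index("Source")
        assert ft.row("A")["F"] == pytest.approx(ref.loc["A", "F"])
        assert ft.row("B")["F"] == pytest.approx(ref.loc["B", "F"])
        assert ft.row("A:B")["F"] == pytest.approx(ref.loc["A * B", "F"])

    def test_simple_effects_zero_when_block_means_equal(self):
        y = np.tile(np.random.default_rng(8).standard_normal((10, 1)), (1, 2))
        tbl = _long_table(y, ["a"] * 5 + ["b"] * 5)
        se = simple_effects(tbl, "y", "grp", "blk")
        paired = se[se["at"].str.startswith("grp=")]
        assert np.allclose(paired["t"], 0.0)

    def test_simple_effect_power_and_null_calibration(self):
        # a 0.8-sd within shift at n = 18 is reliably detected; with no
        # shift the p-values are uniform over seeds
        from scipy.stats import kstest
        rng = np.random.default_rng(9)
        detected, null_ps = 0, []
        for _ in range(300):
            base = rng.standard_normal(18)
            shift = base + 0.8 + rng.standard_normal(18) * 0.9
            r = t_test(shift, base + rng.standard_normal(18) * 0.9, "paired")
            detected += (r.p < 0.05) and (r.t > 0)
            a = rng.standard_normal(17)
            r0 = t_test(a + rng.standard_normal(17),
                        a + rng.standard_normal(17), "paired")
            null_ps.append(r0.p)
        assert detected / 300 > 0.5
        assert kstest(null_ps, "uniform").pvalue > 0.01
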