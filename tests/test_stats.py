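"""ANOVA, Tukey HSD, and the D_eff-vs-radius regression."""

import numpy as np
import pytest
from scipy import stats as sps

from colonydiff import GroupData, one_way_anova, regress_d_vs_radius, tukey_hsd
from colonydiff.exceptions import InsufficientDataError
from colonydiff.physchem import solute_records


def make_groups(*arrays, labels=None):
    labels = labels or [f"g{i}" for i in range(len(arrays))]
    return GroupData(group_labels=labels, values=[np.asarray(a, float) for a in arrays])


class TestAnova:
    def test_equal_group_means_give_zero_f(self):
        data = make_groups([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [2.5, 1.5, 2.0])
        res = one_way_anova(data)
        assert res.f_stat < 1e-12

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)
        res = one_way_anova(make_groups(a, b))
        t, _ = sps.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t**2, rel=1e-9)

    def test_worked_example_matches_brute_force(self):
        """3 groups x 4 replicates: F agrees with an explicit double-loop
        computation of the sums of squares."""
        groups = [[6.0, 8.0, 4.0, 5.0], [8.0, 12.0, 9.0, 11.0], [13.0, 9.0, 11.0, 8.0]]
        res = one_way_anova(make_groups(*groups))
        # independent oracle: accumulate SS term by term
        flat = [v for g in groups for v in g]
        grand = sum(flat) / len(flat)
        ss_b = ss_w = 0.0
        for g in groups:
            mean_g = sum(g) / len(g)
            ss_b += len(g) * (mean_g - grand) ** 2
            for v in g:
                ss_w += (v - mean_g) ** 2
        f_oracle = (ss_b / 2) / (ss_w / 9)
        assert res.f_stat == pytest.approx(f_oracle, rel=1e-12)
        assert res.df_between == 2 and res.df_within == 9
        # and against scipy's implementation
        f_sp, p_sp = sps.f_oneway(*groups)
        assert res.f_stat == pytest.approx(f_sp, rel=1e-9)
        assert res.p_value == pytest.approx(p_sp, rel=1e-9)

    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            data = make_groups(*(rng.normal(rng.uniform(-2, 2), 1.0, rng.integers(2, 9))
                                 for _ in range(rng.integers(2, 6))))
            res = one_way_anova(data)
            flat = np.concatenate(data.values)
            ss_total = ((flat - flat.mean()) ** 2).sum()
            assert res.ss_between + res.ss_within == pytest.approx(ss_total, rel=1e-9)

    def test_degenerate_inputs_flagged(self):
        res = one_way_anova(make_groups([1.0, 1.0], [1.0, 1.0]))
        assert res.degenerate
        res = one_way_anova(make_groups([1.0, 1.0], [2.0, 2.0]))
        assert res.infinite_f and np.isinf(res.f_stat)

    def test_group_invariants_enforced(self):
        with pytest.raises(ValueError):
            GroupData(group_labels=["a"], values=[np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            make_groups([1.0], [2.0, 3.0])


class TestTukey:
    def test_identical_means_nothing_significant(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 6)
        table = tukey_hsd(make_groups(base, base + 0.0, base * 1.0))
        assert not table["significant"].any()

    def test_separated_group_flagged_pairwise(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(0, 0.01, 5)
        g2 = rng.normal(0, 0.01, 5)
        g3 = rng.normal(10, 0.01, 5)
        table = tukey_hsd(make_groups(g1, g2, g3, labels=["a", "b", "c"]))
        sig = {frozenset((r.group1, r.group2)): r.significant
               for r in table.itertuples()}
        assert not sig[frozenset(("a", "b"))]
        assert sig[frozenset(("a", "c"))] and sig[frozenset(("b", "c"))]

    def test_critical_q_from_studentized_range(self):
        """Balanced k = 3, df = 12 design: critical q at 95% is ~3.77."""
        data = make_groups(*(np.arange(5.0) + m for m in (0.0, 1.0, 2.0)))
        table = tukey_hsd(data, alpha=0.05)
        assert table["q_crit"].iloc[0] == pytest.approx(3.77, abs=1e-2)

    def test_significance_agrees_with_scipy(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1.0, 7) for m in (0.0, 0.5, 3.0)]
        table = tukey_hsd(make_groups(*groups))
        ref = sps.tukey_hsd(*groups)
        for row, (i, j) in zip(table.itertuples(), [(0, 1), (0, 2), (1, 2)]):
            assert row.significant == (ref.pvalue[i, j] < 0.05)

    def test_pair_table_covers_all_unordered_pairs(self):
        data = make_groups(*(np.arange(4.0) + m for m in range(4)))
        table = tukey_hsd(data)
        assert len(table) == 6
        assert not (table["group1"] == table["group2"]).any()


class TestRegression:
    def test_collinear_points_give_r2_one(self):
        recs = list(solute_records().values())[:3]
        radii = np.array([r.hydrodynamic_radius for r in recs])
        res = regress_d_vs_radius(recs, 10.0 - 0.5 * radii)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(-0.5, rel=1e-12)

    def test_too_few_points_rejected(self):
        recs = list(solute_records().values())[:2]
        with pytest.raises(InsufficientDataError):
            regress_d_vs_radius(recs, [1.0, 2.0])

    def test_order_invariance(self):
        recs = list(solute_records().values())[:4]
        d = np.array([5.0, 3.0, 2.0, 4.0])
        fwd = regress_d_vs_radius(recs, d)
        rev = regress_d_vs_radius(recs[::-1], d[::-1])
        assert fwd.slope == pytest.approx(rev.slope, rel=1e-12)
        assert fwd.r2 == pytest.approx(rev.r2, rel=1e-12)

    def test_noisy_line_slope_within_ci(self):
        """Seeded noisy line: the OLS slope matches an analytic normal-
        equations oracle exactly and covers the truth at 95%."""
        from colonydiff import SoluteRecord

        rng = np.random.default_rng(17)
        recs = [
            SoluteRecord(name=f"s{i}", molecular_weight=1.0, hydrodynamic_radius=rh)
            for i, rh in enumerate((1.0, 2.0, 4.0, 6.0, 8.0, 9.0))
        ]
        x = np.array([r.hydrodynamic_radius for r in recs])
        y = 5.0 - 0.5 * x + 0.05 * rng.standard_normal(len(x))
        res = regress_d_vs_radius(recs, y)
        # normal-equations oracle
        sxx = ((x - x.mean()) ** 2).sum()
        slope_hat = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        assert res.slope == pytest.approx(slope_hat, rel=1e-12)
        resid = y - (res.intercept + res.slope * x)
        se = np.sqrt((resid**2).sum() / (len(x) - 2) / sxx)
        t_crit = sps.t.ppf(0.975, len(x) - 2)
        assert abs(res.slope - (-0.5)) <= t_crit * se

    def test_dextran_pipeline_regression(self):
        """Fitted D_eff over the three dextran presets decreases with
        hydrodynamic radius with R^2 > 0.8, inside and outside colonies."""
        from colonydiff import (
            default_line,
            estimate_din_dout,
            extract_profile,
            locate_colony,
            simulate_scenario,
        )

        recs = solute_records()
        names = ["dextran10", "dextran70", "dextran155"]
        d_in_vals, d_out_vals = [], []
        for name in names:
            stack, truth = simulate_scenario(f"{name}-LD61-like", seed=0)
            cfg = truth.config
            mask = locate_colony(stack.frames[0, 0], stack.pixel_size)
            series = extract_profile(stack, default_line(mask, (512, 512)))
            fit = estimate_din_dout(
                series, mask, fit_time=1800.0,
                background=cfg.background_level, x_offset=cfg.window_offset,
            )
            d_in_vals.append(fit.fit_in.d_eff)
            d_out_vals.append(fit.fit_out.d_eff)
        sols = [recs[n] for n in names]
        for vals, region in ((d_in_vals, "inside"), (d_out_vals, "outside")):
            res = regress_d_vs_radius(sols, vals, region)
            assert res.slope < 0
            assert res.r2 > 0.8
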