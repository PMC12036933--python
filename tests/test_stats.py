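"""t-tests, mixed ANOVA, BH correction, regressions — against closed forms
and an independent ANOVA implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from somamorph.stats import (
    DegenerateDataError,
    bh_fdr,
    mixed_anova_2x2,
    ols_regress,
    t_independent,
    t_paired,
)


class TestIndependentT:
    def test_identical_groups(self):
        r = t_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0
        assert r.direction == 0

    def test_closed_form(self):
        """x={1,2,3}, y={4,5,6}: pooled s²=1, se=√(2/3), t=-3/se≈-3.674, df=4."""
        r = t_independent([1, 2, 3], [4, 5, 6])
        t_expected = -3.0 / np.sqrt(2.0 / 3.0)
        assert r.statistic == pytest.approx(t_expected, abs=1e-3)
        assert r.statistic == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4
        assert r.p_value == pytest.approx(2.0 * sps.t.sf(abs(t_expected), 4), rel=1e-9)
        assert r.direction == -1

    def test_study_group_sizes_give_df_11(self, rng):
        r = t_independent(rng.normal(size=6), rng.normal(size=7))
        assert r.df == 11

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateDataError):
            t_independent([1.0, 1.0], [2.0, 2.0])

    def test_too_few(self):
        with pytest.raises(DegenerateDataError):
            t_independent([1.0], [2.0, 3.0])

    def test_order_invariant_within_groups(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=7)
        a = t_independent(x, y)
        b = t_independent(x[::-1], np.random.default_rng(1).permutation(y))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)


class TestPairedT:
    def test_equal_pairs(self):
        r = t_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_matches_one_sample_closed_form(self, rng):
        x = rng.normal(size=9)
        y = x - 0.7 + rng.normal(0, 0.3, size=9)
        d = x - y
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        r = t_paired(x, y)
        assert r.statistic == pytest.approx(t_expected, rel=1e-9)
        assert r.df == 8

    def test_seven_pairs_df_6(self, rng):
        r = t_paired(rng.normal(size=7), rng.normal(size=7))
        assert r.df == 6

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(DegenerateDataError):
            t_paired([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestMixedAnova:
    def test_all_equal_gives_zero_f(self):
        y = np.full((8, 2), 3.5)
        groups = ["a"] * 4 + ["b"] * 4
        tab = mixed_anova_2x2(y, groups)
        assert (tab["F"] == 0.0).all()

    def test_pure_within_effect(self, rng):
        """A population shift with no group effect: within-F large,
        between-F near zero."""
        base = rng.normal(0, 0.01, size=13)
        y = np.column_stack([base, base + 2.0])
        groups = ["statin"] * 6 + ["control"] * 7
        tab = mixed_anova_2x2(y, groups)
        assert tab.loc["population", "F"] > 1000
        assert tab.loc["population", "p"] < 1e-9
        assert tab.loc["group", "p"] > 0.05

    @pytest.mark.parametrize("n1,n2,seed", [(6, 7, 0), (5, 5, 1), (4, 9, 2), (8, 8, 3)])
    def test_matches_independent_implementation(self, n1, n2, seed):
        """F, df and p agree with pingouin's mixed ANOVA on balanced and
        unbalanced designs."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        n = n1 + n2
        y = rng.normal(size=(n, 2)) + np.array([0.4, 0.0])
        y[:n1] += rng.normal(0.3)
        groups = np.array(["g1"] * n1 + ["g2"] * n2)
        mine = mixed_anova_2x2(y, groups)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "group": np.repeat(groups, 2),
                "cond": ["A", "B"] * n,
                "y": y.ravel(),
            }
        )
        ref = pg.mixed_anova(data=df, dv="y", within="cond", between="group",
                             subject="subject").set_index("Source")
        for mine_key, ref_key in [("group", "group"), ("population", "cond"),
                                  ("interaction", "Interaction")]:
            assert mine.loc[mine_key, "F"] == pytest.approx(ref.loc[ref_key, "F"], rel=1e-9)
            assert mine.loc[mine_key, "p"] == pytest.approx(
                ref.loc[ref_key, "p_unc"], rel=1e-9
            )
            assert mine.loc[mine_key, "df2"] == ref.loc[ref_key, "DF2"]

    def test_df2_is_eleven_for_study_sizes(self, rng):
        y = rng.normal(size=(13, 2))
        tab = mixed_anova_2x2(y, ["statin"] * 6 + ["control"] * 7)
        assert (tab["df2"] == 11).all()

    def test_missing_within_value_rejected(self):
        y = np.ones((6, 2))
        y[2, 1] = np.nan
        with pytest.raises(DegenerateDataError):
            mixed_anova_2x2(y, ["a"] * 3 + ["b"] * 3)

    def test_relabeling_birds_invariant(self, rng):
        y = rng.normal(size=(13, 2))
        groups = np.array(["statin"] * 6 + ["control"] * 7)
        perm = np.concatenate([rng.permutation(6), 6 + rng.permutation(7)])
        a = mixed_anova_2x2(y, groups)
        b = mixed_anova_2x2(y[perm], groups[perm])
        assert np.allclose(a["F"], b["F"])


class TestBhFdr:
    def test_single_p_unchanged(self):
        adj, rej = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_worked_vector_all_rejected(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)
        assert rej.all()

    def test_worked_pair(self):
        adj, _ = bh_fdr([0.001, 0.9])
        assert adj == pytest.approx([0.002, 0.9])

    def test_empty(self):
        adj, rej = bh_fdr([])
        assert len(adj) == 0 and len(rej) == 0

    def test_monotone_and_prefix_rejections(self, rng):
        p = rng.uniform(size=40)
        adj, rej = bh_fdr(p, alpha=0.2)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        flags = rej[order]
        if flags.any():
            last = np.max(np.nonzero(flags))
            assert flags[: last + 1].all()

    def test_invalid_p_rejected(self):
        with pytest.raises(DegenerateDataError):
            bh_fdr([0.5, 1.5])


class TestOlsRegress:
    def test_exact_line(self):
        x = np.arange(10.0)
        r = ols_regress(x, 2.0 * x + 1.0)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_r_to_t_identity(self, rng):
        """For n=13 the slope t equals r·√(11/(1−r²)) with df=11."""
        x = rng.normal(size=13)
        y = rng.normal(size=13)
        r = ols_regress(x, y)
        rho = sps.pearsonr(x, y)[0]
        t = rho * np.sqrt(11.0 / (1.0 - rho**2))
        assert r.slope / r.stderr == pytest.approx(t, rel=1e-9)
        assert r.p_value == pytest.approx(2.0 * sps.t.sf(abs(t), 11), rel=1e-9)

    def test_two_points_rejected(self):
        with pytest.raises(DegenerateDataError):
            ols_regress([1.0, 2.0], [1.0, 2.0])

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDataError):
            ols_regress([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTypeICalibration:
    def test_null_rejection_rate_near_alpha(self):
        """Under the null generator the bird-level t-test rejects ≈5% of the
        time (light 500-study version; the acceptance suite runs 2000)."""
        from somamorph.simulate import gen_bird_mean_samples, null_effects

        s, c = gen_bird_mean_samples(
            "axis_ratio", null_effects(), n_studies=500, seed=9
        )
        rate = np.mean(
            [t_independent(s[i], c[i]).p_value < 0.05 for i in range(len(s))]
        )
        assert 0.02 <= rate <= 0.08
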