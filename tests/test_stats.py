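import itertools

import numpy as np
import pandas as pd
import pytest

from medocular.stats import (
    anova_table,
    expertise_index,
    holm_adjust,
    paired_t,
    pearson_test,
    rm_anova,
    task_posthoc_by_band,
)


def long_table(rng, n_subj, factors):
    """Balanced within-subject table of N(0,1) values."""
    names = list(factors)
    rows = []
    for s in range(n_subj):
        for combo in itertools.product(*factors.values()):
            rows.append({"subject": f"s{s}", "y": rng.standard_normal(),
                         **dict(zip(names, combo))})
    return pd.DataFrame(rows)


class TestExpertiseIndex:
    @pytest.mark.parametrize("practice,years,expected", [
        (0.0, 5.0, 0.0),
        (102.59, 2.31, 236.9829),
        (60.0, 1.0, 60.0),
    ])
    def test_product(self, practice, years, expected):
        assert expertise_index(practice, years) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            expertise_index(-1.0, 2.0)


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0 and res.effect_size == 0.0

    def test_hand_computed_differences(self):
        # differences (1, 2, 3): mean 2, sd 1 -> t = 2*sqrt(3), df = 2
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2

    def test_dz_is_t_over_sqrt_n(self, rng):
        x = rng.standard_normal(29)
        y = rng.standard_normal(29)
        res = paired_t(x, y)
        assert res.effect_size == pytest.approx(res.statistic / np.sqrt(29))

    def test_printed_worked_example(self):
        # |t| = 3.41 at n = 29 gives d_z ~ 0.633 (printed as .632 from
        # the unrounded statistic)
        assert 3.41 / np.sqrt(29) == pytest.approx(0.632, abs=0.002)

    def test_zero_variance_nonzero_mean(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.statistic == np.inf and res.p == 0.0


class TestPearson:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_test(x, x).effect_size == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_test(x, -2 * x + 7).effect_size == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        res = pearson_test([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.effect_size == pytest.approx(0.8)
        assert res.df == 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == [pytest.approx(0.03)]

    def test_hand_example(self):
        # step-down: 2 x 0.01 = 0.02; then max(0.02, 1 x 0.04) = 0.04
        adj = holm_adjust([0.01, 0.04])
        assert adj == [pytest.approx(0.02), pytest.approx(0.04)]

    def test_adjusted_dominates_raw(self, rng):
        p = rng.uniform(0, 1, size=10)
        adj = holm_adjust(p)
        assert all(a >= r for a, r in zip(adj, p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.1, 1.5])


class TestRmAnova:
    def test_constant_values_give_zero_f(self):
        rng = np.random.default_rng(0)
        tab = long_table(rng, 5, {"a": ["x", "y"]})
        tab["y"] = 1.0
        res = rm_anova(tab, dv="y", within=["a"])
        assert res["a"].F == 0.0

    def test_two_level_factor_equals_paired_t_squared(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            tab = long_table(rng, 8, {"a": ["x", "y"]})
            res = rm_anova(tab, dv="y", within=["a"])
            wide = tab.pivot(index="subject", columns="a", values="y")
            t = paired_t(wide["x"].values, wide["y"].values)
            assert res["a"].F == pytest.approx(t.statistic**2, abs=1e-9)
            assert (res["a"].df_num, res["a"].df_den) == (1, 7)
            assert res["a"].p == pytest.approx(t.p, abs=1e-12)

    def test_two_level_epsilon_is_exactly_one(self):
        rng = np.random.default_rng(3)
        tab = long_table(rng, 6, {"a": ["x", "y"]})
        assert rm_anova(tab, dv="y", within=["a"])["a"].epsilon == 1.0

    def test_epsilon_bounds_for_five_levels(self):
        rng = np.random.default_rng(4)
        tab = long_table(rng, 10, {"band": list("abcde")})
        eps = rm_anova(tab, dv="y", within=["band"])["band"].epsilon
        assert 1 / 4 <= eps <= 1

    def test_three_factor_design_has_seven_effects(self):
        rng = np.random.default_rng(5)
        tab = long_table(rng, 6, {"task": ["F", "I"], "cond": ["C", "S"],
                                  "band": list("abcde")})
        res = rm_anova(tab, dv="y", within=["task", "cond", "band"])
        assert len(res) == 7
        assert set(res) == {"task", "cond", "band", "task:cond", "task:band",
                            "cond:band", "task:cond:band"}

    def test_total_ss_decomposition(self):
        rng = np.random.default_rng(6)
        tab = long_table(rng, 7, {"task": ["F", "I"], "band": list("abc")})
        res = rm_anova(tab, dv="y", within=["task", "band"])
        y = tab["y"].values
        total = ((y - y.mean()) ** 2).sum()
        wide = tab.pivot_table(index="subject", values="y", aggfunc="mean")
        n_cells = 6
        ss_subject = n_cells * ((wide["y"] - y.mean()) ** 2).sum()
        parts = ss_subject + sum(r.ss + r.ss_error for r in res.values())
        assert parts == pytest.approx(total, rel=1e-8)

    def test_unbalanced_table_rejected_with_cells(self):
        rng = np.random.default_rng(7)
        tab = long_table(rng, 5, {"a": ["x", "y"]}).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova(tab, dv="y", within=["a"])

    def test_eta_p2_definition(self):
        rng = np.random.default_rng(8)
        tab = long_table(rng, 6, {"a": list("abc")})
        r = rm_anova(tab, dv="y", within=["a"])["a"]
        assert r.eta_p2 == pytest.approx(r.ss / (r.ss + r.ss_error))

    def test_cross_check_against_pingouin_one_way(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        tab = long_table(rng, 12, {"band": list("abcde")})
        mine = rm_anova(tab, dv="y", within=["band"])["band"]
        ref = pingouin.rm_anova(data=tab, dv="y", within="band",
                                subject="subject", correction=True,
                                effsize="ng2", detailed=True)
        row = ref[ref["Source"] == "band"].iloc[0]
        assert mine.F == pytest.approx(row["F"], rel=1e-9)
        assert mine.p == pytest.approx(row["p_unc"], rel=1e-9)
        assert mine.p_gg == pytest.approx(row["p_GG_corr"], rel=1e-6)
        assert mine.epsilon == pytest.approx(row["eps"], rel=1e-6)
        assert mine.eta_g2 == pytest.approx(row["ng2"], rel=1e-6)

    def test_cross_check_against_pingouin_two_way_f(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        tab = long_table(rng, 10, {"task": ["F", "I"], "band": list("abcd")})
        mine = rm_anova(tab, dv="y", within=["task", "band"])
        ref = pingouin.rm_anova(data=tab, dv="y",
                                within=["task", "band"], subject="subject")
        for src, key in (("task", "task"), ("band", "band"),
                         ("task * band", "task:band")):
            row = ref[ref["Source"] == src].iloc[0]
            assert mine[key].F == pytest.approx(row["F"], rel=1e-9)


class TestPosthoc:
    def test_family_is_all_bands_and_holm_applied(self):
        rng = np.random.default_rng(11)
        rows = []
        for s in range(10):
            for task in ("FAM", "IMW"):
                for band in ("delta", "theta", "alpha", "beta", "gamma"):
                    shift = 3.0 if (task == "IMW" and band == "delta") else 0.0
                    rows.append({"subject": f"s{s}", "task": task, "band": band,
                                 "log_power": rng.standard_normal() + shift})
        tab = pd.DataFrame(rows)
        out = task_posthoc_by_band(tab)
        assert len(out) == 5
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()
        delta_row = out[out["band"] == "delta"].iloc[0]
        assert delta_row["p_holm"] < 0.05 and delta_row["mean_diff"] > 0


def test_anova_table_round_trip():
    rng = np.random.default_rng(12)
    tab = long_table(rng, 5, {"a": ["x", "y"]})
    frame = anova_table(rm_anova(tab, dv="y", within=["a"]))
    assert list(frame.index) == ["a"]
    assert {"F", "p", "p_gg", "epsilon", "eta_g2", "eta_p2"} <= set(frame.columns)
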