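"""Statistics kernel: closed-form t-tests, Pearson, factorial ANOVA against
a sums-of-squares oracle, and the sleep-behaviour correlation table."""

import numpy as np
import pandas as pd
import pytest

from somnadapt.stats import (
    correlate_sleep_behavior,
    factorial_anova,
    mixed_anova,
    one_sample_t,
    one_sample_t_from_summary,
    pearson,
)


class TestOneSampleT:
    def test_mean_at_null_gives_half_p(self):
        res = one_sample_t([0.4, 0.5, 0.6], mu0=0.5)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(0.5)

    def test_closed_form_two_values(self):
        res = one_sample_t([0.3, 0.5], mu0=0.5, tail="lower")
        assert res.t == pytest.approx(-1.0)
        assert res.df == 1
        assert res.p == pytest.approx(0.25)

    def test_two_tailed_is_twice_smaller_one_tail(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.4, 0.1, 15)
        lo = one_sample_t(x, tail="lower").p
        hi = one_sample_t(x, tail="upper").p
        two = one_sample_t(x, tail="two").p
        assert two == pytest.approx(2 * min(lo, hi))

    def test_summary_stat_route(self):
        res = one_sample_t_from_summary(mean=0.20, sd=0.22, n=19, mu0=0.5)
        assert res.t == pytest.approx(-5.943, abs=0.01)
        assert res.d == pytest.approx(1.364, abs=0.01)

    def test_degenerate_sd_flagged(self):
        with pytest.warns(UserWarning):
            res = one_sample_t([0.5, 0.5, 0.5])
        assert res.degenerate


class TestPearson:
    def test_hand_computed_four_points(self):
        res = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6, abs=1e-12)
        assert res.n == 4

    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_definition_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x, y = rng.normal(size=(2, 30))
            res = pearson(x, y)
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert res.r == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


def anova_oracle_2x2(df, dv, f1, f2):
    """Brute-force sums-of-squares decomposition for a balanced 2x2 design."""
    grand = df[dv].mean()
    ss = {}
    for f in (f1, f2):
        ss[f] = sum(len(g) * (g[dv].mean() - grand) ** 2 for _, g in df.groupby(f))
    cell = df.groupby([f1, f2])[dv].mean()
    n_cell = df.groupby([f1, f2]).size().iloc[0]
    ss_cells = n_cell * sum(
        (cell[a, b] - grand) ** 2 for a, b in cell.index
    )
    ss[f"{f1}:{f2}"] = ss_cells - ss[f1] - ss[f2]
    ss_total = ((df[dv] - grand) ** 2).sum()
    ss["error"] = ss_total - ss_cells
    return ss


class TestFactorialAnova:
    def balanced_2x2(self):
        return pd.DataFrame(
            dict(
                y=[3.0, 4.0, 7.0, 6.0, 5.0, 5.5, 12.0, 11.0],
                A=["a", "a", "a", "a", "b", "b", "b", "b"],
                B=["x", "x", "y", "y", "x", "x", "y", "y"],
            )
        )

    def test_matches_ss_oracle_on_balanced_design(self):
        df = self.balanced_2x2()
        res = factorial_anova(df, "y", ["A", "B"])
        oracle = anova_oracle_2x2(df, "y", "A", "B")
        ms_err = oracle["error"] / 4  # df_resid = 8 - 4
        table = res.table.set_index("effect")
        for eff in ("A", "B", "A:B"):
            assert table.loc[eff, "sum_sq"] == pytest.approx(oracle[eff], abs=1e-9)
            assert table.loc[eff, "F"] == pytest.approx(oracle[eff] / ms_err, abs=1e-9)

    def test_ss_decomposition_additive(self):
        df = self.balanced_2x2()
        res = factorial_anova(df, "y", ["A", "B"])
        grand = df["y"].mean()
        ss_total = ((df["y"] - grand) ** 2).sum()
        import statsmodels.formula.api as smf

        resid = smf.ols("y ~ C(A, Sum)*C(B, Sum)", df).fit().ssr
        assert res.table["sum_sq"].sum() + resid == pytest.approx(ss_total, abs=1e-9)

    def test_location_invariance(self):
        df = self.balanced_2x2()
        shifted = df.assign(y=df["y"] + 100.0)
        f0 = factorial_anova(df, "y", ["A", "B"]).table["F"].to_numpy()
        f1 = factorial_anova(shifted, "y", ["A", "B"]).table["F"].to_numpy()
        assert np.allclose(f0, f1, atol=1e-8)

    def test_all_equal_observations_give_zero_f(self):
        df = self.balanced_2x2().assign(y=2.0)
        res = factorial_anova(df, "y", ["A", "B"])
        assert (res.table["F"] == 0.0).all()
        assert (res.table["p"] == 1.0).all()

    def test_three_factor_design_with_posthoc(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            dict(
                fmr=rng.normal(0.3, 0.1, 40),
                group=np.tile(["sleep", "wake"], 20),
                face=np.repeat(["A", "B"], 20),
                gender=np.tile(["m", "m", "f", "f"], 10),
            )
        )
        df.loc[df.group == "sleep", "fmr"] -= 0.15
        res = factorial_anova(df, "fmr", ["group", "face", "gender"], posthoc=["group"])
        assert len(res.table) == 7  # 3 mains + 3 two-way + 1 three-way
        assert res.posthoc is not None
        assert ((res.posthoc["p_bonf"] >= res.posthoc["p_unc"] - 1e-15).all())

    def test_empty_cells_drop_interactions(self):
        df = self.balanced_2x2().iloc[:6]  # cell (b, y) emptied
        df = df[~((df.A == "b") & (df.B == "y"))]
        with pytest.warns(UserWarning, match="empty"):
            res = factorial_anova(df, "y", ["A", "B"])
        assert "A:B" not in set(res.table["effect"])
        assert res.dropped_effects


def test_mixed_anova_recovers_within_effect():
    rng = np.random.default_rng(8)
    n = 16
    subj = np.repeat(np.arange(n), 2)
    session = np.tile(["adaptation", "test"], n)
    group = np.repeat(["sleep", "wake"], n)
    rating = rng.normal(3.0, 0.3, 2 * n)
    rating[session == "test"] += 1.5  # strong within-subject effect
    df = pd.DataFrame(dict(subject=subj, session=session, group=group, rating=rating))
    out = mixed_anova(df, dv="rating", within="session", between="group", subject="subject")
    sess = out[out["Source"] == "session"].iloc[0]
    assert sess["p_unc"] < 1e-6


class TestCorrelateSleepBehavior:
    def test_planted_and_null_parameters(self):
        rng = np.random.default_rng(2)
        n = 12
        rem = rng.normal(11, 4, n)
        fmr = pd.Series(0.02 * rem + rng.normal(0, 0.01, n),
                        index=[f"s{i}" for i in range(n)], name="fmr")
        params = pd.DataFrame(
            dict(rem=rem, noise=rng.normal(size=n)), index=fmr.index
        )
        out = correlate_sleep_behavior(params, fmr).set_index("parameter")
        assert out.loc["rem", "r"] > 0.9
        assert abs(out.loc["noise", "r"]) < 0.7
        assert (out["n"] == n).all()

    def test_short_and_constant_parameters_skipped(self):
        fmr = pd.Series([0.2, 0.3, 0.4], index=list("abc"))
        params = pd.DataFrame(
            dict(const=[1.0, 1.0, 1.0], sparse=[0.5, np.nan, np.nan]), index=list("abc")
        )
        with pytest.warns(UserWarning):
            out = correlate_sleep_behavior(params, fmr)
        assert out.empty
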