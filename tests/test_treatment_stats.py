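"""Factorial ANOVA, LSD letters, and Kruskal–Wallis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tomsugar as ts
from tomsugar.core_model import ConfigurationError
from tomsugar.treatment_stats import factorial_anova, kruskal_wallis, lsd_letters


def balanced_table(rng, n_rep=3, effects=None):
    """Random balanced 4x2x2 table with optional additive effects."""
    effects = effects or {}
    rows = []
    for w, p, s in itertools.product("ABCD", "xy", "uv"):
        for r in range(n_rep):
            y = rng.normal()
            y += effects.get("water", {}).get(w, 0.0)
            y += effects.get("potassium", {}).get(p, 0.0)
            y += effects.get("stage", {}).get(s, 0.0)
            rows.append({"water": w, "potassium": p, "stage": s, "y": y})
    return pd.DataFrame(rows)


def projection_oracle(table, response, factors):
    """Brute-force ANOVA via orthogonal projections of the model matrix.

    Builds full-rank sum-coded design blocks per term and computes each
    term's sum of squares as the squared norm of the projection of y onto
    the increment of the column space — independent of the implementation
    under test.
    """
    y = table[response].to_numpy(dtype=float)
    n = len(y)

    def codes(f):
        levels = sorted(table[f].unique())
        X = np.zeros((n, len(levels) - 1))
        for j, lev in enumerate(levels[:-1]):
            X[:, j] = (table[f] == lev).astype(float) - (table[f] == levels[-1]).astype(float)
        return X

    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for r in range(1, len(factors) + 1):
        for sub in itertools.combinations(factors, r):
            mats = [codes(f) for f in sub]
            X = mats[0]
            for m in mats[1:]:
                X = np.einsum("ni,nj->nij", X, m).reshape(n, -1)
            blocks.append(X)
            names.append(" x ".join(sub))

    ss = {}
    prev_fit = np.zeros(n)
    X_acc = np.empty((n, 0))
    for name, block in zip(names, blocks):
        X_acc = np.hstack([X_acc, block])
        beta, *_ = np.linalg.lstsq(X_acc, y, rcond=None)
        fit = X_acc @ beta
        ss[name] = float(np.sum((fit - prev_fit) ** 2))
        prev_fit = fit
    ss["Residual"] = float(np.sum((y - prev_fit) ** 2))
    return ss


class TestFactorialAnova:
    def test_all_equal_responses_zero_ss(self):
        table = balanced_table(np.random.default_rng(0))
        table["y"] = 3.14
        res = factorial_anova(table, "y")
        terms = res.table.drop(index="Residual")
        assert np.allclose(terms["sum_sq"], 0.0, atol=1e-18)
        assert np.allclose(terms["F"].fillna(0.0), 0.0)

    def test_decomposition_sums_to_total(self):
        table = balanced_table(np.random.default_rng(1))
        res = factorial_anova(table, "y")
        total = float(np.sum((table["y"] - table["y"].mean()) ** 2))
        assert res.table["sum_sq"].sum() == pytest.approx(total, rel=1e-12)
        assert res.table["df"].sum() == len(table) - 1

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_projection_oracle(self, seed):
        table = balanced_table(np.random.default_rng(seed))
        factors = ("water", "potassium", "stage")
        mine = factorial_anova(table, "y", factors).table
        oracle = projection_oracle(table, "y", factors)
        for term in mine.index:
            if term == "Residual":
                continue
            assert mine.loc[term, "sum_sq"] == pytest.approx(oracle[term], abs=1e-8)
        assert mine.loc["Residual", "sum_sq"] == pytest.approx(oracle["Residual"], abs=1e-8)

    def test_matches_statsmodels(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        table = balanced_table(np.random.default_rng(5))
        fit = smf.ols("y ~ C(water)*C(potassium)*C(stage)", data=table).fit()
        ref = anova_lm(fit, typ=2)
        mine = factorial_anova(table, "y").table
        pairs = {
            "water": "C(water)",
            "potassium x stage": "C(potassium):C(stage)",
            "water x potassium x stage": "C(water):C(potassium):C(stage)",
        }
        for term, sm_term in pairs.items():
            assert mine.loc[term, "F"] == pytest.approx(ref.loc[sm_term, "F"], rel=1e-10)

    def test_injected_effect_detected(self):
        rng = np.random.default_rng(6)
        table = balanced_table(rng, effects={"water": {"A": 2.0}})
        res = factorial_anova(table, "y")
        assert res.p_value("water") < 0.01
        assert res.p_value("potassium x stage") > 0.01

    def test_two_factor_variant(self):
        table = balanced_table(np.random.default_rng(7))
        res = factorial_anova(table, "y", factors=("water", "potassium"))
        assert set(res.table.index) == {"water", "potassium", "water x potassium", "Residual"}

    def test_unbalanced_rejected(self):
        table = balanced_table(np.random.default_rng(8))
        with pytest.raises(ConfigurationError, match="unbalanced"):
            factorial_anova(table.iloc[:-1], "y")

    def test_empty_cell_named(self):
        table = balanced_table(np.random.default_rng(9))
        drop = (table["water"] == "A") & (table["potassium"] == "x") & (table["stage"] == "u")
        with pytest.raises(ConfigurationError, match="empty cell"):
            factorial_anova(table[~drop], "y")

    def test_null_type_I_error_rate(self):
        """Water-effect false positive rate at alpha=0.05 over 500 null sims."""
        rejections = 0
        for seed in range(500):
            table = balanced_table(np.random.default_rng(10_000 + seed), n_rep=2)
            if factorial_anova(table, "y").p_value("water") < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 500 <= 0.08


class TestLsdLetters:
    def test_equal_means_share_one_letter(self):
        g = lsd_letters({"a": 1.0, "b": 1.0, "c": 1.0}, residual_ms=1.0, residual_df=10, n_per_level=3)
        assert set(g.letters.values()) == {"a"}

    def test_separated_means_distinct_letters(self):
        g = lsd_letters({"hi": 10.0, "lo": 0.0}, residual_ms=1e-6, residual_df=10, n_per_level=3)
        assert g.letters["hi"] == "a" and g.letters["lo"] == "b"

    @pytest.mark.parametrize("seed", range(5))
    def test_letters_consistent_with_every_pairwise_test(self, seed):
        """Shared letter <-> non-significant pair, checked exhaustively."""
        rng = np.random.default_rng(seed)
        levels = [f"L{i}" for i in range(6)]
        means = {lv: rng.normal(scale=2.0) for lv in levels}
        ms, df, n = 1.0, 20, 4
        g = lsd_letters(means, ms, df, n)
        t_crit = stats.t.ppf(0.975, df)
        lsd = t_crit * np.sqrt(ms * 2.0 / n)
        for a, b in itertools.combinations(levels, 2):
            significant = abs(means[a] - means[b]) > lsd
            share = set(g.letters[a]) & set(g.letters[b])
            assert significant == (not share), (a, b, g.letters)

    def test_largest_mean_gets_letter_a(self):
        g = lsd_letters({"x": 5.0, "y": 0.0, "z": -5.0}, residual_ms=1e-6, residual_df=10, n_per_level=3)
        assert g.letters["x"] == "a" and g.letters["z"] == "c"


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        h, p = kruskal_wallis([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert h == 0.0 and p == 1.0

    def test_two_disjoint_groups_hand_ranks(self):
        """n=3 each, no overlap: H = 12/(N(N+1)) * sum n(rbar - (N+1)/2)^2."""
        g1, g2 = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        h, p = kruskal_wallis(g1, g2)
        # ranks 1,2,3 and 4,5,6 -> means 2 and 5; H = 12/42 * 3*((2-3.5)^2+(5-3.5)^2)
        assert h == pytest.approx(12 / 42 * 3 * (1.5**2 + 1.5**2), rel=1e-12)

    def test_chi_square_p_close_to_permutation(self):
        """Chi-square approximation agrees with a permutation oracle."""
        rng = np.random.default_rng(11)
        groups = [rng.normal(size=6), rng.normal(size=6) + 1.0, rng.normal(size=6)]
        h_obs, p_chi = kruskal_wallis(*groups)
        flat = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = 0
        n_perm = 3000
        for _ in range(n_perm):
            rng.shuffle(flat)
            parts = np.split(flat, np.cumsum(sizes)[:-1])
            h_p, _ = kruskal_wallis(*parts)
            if h_p >= h_obs:
                count += 1
        p_perm = count / n_perm
        assert p_perm == pytest.approx(p_chi, abs=0.03)
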