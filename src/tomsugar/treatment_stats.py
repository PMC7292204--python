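"""Treatment statistics: balanced factorial ANOVA, LSD letters, Kruskal–Wallis.

The study's statistical stage is a balanced fixed-effects factorial —
water (4 levels) x potassium (2) x growth stage (2) over the whole
experiment, or water x potassium within the maturation stage — followed
by Fisher's least-significant-difference (LSD) multiple range test at
P = 0.05 summarised as a compact letter display ("a" = largest mean;
levels sharing a letter do not differ significantly).

In a balanced design sequential and marginal sums of squares coincide, so
the decomposition is computed directly from cell means via
inclusion–exclusion: the effect of a factor subset S at an observation is
the Möbius-alternating sum of the means over all sub-subsets of S, and
SS(S) is the sum of squared effects over observations.  The LSD test is
applied without family-wise correction, as the procedure prescribes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ConfigurationError, DomainError


@dataclass
class AnovaResult:
    """Fixed-effects decomposition; one row per term plus residual."""

    table: pd.DataFrame  # index: term; columns: df, sum_sq, mean_sq, F, p
    factors: tuple
    n_obs: int

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["Residual", "mean_sq"])

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["Residual", "df"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _check_balance(df: pd.DataFrame, factors, response):
    counts = df.groupby(list(factors), observed=True)[response].count()
    full = 1
    for f in factors:
        full *= df[f].nunique()
    if len(counts) < full:
        present = set(counts.index if len(factors) > 1 else [(i,) for i in counts.index])
        levels = [sorted(df[f].unique()) for f in factors]
        empty = [c for c in itertools.product(*levels) if c not in present]
        raise ConfigurationError(f"factorial table has empty cell(s): {empty}")
    if counts.nunique() != 1:
        raise ConfigurationError(
            "unbalanced design (unequal cell counts); analyse a balanced subset "
            "of replicates instead"
        )
    return int(counts.iloc[0])


def factorial_anova(
    table: pd.DataFrame,
    response: str,
    factors: tuple = ("water", "potassium", "stage"),
) -> AnovaResult:
    """Balanced fixed-effects ANOVA with all interactions.

    ``factors`` may name two or three (or more) columns; the maturation
    stage analysis is the same machinery with the stage factor dropped.
    Requires a balanced design with at least 2 replicates per cell.
    """
    for col in (response, *factors):
        if col not in table.columns:
            raise ConfigurationError(f"factorial table is missing column {col}")
    n_per_cell = _check_balance(table, factors, response)
    if n_per_cell < 2:
        raise ConfigurationError("ANOVA needs at least 2 replicates per cell")

    y = table[response].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()

    # per-observation means over every factor subset (∅ -> grand mean)
    subset_means = {(): np.full(n, grand)}
    for r in range(1, len(factors) + 1):
        for sub in itertools.combinations(factors, r):
            subset_means[sub] = table.groupby(list(sub), observed=True)[response].transform("mean").to_numpy()

    rows = {}
    ss_terms = 0.0
    df_terms = 0
    levels = {f: table[f].nunique() for f in factors}
    for r in range(1, len(factors) + 1):
        for sub in itertools.combinations(factors, r):
            effect = np.zeros(n)
            for k in range(r + 1):
                for t in itertools.combinations(sub, k):
                    effect += (-1) ** (r - k) * subset_means[t]
            ss = float(np.sum(effect**2))
            df_term = 1
            for f in sub:
                df_term *= levels[f] - 1
            rows[" x ".join(sub)] = (df_term, ss)
            ss_terms += ss
            df_terms += df_term

    cell_mean = subset_means[tuple(factors)]
    ss_resid = float(np.sum((y - cell_mean) ** 2))
    df_resid = n - int(np.prod([levels[f] for f in factors]))
    ms_resid = ss_resid / df_resid

    out = []
    for term, (df_t, ss) in rows.items():
        ms = ss / df_t
        F = ms / ms_resid if ms_resid > 0 else 0.0
        p = float(stats.f.sf(F, df_t, df_resid)) if ms_resid > 0 else 1.0
        out.append({"term": term, "df": df_t, "sum_sq": ss, "mean_sq": ms, "F": F, "p": p})
    out.append(
        {"term": "Residual", "df": df_resid, "sum_sq": ss_resid, "mean_sq": ms_resid,
         "F": np.nan, "p": np.nan}
    )
    result = pd.DataFrame(out).set_index("term")
    return AnovaResult(table=result, factors=tuple(factors), n_obs=n)


# ---------------------------------------------------------------------------
# Fisher's LSD with compact letter display
# ---------------------------------------------------------------------------

@dataclass
class LsdGrouping:
    """Per-level means with LSD letters ('a' = largest mean)."""

    means: pd.Series  # sorted descending
    letters: dict
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.means, "letters": [self.letters[k] for k in self.means.index]}
        )


def lsd_letters(
    means: dict | pd.Series,
    residual_ms: float,
    residual_df: int,
    n_per_level,
    alpha: float = 0.05,
) -> LsdGrouping:
    """Fisher's LSD multiple range test as a compact letter display.

    ``n_per_level`` is an int (equal group sizes) or a mapping per level.
    Two levels differ when |mean_i - mean_j| exceeds
    t(1-alpha/2, df) * sqrt(MS_resid * (1/n_i + 1/n_j)).  Letters are
    assembled by insert-and-absorb: start from one class holding every
    level; each significant pair splits every class containing both;
    classes nested in another are absorbed.
    """
    if residual_df < 1:
        raise DomainError("LSD needs at least 1 residual degree of freedom")
    means = pd.Series(means).sort_values(ascending=False)
    levels = list(means.index)
    if isinstance(n_per_level, dict):
        n_of = {k: n_per_level[k] for k in levels}
    else:
        n_of = {k: int(n_per_level) for k in levels}
    t_crit = stats.t.ppf(1 - alpha / 2, residual_df)

    def significant(a, b):
        lsd = t_crit * np.sqrt(residual_ms * (1.0 / n_of[a] + 1.0 / n_of[b]))
        return abs(means[a] - means[b]) > lsd

    classes = [set(levels)]
    for a, b in itertools.combinations(levels, 2):
        if not significant(a, b):
            continue
        new_classes = []
        for cls in classes:
            if a in cls and b in cls:
                new_classes.append(cls - {a})
                new_classes.append(cls - {b})
            else:
                new_classes.append(cls)
        # absorb: drop empties, duplicates, and classes nested in another
        uniq = []
        for c in new_classes:
            if c and c not in uniq:
                uniq.append(c)
        classes = [c for c in uniq if not any(c < other for other in uniq)]

    # order classes by their largest member mean; label 'a', 'b', ...
    classes.sort(key=lambda c: -max(means[m] for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letter_of = {}
    for letter, cls in zip(alphabet, classes):
        for lvl in cls:
            letter_of.setdefault(lvl, []).append(letter)
    letters = {lvl: "".join(sorted(letter_of[lvl])) for lvl in levels}
    return LsdGrouping(means=means, letters=letters, alpha=alpha)


def lsd_from_anova(
    table: pd.DataFrame,
    response: str,
    factor: str,
    anova: AnovaResult,
    alpha: float = 0.05,
) -> LsdGrouping:
    """LSD letters for one factor's level means using the ANOVA residual."""
    means = table.groupby(factor, observed=True)[response].mean()
    counts = table.groupby(factor, observed=True)[response].count()
    return lsd_letters(
        means.to_dict(),
        anova.residual_ms,
        anova.residual_df,
        counts.to_dict(),
        alpha=alpha,
    )


def kruskal_wallis(*groups):
    """Rank-based Kruskal–Wallis H with tie correction; chi-square p.

    Degenerate input (all observations identical) returns H = 0, p = 1.
    """
    if len(groups) < 2:
        raise DomainError("Kruskal–Wallis needs at least two groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)
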