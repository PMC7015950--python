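"""Shared one-way group comparison machinery.

One-way ANOVA, all pairwise Welch t-tests with Bonferroni correction,
and a deterministic compact letter display, used both by the qPCR ratio
comparisons and the taxa-level screens.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ValidationError

__all__ = ["anova_oneway", "pairwise_welch_bonferroni",
           "compact_letter_display", "group_summary"]


def group_summary(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-level n, mean and standard error of the mean."""
    df = pd.DataFrame({"value": values, "group": groups.loc[values.index]})
    out = df.groupby("group")["value"].agg(n="count", mean="mean", sd="std")
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def anova_oneway(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across group levels."""
    arrays = [values[groups.loc[values.index] == g].to_numpy()
              for g in pd.unique(groups.loc[values.index])]
    arrays = [a for a in arrays if len(a)]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    if all(np.ptp(a) == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        equal = max(means) == min(means)
        return (0.0, 1.0) if equal else (math.inf, 0.0)
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test with a degenerate-variance convention.

    If both groups have zero variance the limit is taken: p = 1 for
    equal means, p = 0 otherwise (t = 0 / +-inf).
    """
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pairwise_welch_bonferroni(values: pd.Series, groups: pd.Series,
                              ) -> pd.DataFrame:
    """All pairwise Welch t-tests, Bonferroni-adjusted over the pairs.

    Adjusted p = raw p x number of pairs, capped at 1.  Levels with a
    single observation are excluded (a t-test is undefined there).
    """
    g = groups.loc[values.index]
    levels = [lv for lv in pd.unique(g) if (g == lv).sum() >= 2]
    if len(levels) < 2:
        raise ValidationError(
            "pairwise tests need >= 2 groups with >= 2 samples each")
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a_lv, b_lv in pairs:
        a = values[g == a_lv].to_numpy(dtype=float)
        b = values[g == b_lv].to_numpy(dtype=float)
        t, p = _welch(a, b)
        rows.append(dict(group_a=a_lv, group_b=b_lv, t=t, p_raw=p,
                         p_bonferroni=min(1.0, p * len(pairs))))
    return pd.DataFrame(rows)


def compact_letter_display(pairwise: pd.DataFrame, order,
                           alpha: float = 0.05,
                           p_col: str = "p_bonferroni") -> dict:
    """Assign letters so levels share a letter iff not significantly different.

    Insert-and-absorb construction: start with all levels in one letter
    group; each significant pair splits every group containing both;
    subset groups are absorbed.  ``order`` fixes the letter assignment
    (typically levels sorted by decreasing mean) so output is
    deterministic.
    """
    order = list(order)
    sig = [(r.group_a, r.group_b) for r in pairwise.itertuples()
           if getattr(r, p_col) < alpha]
    groups: list[set] = [set(order)]
    for a, b in sig:
        nxt = []
        for s in groups:
            if a in s and b in s:
                nxt.append(s - {a})
                nxt.append(s - {b})
            else:
                nxt.append(s)
        # absorb: drop duplicates and strict subsets
        groups = []
        for s in nxt:
            if not s:
                continue
            if any(s < t or s == t for t in nxt if t is not s):
                if any(s == t for t in groups):
                    continue
                if any(s < t for t in nxt if t is not s):
                    continue
            groups.append(s)
    groups.sort(key=lambda s: min(order.index(m) for m in s))
    letters = {lv: "" for lv in order}
    for letter, s in zip(_letter_stream(), groups):
        for lv in order:
            if lv in s:
                letters[lv] += letter
    return letters


def _letter_stream():
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for size in range(1, 4):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)
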