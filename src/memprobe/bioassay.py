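"""Seedling root-length bioassay statistics.

Summaries, growth-inhibition percentages against a control, and a randomized
complete block ANOVA with Tukey HSD pairwise comparisons rendered as a compact
letter display (treatments sharing a letter are not significantly different).
The replicate unit is the dish (one dish of seedlings per treatment per
block); seedling-level input is aggregated to per-dish means first.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range
from sklearn.base import BaseEstimator
from statsmodels.stats.anova import anova_lm

__all__ = [
    "summarize",
    "inhibition_percentage",
    "BlockAnovaTukey",
    "anova_tukey_cld",
    "compact_letter_display",
]


def load_bioassay_table(path) -> pd.DataFrame:
    """Read a bioassay CSV; either seedling-level (treatment, block, dish,
    root_length_mm) or pre-aggregated (treatment, block, mean_mm)."""
    df = pd.read_csv(path)
    if {"treatment", "block", "mean_mm"} <= set(df.columns):
        return df.rename(columns={"mean_mm": "root_length_mm"}).assign(dish=lambda d: d.index)
    missing = {"treatment", "block", "root_length_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"bioassay CSV missing columns: {sorted(missing)}")
    if "dish" not in df.columns:
        df = df.assign(dish=0)
    return df


def to_dish_means(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate seedling rows to per-dish mean root lengths (the replicate unit)."""
    cols = ["treatment", "block"] + (["dish"] if "dish" in table.columns else [])
    g = table.groupby(cols, sort=True)["root_length_mm"].mean().reset_index()
    return g


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean, sample SD (n−1) and n over per-dish means.

    Groups of size one get a missing SD rather than an error.
    """
    if table.empty:
        raise ValueError("empty bioassay table")
    if np.any(table["root_length_mm"] < 0):
        raise ValueError("root lengths must be non-negative")
    dishes = to_dish_means(table)
    out = (
        dishes.groupby("treatment", sort=True)["root_length_mm"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan, n="count")
        .reset_index()
    )
    return out


def inhibition_percentage(mean_treatment: float, mean_control: float) -> float:
    """Growth inhibition relative to control, %, rounded to one decimal."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return round(100.0 * (mean_control - mean_treatment) / mean_control, 1)


def compact_letter_display(
    levels: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant[(a, b)]`` is True when a and b differ.  Two levels share at
    least one letter iff their comparison is non-significant.
    """

    def differs(a, b):
        return significant.get((a, b), significant.get((b, a), False))

    # letter groups are sets of mutually non-different levels
    groups: list[set[str]] = []
    for lv in levels:
        placed = False
        for g in groups:
            if not any(differs(lv, other) for other in g):
                g.add(lv)
                placed = True
        if not placed:
            groups.append({lv})
    # insert step: every non-significant pair must share a group
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            if not differs(a, b) and not any(a in g and b in g for g in groups):
                groups.append({a, b})
    # absorb subsets
    groups = [g for g in groups if not any(g < h for h in groups if h is not g)]
    # deduplicate and order by the first level they contain
    uniq: list[set[str]] = []
    for g in groups:
        if g not in uniq:
            uniq.append(g)
    uniq.sort(key=lambda g: min(levels.index(x) for x in g))
    letters = {lv: "" for lv in levels}
    for letter, g in zip(string.ascii_lowercase, uniq):
        for lv in g:
            letters[lv] += letter
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


class BlockAnovaTukey(BaseEstimator):
    """Randomized-block ANOVA with Tukey HSD and compact letter display.

    fit(table) expects a tidy table with columns ``treatment``, ``block`` and
    ``root_length_mm`` (seedling rows are first aggregated to per-dish means).
    The model is a two-way fixed-effects ANOVA, response ~ treatment + block;
    Tukey comparisons use the studentized-range distribution with the ANOVA
    residual mean square, with the Tukey–Kramer adjustment for unequal n.

    Parameters
    ----------
    alpha : family-wise significance level for the letter display.
    control : control treatment label used for inhibition percentages.
    include_block : set False to pool over blocks (one-way ANOVA fallback).
    """

    def __init__(self, alpha: float = 0.05, control: str = "Control", include_block: bool = True):
        self.alpha = alpha
        self.control = control
        self.include_block = include_block

    def _check_balance(self, dishes: pd.DataFrame) -> None:
        cells = dishes.groupby(["treatment", "block"]).size().unstack(fill_value=0)
        missing = [(t, b) for t in cells.index for b in cells.columns if cells.loc[t, b] == 0]
        if missing:
            raise ValueError(
                "unbalanced block design, missing treatment x block cells: "
                + ", ".join(f"({t}, {b})" for t, b in missing)
                + "; use include_block=False for a one-way analysis"
            )

    def fit(self, table: pd.DataFrame):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        dishes = to_dish_means(table)
        counts = dishes.groupby("treatment").size()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError("need >= 2 treatments with >= 2 replicates each")
        data = dishes.rename(columns={"root_length_mm": "y"})
        if self.include_block:
            self._check_balance(dishes)
            model = smf.ols("y ~ C(treatment) + C(block)", data=data).fit()
        else:
            model = smf.ols("y ~ C(treatment)", data=data).fit()
        self.anova_table_ = anova_lm(model, typ=2)
        self.mse_ = float(model.mse_resid)
        self.df_resid_ = float(model.df_resid)

        means = dishes.groupby("treatment", sort=True)["root_length_mm"].mean()
        ns = counts.reindex(means.index)
        levels = list(means.index)
        k = len(levels)
        rows = []
        sig: dict[tuple[str, str], bool] = {}
        for i, a in enumerate(levels):
            for b in levels[i + 1 :]:
                se = np.sqrt(self.mse_ / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
                q = abs(means[a] - means[b]) / se
                p = float(studentized_range.sf(q, k, self.df_resid_))
                sig[(a, b)] = p < self.alpha
                rows.append((a, b, means[a] - means[b], q, p, sig[(a, b)]))
        self.pairwise_ = pd.DataFrame(
            rows, columns=["treatment_a", "treatment_b", "mean_diff", "q", "p_adj", "significant"]
        )
        self.letters_ = compact_letter_display(levels, sig)

        summary = summarize(table)
        summary["tukey_letters"] = summary["treatment"].map(self.letters_)
        if self.control in means.index:
            ctrl = means[self.control]
            summary["inhibition_pct"] = [
                inhibition_percentage(m, ctrl) for m in summary["mean"]
            ]
        self.summary_ = summary
        return self

    @property
    def f_treatment_(self) -> float:
        return float(self.anova_table_.loc["C(treatment)", "F"])

    @property
    def p_treatment_(self) -> float:
        return float(self.anova_table_.loc["C(treatment)", "PR(>F)"])


def anova_tukey_cld(
    table: pd.DataFrame,
    alpha: float = 0.05,
    control: str = "Control",
    include_block: bool = True,
) -> BlockAnovaTukey:
    """Convenience wrapper: fit the block ANOVA + Tukey letters on a tidy table."""
    return BlockAnovaTukey(alpha=alpha, control=control, include_block=include_block).fit(table)
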