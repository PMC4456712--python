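"""Factorial ANOVA over the batched SRD results.

Two-way (size class x selection) and three-way (adding pretreatment)
fixed-effect ANOVAs with all interactions, using sigma-restricted
(sum-to-zero) parameterization, quantify which design factors move the
SRD_nor response.  Fitting is delegated to statsmodels OLS; for balanced
designs the sums of squares coincide with the classical between/within
decomposition.  p-values come from the F distribution with no
multiple-testing correction; normality is not enforced — the analysis
leans on large cell counts.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["factorial_anova", "cell_means"]


def _check_cells(table: pd.DataFrame, factors: Sequence[str]) -> None:
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"factor column {f!r} not in table")
    counts = table.groupby(list(factors), observed=True).size()
    levels = [table[f].nunique() for f in factors]
    if len(counts) < int(np.prod(levels)):
        full = pd.MultiIndex.from_product(
            [sorted(table[f].unique()) for f in factors], names=factors)
        missing = full.difference(counts.index)
        raise ValueError(f"empty design cell(s): {list(missing)[:5]}")


def factorial_anova(table: pd.DataFrame, factors: Sequence[str],
                    response: str = "srd_nor") -> pd.DataFrame:
    """ANOVA table (df, sum_sq, mean_sq, F, p) for main effects and all
    interactions of the given factors.

    Factors are treated as categorical with sum-to-zero contrasts.  Raises
    if any factor-level combination has no observations.
    """
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in table")
    if not factors:
        raise ValueError("at least one factor required")
    _check_cells(table, factors)
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    model = smf.ols(f"{response} ~ {terms}", data=table).fit()
    if model.df_resid > 0 and np.isclose(model.ssr, 0.0):
        # zero residual variance: build the table directly, F undefined
        aov = sm.stats.anova_lm(model, typ=2)
    else:
        aov = sm.stats.anova_lm(model, typ=3).drop(index="Intercept")
    aov = aov.rename(columns={"PR(>F)": "p_value", "F": "F"})
    aov["mean_sq"] = aov["sum_sq"] / aov["df"]
    aov.index = [_clean_term(t) for t in aov.index]
    aov.index.name = "effect"
    return aov[["df", "sum_sq", "mean_sq", "F", "p_value"]]


def _clean_term(term: str) -> str:
    return term.replace("C(", "").replace(", Sum)", "").replace(":", " x ")


def cell_means(table: pd.DataFrame, factors: Sequence[str],
               response: str = "srd_nor", alpha: float = 0.05) -> pd.DataFrame:
    """Per-cell mean of the response with a symmetric t confidence interval.

    Balanced cells make the weighted mean equal the simple mean.  Cells with
    a single observation have no estimable interval and are flagged.
    """
    _check_cells(table, factors)
    rows = []
    for key, grp in table.groupby(list(factors), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        x = grp[response].to_numpy(dtype=float)
        n = x.size
        mean = x.mean()
        if n > 1:
            half = stats.t.ppf(1 - alpha / 2, n - 1) * x.std(ddof=1) / np.sqrt(n)
            lo, hi, flagged = mean - half, mean + half, False
        else:
            lo = hi = np.nan
            flagged = True
        rows.append(dict(zip(factors, key)) | {
            "mean": mean, "n": n, "ci_low": lo, "ci_high": hi,
            "ci_undefined": flagged,
        })
    return pd.DataFrame(rows).set_index(list(factors))
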