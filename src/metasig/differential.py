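"""Per-metabolite two-group comparison.

Group means and SDs, a two-sided two-sample test (pooled-variance Student t
by default; Welch t and Mann-Whitney U available), and the fold change
reported in the magnitude convention: the ratio of group means is given
larger-over-smaller together with a direction flag, so a 4-fold decrease
is reported as fold_change 4 with direction "down" rather than 0.25.
Benjamini-Hochberg adjusted p-values are added alongside the raw ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .matrix import MetaboliteMatrix

__all__ = ["two_group_test", "fold_change"]

_TESTS = ("student_t", "welch_t", "mann_whitney")


def _split_groups(X: MetaboliteMatrix, groups) -> tuple[str, str, np.ndarray, np.ndarray]:
    g = pd.Series(groups) if groups is not None else X.groups()
    g = g.reindex(X.sample_ids)
    if g.isna().any():
        missing = list(g.index[g.isna()])
        raise ValidationError(f"samples without a group label: {missing}")
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValidationError(f"exactly two group labels required, got {labels}")
    a, b = labels
    mask_a = (g == a).to_numpy()
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValidationError("each group needs >= 2 samples")
    return a, b, X.values[:, mask_a], X.values[:, ~mask_a]


def two_group_test(
    X: MetaboliteMatrix, groups=None, test: str = "student_t"
) -> pd.Series:
    """Two-sided per-metabolite p-values for a two-group comparison.

    ``student_t`` uses the pooled-variance t statistic; ``welch_t`` the
    unequal-variance form; ``mann_whitney`` the exact U distribution for a
    combined n <= 12 without ties, otherwise the tie-corrected normal
    approximation.  When the pooled variance of a metabolite is zero the t
    statistic is unbounded: p is 0 if the group means differ and NaN
    (degenerate, no information) if they coincide.
    """
    if test not in _TESTS:
        raise ValidationError(f"unknown test {test!r}; choose from {_TESTS}")
    _, _, A, B = _split_groups(X, groups)
    if test == "mann_whitney":
        n = A.shape[1] + B.shape[1]
        p = np.empty(X.n_metabolites)
        for i in range(X.n_metabolites):
            exact = n <= 12 and np.unique(np.r_[A[i], B[i]]).size == n
            p[i] = stats.mannwhitneyu(
                A[i], B[i], alternative="two-sided",
                method="exact" if exact else "asymptotic",
            ).pvalue
    else:
        res = stats.ttest_ind(A, B, axis=1, equal_var=(test == "student_t"))
        p = np.asarray(res.pvalue, dtype=float).copy()
        var_a = A.var(axis=1, ddof=1)
        var_b = B.var(axis=1, ddof=1)
        degenerate = (var_a == 0) & (var_b == 0)
        means_differ = A.mean(axis=1) != B.mean(axis=1)
        p[degenerate & means_differ] = 0.0
        p[degenerate & ~means_differ] = np.nan
    return pd.Series(p, index=X.metabolite_ids, name="p_value")


def fold_change(
    X: MetaboliteMatrix,
    groups=None,
    reference: str | None = None,
    test: str = "student_t",
) -> pd.DataFrame:
    """Per-metabolite differential table.

    Columns: group means and SDs (sample SD, ddof=1), ``fold_change`` (the
    ratio of group means, larger-over-smaller, >= 1), ``direction`` (up or
    down in the reference group, "unchanged" at ratio 1, "undefined" when a
    group mean is zero), raw and BH-adjusted two-sided p-values.  The
    fold change of a metabolite with a zero group mean is NaN; no epsilon
    is applied to the reported ratios.
    """
    a, b, A, B = _split_groups(X, groups)
    if reference is None:
        reference = a
    if reference not in (a, b):
        raise ValidationError(f"reference {reference!r} is not one of {[a, b]}")
    if reference != a:
        a, b, A, B = b, a, B, A

    mean_ref, mean_other = A.mean(axis=1), B.mean(axis=1)
    sd_ref = A.std(axis=1, ddof=1)
    sd_other = B.std(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        hi = np.maximum(mean_ref, mean_other)
        lo = np.minimum(mean_ref, mean_other)
        fc = np.where(lo > 0, hi / lo, np.nan)
    direction = np.where(
        (mean_ref == 0) | (mean_other == 0),
        "undefined",
        np.where(
            mean_ref > mean_other,
            f"up_in_{a}",
            np.where(mean_ref < mean_other, f"down_in_{a}", "unchanged"),
        ),
    )
    # a genuinely unchanged metabolite has a defined ratio of 1
    both_zero_free = (mean_ref > 0) & (mean_other > 0)
    p = two_group_test(X, groups, test=test).to_numpy()
    adjusted = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        adjusted[ok] = multipletests(p[ok], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            f"mean_{a}": mean_ref,
            f"sd_{a}": sd_ref,
            f"mean_{b}": mean_other,
            f"sd_{b}": sd_other,
            "fold_change": np.where(both_zero_free, fc, np.nan),
            "direction": direction,
            "p_value": p,
            "adjusted_p": adjusted,
        },
        index=pd.Index(X.metabolite_ids, name="metabolite"),
    )
    return table
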