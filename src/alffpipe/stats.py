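"""Behavioral comparisons and brain-behavior correlation with FDR control."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "pearson_r",
    "fdr_bh",
    "correlate_alff_behavior",
    "behavior_group_stats",
]

_EXACT_MAX_PAIRS = 200


def mann_whitney_u(a, b):
    """Two-sided Mann-Whitney U; exact p for small tie-free samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= _EXACT_MAX_PAIRS and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(a, b):
    """Paired alternative to the Mann-Whitney comparison."""
    res = sps.wilcoxon(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y):
    """Sample Pearson correlation with the t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def correlate_alff_behavior(
    feature_deltas: pd.DataFrame,
    behavior_deltas: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Pearson r of per-subject ALFF deltas against behavior deltas.

    Both inputs are indexed by subject (post - pre differences); every
    (region, measure) pair is tested and the whole family is FDR-corrected
    together.  The full table is returned regardless of significance.
    """
    if len(feature_deltas) != len(behavior_deltas) or \
            not feature_deltas.index.equals(behavior_deltas.index):
        raise ValueError("feature and behavior deltas must align on subjects")
    if len(feature_deltas) < 3:
        raise ValueError("need at least 3 subjects")
    rows = []
    for measure in behavior_deltas.columns:
        yv = behavior_deltas[measure].to_numpy(dtype=float)
        for region in feature_deltas.columns:
            xv = feature_deltas[region].to_numpy(dtype=float)
            r, p = pearson_r(xv, yv)
            rows.append({"region": int(region), "measure": measure,
                         "r": r, "p": p})
    table = pd.DataFrame(rows)
    reject, p_adj = fdr_bh(table["p"].to_numpy(), q=q)
    table["p_fdr"] = p_adj
    table["significant"] = reject
    return table


def behavior_group_stats(behavior: pd.DataFrame, paired: bool = False) -> pd.DataFrame:
    """Pre vs post comparison of RET accuracy, RET response time and CFMT.

    Mann-Whitney by default (as the source analyses report); a Wilcoxon
    signed-rank alternative is available with ``paired=True``.
    """
    test = wilcoxon_signed_rank if paired else mann_whitney_u
    rows = []
    for measure, pre_col, post_col in [
        ("ret", "ret_pre", "ret_post"),
        ("ret_rt", "ret_rt_pre", "ret_rt_post"),
        ("cfmt", "cfmt_pre", "cfmt_post"),
    ]:
        pre = behavior[pre_col].to_numpy(dtype=float)
        post = behavior[post_col].to_numpy(dtype=float)
        stat, p = test(pre, post)
        rows.append({
            "measure": measure,
            "pre_mean": pre.mean(), "pre_sd": pre.std(ddof=1),
            "post_mean": post.mean(), "post_sd": post.std(ddof=1),
            "statistic": stat, "p": p,
            "test": "wilcoxon" if paired else "mann-whitney",
        })
    return pd.DataFrame(rows)
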