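"""Standardized-difference balance diagnostics for multi-group matching.

For continuous covariates the standardized difference between two groups
is |m_t - m_c| / sqrt((v_t + v_c) / 2) with sample (n-1) variances; for
dichotomous covariates it is |p_t - p_c| / sqrt((p_t(1-p_t) +
p_c(1-p_c)) / 2).  With three treatment groups all pairwise comparisons
are computed and the greatest value summarizes the overall balance of a
covariate; values below 0.1 conventionally indicate negligible
imbalance.  Unlike hypothesis tests, the statistic is a property of the
sample and is unaffected by sample size, which makes it suitable for
comparing balance before and after matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matching import MatchedSample

__all__ = [
    "IMBALANCE_THRESHOLD",
    "std_diff_continuous",
    "std_diff_dichotomous",
    "max_pairwise_std_diff",
    "balance_table",
]

#: Conventional threshold below which a covariate is considered balanced.
IMBALANCE_THRESHOLD = 0.1


def std_diff_continuous(mean_t: float, mean_c: float, var_t: float, var_c: float) -> float:
    """Standardized difference of a continuous covariate between two groups."""
    if var_t < 0 or var_c < 0:
        raise ValueError("variances must be non-negative")
    if var_t + var_c == 0:
        raise ValueError("both variances are zero; standardized difference undefined")
    return abs(mean_t - mean_c) / np.sqrt((var_t + var_c) / 2.0)


def std_diff_dichotomous(p_t: float, p_c: float) -> float:
    """Standardized difference of a dichotomous covariate between two groups."""
    if not (0.0 <= p_t <= 1.0 and 0.0 <= p_c <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    denom = (p_t * (1.0 - p_t) + p_c * (1.0 - p_c)) / 2.0
    if denom == 0:
        raise ValueError("degenerate proportions; standardized difference undefined")
    return abs(p_t - p_c) / np.sqrt(denom)


def _is_dichotomous(x: np.ndarray) -> bool:
    return bool(np.isin(np.unique(x), (0, 1)).all())


def max_pairwise_std_diff(
    table: pd.DataFrame,
    covariate: str,
    group_col: str = "group",
    kind: str | None = None,
) -> float:
    """Greatest pairwise standardized difference of one covariate.

    Computes the standardized difference for every pair of treatment
    groups and returns the maximum.  The covariate is treated as
    dichotomous when its values are a subset of {0, 1}, unless ``kind``
    (``"continuous"`` or ``"dichotomous"``) overrides the detection.
    """
    x = table[covariate].to_numpy(dtype=float)
    g = table[group_col].to_numpy()
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if (g == lab).sum() < 2:
            raise ValueError(f"group {lab} has fewer than 2 subjects")
    if kind is None:
        kind = "dichotomous" if _is_dichotomous(x) else "continuous"
    best = 0.0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            xi, xj = x[g == labels[i]], x[g == labels[j]]
            if kind == "dichotomous":
                d = std_diff_dichotomous(xi.mean(), xj.mean())
            else:
                d = std_diff_continuous(
                    xi.mean(), xj.mean(), xi.var(ddof=1), xj.var(ddof=1)
                )
            best = max(best, d)
    return float(best)


def balance_table(
    pre: pd.DataFrame,
    post: MatchedSample | pd.DataFrame,
    covariates: list[str] | tuple[str, ...] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Before/after-matching balance report.

    One row per covariate with the pre- and post-matching maximum
    pairwise standardized differences and a flag marking covariates at or
    above the 0.1 imbalance threshold after matching.  ``post`` may be a
    :class:`MatchedSample` derived from ``pre`` (post statistics are then
    computed on the subjects appearing in matched sets, pooled per group)
    or a ready-made subject table.  An empty matched sample yields NaN
    post values, flagged.
    """
    if covariates is None:
        covariates = [c for c in pre.columns if c not in (group_col, "Y")]
    if isinstance(post, MatchedSample):
        matched_ids = post.matched_ids()
        post_tbl = pre.loc[matched_ids] if matched_ids.size else pre.iloc[:0]
    else:
        post_tbl = post
    rows = []
    for cov in covariates:
        sd_pre = max_pairwise_std_diff(pre, cov, group_col)
        try:
            sd_post = max_pairwise_std_diff(post_tbl, cov, group_col)
        except ValueError:
            sd_post = np.nan
        rows.append(
            {
                "covariate": cov,
                "sd_pre": sd_pre,
                "sd_post": sd_post,
                "flag_ge_0.1": bool(np.isnan(sd_post) or sd_post >= IMBALANCE_THRESHOLD),
            }
        )
    return pd.DataFrame(rows)
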