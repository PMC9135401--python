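"""Two-sided Wilcoxon rank-sum tests.

Two code paths: an exact null distribution of the rank sum (dynamic program
over subset sums, valid with ties) for small combined sample sizes, and a
tie-corrected normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.stats import norm, rankdata

EXACT_MAX_N = 21  # exact enumeration for combined sample sizes <= 20


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p-value for the rank-sum of ``x`` vs ``y``.

    Enumerates the permutation null of the group-1 rank sum via a subset-sum
    dynamic program over doubled midranks (integers even under ties).
    Two-sided: P(|S - E[S]| >= |s_obs - E[S]|) over all label assignments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks2 = np.rint(2 * rankdata(np.concatenate([x, y]))).astype(np.int64)
    s_obs = int(ranks2[:n1].sum())
    total = int(ranks2.sum())
    # center by n * E[S] = n1 * total so everything stays integer
    c_obs = abs(n * s_obs - n1 * total)

    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    max_sum = int(np.sort(ranks2)[-n1:].sum())
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for v in ranks2:
        v = int(v)
        if v > max_sum:
            continue
        # descending k so each element is used at most once
        for k in range(n1 - 1, -1, -1):
            dp[k + 1, v:] += dp[k, : max_sum + 1 - v]
    sums = np.arange(max_sum + 1, dtype=np.int64)
    centered = np.abs(n * sums - n1 * total)
    hits = dp[n1, centered >= c_obs].sum()
    return float(hits / comb(n, n1))


def _tie_term(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def approx_ranksum_p(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized normal-approximation p-values, one per row of ``values``.

    ``in_group`` is a boolean mask over columns selecting group 1.  Tie
    correction and a 0.5 continuity correction are applied.
    """
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    n = values.shape[1]
    n1 = int(in_group.sum())
    n2 = n - n1
    ranks = rankdata(values, axis=1)
    w = ranks[:, in_group].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    ties = np.array([_tie_term(row) for row in values])
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    p = np.ones(values.shape[0])
    ok = var > 0
    dev = w[ok] - mu
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2.0 * norm.sf(np.abs(z)))
    return p


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value; exact when ``len(x)+len(y) < EXACT_MAX_N``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) + len(y) < EXACT_MAX_N:
        return exact_ranksum_p(x, y)
    mask = np.zeros(len(x) + len(y), dtype=bool)
    mask[: len(x)] = True
    return float(approx_ranksum_p(np.concatenate([x, y])[None, :], mask)[0])


def ranksum_p_rows(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values with the exact/approx switch."""
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    if values.shape[1] < EXACT_MAX_N:
        out = np.empty(values.shape[0])
        for i, row in enumerate(values):
            out[i] = exact_ranksum_p(row[in_group], row[~in_group])
        return out
    return approx_ranksum_p(values, in_group)
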