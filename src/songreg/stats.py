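"""Cohort-level hypothesis tests: paired t, sign test, Pearson correlation."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["paired_t_test", "sign_test_below_median", "pearson_correlation"]


def paired_t_test(
    observed: Sequence[float], model: Sequence[float]
) -> tuple[float, int, float]:
    """Paired t-test on (model - observed) difference scores.

    Returns ``(t, df, p)`` with ``df = n - 1`` and a two-sided p-value.
    Identical vectors give ``(0, n-1, 1)``; nonzero-mean differences with
    zero variance are a degenerate case and raise.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(model, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if np.all(d == 0):
            return 0.0, df, 1.0
        raise ValueError("zero-variance nonzero differences: t is undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


def sign_test_below_median(ranks: Sequence[float], n_perm: int) -> float:
    """One-sided sign test that ranks fall below the permutation median.

    Ranks exactly at ``n_perm / 2`` are dropped; returns the binomial
    probability of at least the observed number of below-median ranks under
    a fair coin.
    """
    r = np.asarray(ranks, dtype=float)
    if len(r) < 1:
        raise ValueError("need at least one rank")
    if np.any((r < 1) | (r > n_perm)):
        raise ValueError("ranks must lie in [1, n_perm]")
    median = n_perm / 2.0
    below = int(np.sum(r < median))
    above = int(np.sum(r > median))
    n_use = below + above
    if n_use == 0:
        raise ValueError("all ranks fall exactly at the median; test undefined")
    return float(sps.binomtest(below, n_use, 0.5, alternative="greater").pvalue)


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson r with its two-sided p-value and sample size."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 points")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    res = sps.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue), n
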