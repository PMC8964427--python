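"""Shared statistical primitives.

The miRNA-sponge significance test and the over-representation (enrichment)
test are the same upper-tail hypergeometric probability; both modules call
:func:`hypergeom_upper_tail` so the two can never drift apart.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_upper_tail", "bh_qvalues", "pearson_matrix", "spearman_matrix"]


def hypergeom_upper_tail(x: int, K: int, M: int, N: int) -> float:
    """Exact P(X >= x) for X ~ Hypergeometric(population N, successes K, draws M).

    Parameters
    ----------
    x : observed overlap count.
    K : number of "success" items in the population (e.g. miRNAs sponged by
        the lncRNA, or genes annotated to a term).
    M : number of draws (e.g. miRNAs sponged by the mRNA, or study set size).
    N : population size (the miRNA or gene universe).

    Computed via scipy's log-gamma based pmf/sf, so it is exact (no normal
    approximation) and stable for large counts.
    """
    if not (0 <= K <= N and 0 <= M <= N):
        raise ValueError(f"inconsistent counts: K={K}, M={M} must lie in [0, N={N}]")
    if not (0 <= x <= min(K, M)):
        raise ValueError(f"overlap x={x} outside [0, min(K={K}, M={M})]")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, M))


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for a 1-D array of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pearson_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation between rows of `a` and rows of `b`.

    Rows are features, columns are shared samples. Zero-variance rows yield
    NaN in the corresponding entries.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("row matrices must share the sample axis")
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    ss_a = (ac**2).sum(axis=1)
    ss_b = (bc**2).sum(axis=1)
    # sqrt of the product (not product of sqrts): keeps rational correlations
    # on integer data exact, so strict threshold boundaries behave correctly
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.sqrt(np.outer(ss_a, ss_b))
    # clamp numerical overshoot; keep NaN for degenerate rows
    return np.clip(r, -1.0, 1.0, out=r)


def spearman_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Spearman rank correlation (average ranks for ties)."""
    ra = np.apply_along_axis(stats.rankdata, 1, np.asarray(a, dtype=float))
    rb = np.apply_along_axis(stats.rankdata, 1, np.asarray(b, dtype=float))
    return pearson_matrix(ra, rb)


def pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p-values for Pearson correlations at sample size `n`.

    Uses t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom; |r| = 1
    maps to p = 0 and r = 0 to p = 1.
    """
    if n < 3:
        raise ValueError("need at least 3 paired samples for a p-value")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.where(np.isnan(r), np.nan, p)
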