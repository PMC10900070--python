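"""Statistical comparisons between treatment-planning conditions.

Three tests cover the study's analyses: Fisher's exact test on the
proportions of subjects achieving 95% wall coverage, the paired Wilcoxon
signed-rank test on per-subject endpoints between conditions, and
Spearman rank correlation of required power against wall absorption and
cavity surface area.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_exact_two_sided",
    "wilcoxon_signed_rank",
    "spearman_correlation",
]


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Rows are conditions, columns achieved / not achieved. Two-sided by the
    minimum-likelihood convention: sum of hypergeometric probabilities of
    all tables (fixed margins) no more likely than the observed one. A
    zero margin carries no information; p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        warnings.warn("a margin of the 2x2 table is zero; the test is undefined (p = 1)",
                      stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (statistic, p).

    Zero differences are dropped (classic Wilcoxon convention), tied
    differences receive average ranks. The null distribution is exact for
    small tie-free samples and a tie-corrected normal approximation
    otherwise. All-zero differences carry no information; p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length (paired samples)")
    d = x - y
    nonzero = np.count_nonzero(d)
    if nonzero == 0:
        warnings.warn("all paired differences are zero; the test is undefined (p = 1)",
                      stacklevel=2)
        return 0.0, 1.0
    if nonzero < 3:
        raise ValueError("need at least 3 nonzero paired differences")
    res = sps.wilcoxon(x, y, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def spearman_correlation(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation; returns (rho, p).

    rho is the Pearson correlation of average ranks. The p-value uses an
    exact permutation null for n ≤ ``exact_max_n`` and the
    t-approximation t = rho·sqrt((n−2)/(1−rho²)) beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("Spearman correlation needs n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation is undefined for constant input")

    rho = float(sps.spearmanr(x, y).statistic)
    if n <= exact_max_n:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(_rank_corr(rx, ry))
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            if abs(_rank_corr(rx, np.asarray(perm))) >= obs - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    return rho, float(sps.spearmanr(x, y).pvalue)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    return float((rx * ry).sum()) / denom
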