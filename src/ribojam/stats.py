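"""Shared statistics: partial Spearman correlation, rank tests, hypergeometric
tail and Benjamini–Hochberg FDR.

Partial Spearman correlation is computed by rank-transforming every variable
(midranks for ties) and taking the partial Pearson correlation of the ranks
given the controls via the inverse correlation matrix; the residualization
route (regress ranks on controls, correlate residuals) is algebraically
identical and is used as the cross-check in the test-suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "partial_spearman",
    "rank_sum",
    "sign_rank",
    "hypergeom_tail",
    "bh_fdr",
]


def partial_spearman(
    x: np.ndarray, y: np.ndarray, controls: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given control variables.

    ``controls`` is an (n, k) matrix (or None / empty for the plain Spearman
    correlation).  The p-value is the asymptotic t approximation with
    df = n - k - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(controls, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    n = len(x)
    k = Z.shape[1]
    if len(y) != n or Z.shape[0] != n:
        raise ValueError("x, y and controls must have equal length")
    if n <= k + 2:
        raise ValueError(f"need n > #controls + 2 (n={n}, k={k})")

    data = np.column_stack([x, y, Z])
    ranks = np.apply_along_axis(sps.rankdata, 0, data)
    sd = ranks.std(axis=0)
    if np.any(sd[:2] == 0):
        raise ValueError("x or y is constant")
    if np.any(sd[2:] == 0):
        raise ValueError("constant control variable")
    C = np.corrcoef(ranks, rowvar=False)
    try:
        P = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        raise ValueError("singular control matrix (collinear controls)") from None
    rho = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - k - 2
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return rho, float(p)


def rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def sign_rank(paired_diff) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired differences."""
    d = np.asarray(paired_diff, dtype=float)
    if d.size == 0:
        raise ValueError("empty sample")
    if np.all(d == 0):
        return 1.0
    return float(sps.wilcoxon(d).pvalue)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) drawing n from a universe of N with K successes."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("invalid hypergeometric parameters")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    return multipletests(p, method="fdr_bh")[1]
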