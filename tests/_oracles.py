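"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: plain dynamic programming
and textbook formulas only.
"""

from __future__ import annotations

import numpy as np


def dp_semiglobal(pattern: str, text: str) -> int:
    """Full DP table semi-global edit distance (pattern consumed, free text ends)."""
    m, n = len(pattern), len(text)
    D = np.zeros((m + 1, n + 1), dtype=int)
    D[:, 0] = np.arange(m + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            D[i, j] = min(
                D[i - 1, j] + 1,
                D[i, j - 1] + 1,
                D[i - 1, j - 1] + (pattern[i - 1] != text[j - 1]),
            )
    return int(D[m].min())


def dp_global(a: str, b: str) -> int:
    """Full DP table end-to-end Levenshtein distance."""
    m, n = len(a), len(b)
    D = np.zeros((m + 1, n + 1), dtype=int)
    D[:, 0] = np.arange(m + 1)
    D[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            D[i, j] = min(
                D[i - 1, j] + 1,
                D[i, j - 1] + 1,
                D[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(D[m, n])


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Naive Benjamini-Hochberg adjusted p-values (step-up, with monotonicity)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end  # 1-based rank of this p-value
        val = min(prev, p[idx] * n / rank)
        q[idx] = val
        prev = val
    return q


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form OLS slope: cov(x, y) / var(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))


def exact_binom_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper-Pearson interval via the beta distribution."""
    from scipy import stats

    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
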