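"""Rank-sum and t statistics used throughout the assays.

The Mann-Whitney U test uses midrank tie handling, an exact null
distribution (count recurrence) for small untied samples, and a normal
approximation with tie and continuity corrections otherwise.  The unpaired
t-test defaults to the Welch (unequal-variance) form.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = ["mann_whitney", "unpaired_t_test"]


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank arrangements of n vs m observations giving each U value.

    Classic recurrence: f(u; n, m) = f(u - m; n - 1, m) + f(u; n, m - 1),
    equivalent to the Gaussian-binomial expansion, so min(n, m) <= 8 stays
    cheap even when the other sample is large.
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)
    b = _u_counts(n, m - 1)
    size = n * m + 1
    out = [0] * size
    for u in range(size):
        if u - m >= 0 and u - m < len(a):
            out[u] += a[u - m]
        if u < len(b):
            out[u] += b[u]
    return tuple(out)


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U (Wilcoxon rank-sum) test.

    Returns ``(U_A, p)``.  Exact p by the count distribution when
    min(n, m) <= 8 and there are no ties; otherwise the normal approximation
    with midrank tie correction and a 0.5 continuity correction.  Samples
    with zero rank variance (all values identical) give p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    r_a = float(ranks[:n].sum())
    u_a = r_a - n * (n + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and min(n, m) <= 8:
        counts = _u_counts(n, m)
        total = sum(counts)
        u_small = int(round(min(u_a, n * m - u_a)))
        p = min(1.0, 2.0 * sum(counts[: u_small + 1]) / total)
        return u_a, p

    mean_u = n * m / 2.0
    nm_tot = n + m
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (nm_tot * (nm_tot - 1)) \
        if nm_tot > 1 else 0.0
    var_u = n * m / 12.0 * ((nm_tot + 1) - tie_term)
    if var_u <= 0:
        return u_a, 1.0
    z = (abs(u_a - mean_u) - 0.5) / np.sqrt(var_u)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return u_a, p


def unpaired_t_test(sample_a, sample_b, equal_var: bool = False) -> tuple[float, float]:
    """Two-tailed unpaired t-test, Welch form by default.

    Returns ``(t, p)``; identical samples give t = 0, p = 1, and swapping
    the samples flips the sign of t.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    n, m = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if equal_var:
        sp2 = ((n - 1) * va + (m - 1) * vb) / (n + m - 2)
        se2 = sp2 * (1.0 / n + 1.0 / m)
        dof = n + m - 2
    else:
        se2 = va / n + vb / m
        dof = se2 ** 2 / ((va / n) ** 2 / (n - 1) + (vb / m) ** 2 / (m - 1)) \
            if se2 > 0 else n + m - 2
    if se2 <= 0:
        return 0.0, 1.0
    t = diff / np.sqrt(se2)
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), dof)))
    return float(t), p
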