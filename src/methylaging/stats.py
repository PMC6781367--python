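"""Statistical primitives shared across the pipeline.

The two-sided Fisher exact test and the Benjamini-Hochberg adjustment are
implemented here from first principles because their exact definitions are
part of the analysis contract:

* ``fisher_exact_two_sided`` sums the probabilities of all 2x2 tables with
  the observed margins whose probability is <= the observed table's.  The
  enumeration uses exact integer binomial weights, so ties are decided by
  integer comparison rather than a floating-point epsilon.
* ``bh_adjust`` is the standard step-up procedure
  ``q_(i) = min(1, min_{j>=i} p_(j) * m / j)`` over the sorted p-values.

Hypergeometric tail probabilities and the Kruskal-Wallis test are delegated
to scipy.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats as sps


def fisher_exact_two_sided(m_a: int, u_a: int, m_b: int, u_b: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[m_a, u_a], [m_b, u_b]].

    Defined as the sum of hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed table.
    Computed with exact integer arithmetic; the only rounding is the final
    big-integer division to a float.
    """
    for value in (m_a, u_a, m_b, u_b):
        if value < 0:
            raise ValueError("cell counts must be >= 0")
    r1, r2 = m_a + u_a, m_b + u_b
    c1 = m_a + m_b
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table is possible
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[m_a - lo]
    numerator = sum(w for w in weights if w <= w_obs)
    return numerator / comb(n, c1)


def fisher_exact_many(tables: np.ndarray) -> np.ndarray:
    """Vector of two-sided Fisher exact p-values for an (n, 4) array of
    tables given as rows (m_a, u_a, m_b, u_b)."""
    tables = np.asarray(tables)
    return np.array(
        [fisher_exact_two_sided(*(int(v) for v in row)) for row in tables], dtype=float
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries (untested hypotheses) are passed through unchanged and do
    not count toward the family size.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    values = p[mask]
    m = values.size
    if m == 0:
        return q
    if ((values < 0) | (values > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(values, kind="mergesort")
    ranked = values[order] * m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    q[mask] = out
    return q


def hypergeom_tails(
    k: np.ndarray | int, N: np.ndarray | int, K: np.ndarray | int, n: np.ndarray | int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact hypergeometric tail probabilities for drawing ``k`` marked items
    in ``n`` draws from a universe of ``N`` items of which ``K`` are marked.

    Returns ``(p_over, p_under)`` where ``p_over = P(X >= k)`` and
    ``p_under = P(X <= k)``.
    """
    k = np.asarray(k)
    p_over = sps.hypergeom.sf(k - 1, np.asarray(N), np.asarray(K), np.asarray(n))
    p_under = sps.hypergeom.cdf(k, np.asarray(N), np.asarray(K), np.asarray(n))
    return p_over, p_under


def conover_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Conover-Iman rank comparison of two groups.

    The samples are ranked jointly (average ranks on ties); the statistic is
    the difference in mean ranks scaled by the pooled rank variance with the
    Kruskal-Wallis tie/statistic correction, referred to a t distribution
    with N - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = _conover_matrix(x[None, :], y[None, :])
    return float(t[0]), float(p[0])


def _conover_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Conover-Iman comparison over rows of ``x`` (g x n1) vs
    ``y`` (g x n2).  Rows with zero rank variance get p = 1."""
    n1, n2 = x.shape[1], y.shape[1]
    N = n1 + n2
    combined = np.concatenate([x, y], axis=1)
    ranks = sps.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].mean(axis=1)
    r2 = ranks[:, n1:].mean(axis=1)
    s2 = (np.sum(ranks**2, axis=1) - N * ((N + 1) / 2) ** 2) / (N - 1)
    # Kruskal-Wallis H with tie correction folded in through the rank sums
    with np.errstate(invalid="ignore", divide="ignore"):
        h = (n1 * (r1 - (N + 1) / 2) ** 2 + n2 * (r2 - (N + 1) / 2) ** 2) / s2
        denom2 = s2 * ((N - 1 - h) / (N - 2)) * (1 / n1 + 1 / n2)
        t = (r1 - r2) / np.sqrt(np.maximum(denom2, 0.0))
    t = np.where(s2 <= 0, 0.0, t)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df=N - 2)
    p = np.where(s2 <= 0, 1.0, np.minimum(p, 1.0))
    return t, p


def welch_t_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test of ``x`` (g x n1) vs ``y`` (g x n2); the
    t-statistic alternative to the rank-based contrast."""
    res = sps.ttest_ind(x, y, axis=1, equal_var=False)
    t = np.where(np.isfinite(res.statistic), res.statistic, 0.0)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    return t, p


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p; (nan, nan) if either input is
    constant or fewer than 3 pairs are available."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_groups(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H and p across >= 2 non-empty groups."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        return float("nan"), float("nan")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all values identical
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def derive_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from a global seed."""
    import hashlib

    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
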