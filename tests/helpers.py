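"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own code paths: plain-Python EM,
definitional BH step-up, and normal-equation OLS, so agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_em(
    candidate_sets: list[frozenset[str]],
    te_ids: list[str],
    lengths: dict[str, int],
    read_length: int,
    n_iter: int = 10_000,
) -> dict[str, float]:
    """Plain-Python EM, fixed iteration count, no vectorization."""
    assigned = [s for s in candidate_sets if s]
    n = len(assigned)
    efflen = {t: max(lengths[t] - read_length + 1, 1) for t in te_ids}
    alpha = {t: n / len(te_ids) for t in te_ids}
    for _ in range(n_iter):
        new = {t: 0.0 for t in te_ids}
        for s in assigned:
            weights = {t: alpha[t] / efflen[t] for t in s}
            total = sum(weights.values())
            for t in s:
                new[t] += weights[t] / total
        alpha = new
    return alpha


def brute_bh(p_values: np.ndarray) -> np.ndarray:
    """BH step-up straight from the definition, O(m^2)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [
            m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]
        ]
        q[i] = min(min(candidates), 1.0)
    return q


def ols_normal_equations(X: np.ndarray, y: np.ndarray, term: int = 1):
    """OLS via explicit normal equations; returns (beta, se, t, p) for term."""
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[term, term])
    t = coef[term] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return float(coef[term]), float(se), float(t), float(p)


def anova_via_indicator_regression(groups: dict[str, np.ndarray]):
    """One-way ANOVA F by comparing full (group indicators) vs null model."""
    names = list(groups)
    y = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    n = y.size
    X = np.column_stack(
        [np.ones(n)]
        + [
            np.concatenate(
                [np.full(len(groups[g]), 1.0 if g == name else 0.0) for g in names]
            )
            for name in names[1:]
        ]
    )
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    rss_full = float(((y - X @ beta) ** 2).sum())
    rss_null = float(((y - y.mean()) ** 2).sum())
    df1 = len(names) - 1
    df2 = n - len(names)
    F = ((rss_null - rss_full) / df1) / (rss_full / df2)
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


def random_em_instance(rng: np.random.Generator):
    """Random small EM instance: <= 3 TEs, <= 50 reads, assorted lengths."""
    n_te = int(rng.integers(1, 4))
    te_ids = [f"T{i}" for i in range(n_te)]
    lengths = {t: int(rng.integers(150, 500)) for t in te_ids}
    n_reads = int(rng.integers(1, 51))
    sets = []
    for _ in range(n_reads):
        size = int(rng.integers(1, n_te + 1))
        sets.append(frozenset(rng.choice(te_ids, size=size, replace=False)))
    return te_ids, lengths, sets
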