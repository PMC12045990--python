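"""Closed-form statistical tests used across the analysis modules.

The comparisons the analyses need — pooled-variance two-sample t, one-way
ANOVA F, the paired (matched) t, and the Mann-Whitney rank-sum U — are
implemented directly from their textbook closed forms so each module's
statistics are self-contained and auditable.  Tail probabilities come from
the corresponding reference distributions in :mod:`scipy.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "pooled_t_test",
    "one_way_anova",
    "paired_t_test",
    "mann_whitney_u",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test: the statistic, its p-value and context."""

    statistic: float
    p_value: float
    df: float | None = None
    method: str = ""
    n: tuple[int, ...] = ()


def _as1d(x: Sequence[float]) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty sample")
    return a


def pooled_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed independent two-sample t test with pooled variance.

    t = (mean_a - mean_b) / sqrt(s_p^2 (1/n_a + 1/n_b)) with
    s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2).
    """
    a, b = _as1d(a), _as1d(b)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    denom = sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if denom == 0.0:
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    else:
        t = (a.mean() - b.mean()) / denom
    p = float(2.0 * _sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TestResult(float(t), p, df=float(df), method="pooled t", n=(na, nb))


def one_way_anova(*groups: Sequence[float]) -> TestResult:
    """One-way fixed-effects ANOVA F statistic over >= 2 groups.

    F = MS_between / MS_within from the usual sum-of-squares decomposition.
    """
    gs = [_as1d(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs at least 2 observations")
    k = len(gs)
    ns = np.array([g.size for g in gs])
    n_tot = int(ns.sum())
    grand = np.concatenate(gs).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, gs)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_b, df_w = k - 1, n_tot - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f = 0.0 if ms_b == 0.0 else np.inf
    else:
        f = ms_b / ms_w
    p = float(_sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return TestResult(float(f), p, df=float(df_b), method="one-way ANOVA",
                      n=tuple(int(n) for n in ns))


def paired_t_test(diffs: Sequence[float]) -> TestResult:
    """Matched-pairs t test of the differences against zero.

    t = mean(d) / (sd(d) / sqrt(n)), df = n - 1.
    """
    d = _as1d(diffs)
    n = d.size
    if n < 2:
        raise ValueError("paired t needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if d.mean() == 0.0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / sqrt(n))
    p = float(2.0 * _sps.t.sf(abs(t), n - 1)) if np.isfinite(t) else 0.0
    return TestResult(float(t), p, df=float(n - 1), method="paired t", n=(n,))


def _rank_with_ties(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of the pooled sample plus the tie-group sizes."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    tie_sizes = []
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        tie_sizes.append(j - i + 1)
        i = j + 1
    return ranks, np.array(tie_sizes)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks, _ = _rank_with_ties(np.concatenate([a, b]))
    r1 = ranks[: a.size].sum()
    return float(r1 - a.size * (a.size + 1) / 2.0)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by full enumeration of group assignments.

    Enumerates every way of labelling the pooled observations, computing the
    permutation distribution of U (ties included); two-sided p is the
    probability of a U at least as far from n1*n2/2 as observed.
    """
    pooled = np.concatenate([a, b])
    n1, n = a.size, pooled.size
    ranks, _ = _rank_with_ties(pooled)
    mu = a.size * b.size / 2.0
    dev_obs = abs(u_obs - mu)
    hits = 0
    total = comb(n, n1)
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return min(1.0, hits / total)


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   exact: bool | None = None) -> TestResult:
    """Two-sided Mann-Whitney U (rank-sum) test.

    U = R1 - n1(n1+1)/2 with midranks for ties.  When the combined sample
    size is <= 20 (or ``exact=True``) the p-value comes from full
    enumeration of the permutation distribution; otherwise the normal
    approximation with the tie-corrected variance

        var(U) = n1 n2 / 12 * [(n + 1) - sum(t^3 - t) / (n (n - 1))]

    and a 0.5 continuity correction is used.
    """
    a, b = _as1d(a), _as1d(b)
    n1, n2 = a.size, b.size
    n = n1 + n2
    u = _u_statistic(a, b)
    if exact is None:
        exact = n <= 20
    if exact:
        p = _exact_two_sided_p(a, b, u)
        return TestResult(u, p, method="Mann-Whitney U (exact)", n=(n1, n2))
    _, ties = _rank_with_ties(np.concatenate([a, b]))
    mu = n1 * n2 / 2.0
    tie_term = float(((ties ** 3) - ties).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, method="Mann-Whitney U (normal approx)",
                          n=(n1, n2))
    z = (abs(u - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    p = float(2.0 * _sps.norm.sf(z))
    return TestResult(u, min(1.0, p), method="Mann-Whitney U (normal approx)",
                      n=(n1, n2))
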