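"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's vectorized implementations:
coverage-quorum subsampling is evaluated by exact expectation over all
draw orders, the forcing discretization by a literal double-loop sum,
and rarefaction via the hypergeometric distribution from scipy.
"""

from functools import lru_cache

import numpy as np
from scipy import stats


def exact_sqs_mean(counts: dict, q: float,
                   goods_u_correction: bool = False,
                   exclude_dominant: bool = False) -> float:
    """Exact expected quorum-subsampled richness by enumerating draw
    orders of the occurrence multiset (occurrence unit)."""
    names = sorted(counts)
    n = np.array([counts[g] for g in names], dtype=int)
    total = int(n.sum())
    shares = n / total
    if goods_u_correction:
        u = 1.0 - np.count_nonzero(n == 1) / total
        shares = shares * u
    if exclude_dominant and len(n) > 1:
        shares = shares.copy()
        shares[int(np.argmax(n))] = 0.0
    share_t = tuple(shares)
    tol = 1e-12

    @lru_cache(maxsize=None)
    def expect(remaining: tuple, seen: int) -> float:
        rem_total = sum(remaining)
        out = 0.0
        for g, r in enumerate(remaining):
            if r == 0:
                continue
            p = r / rem_total
            if seen & (1 << g):
                nxt = list(remaining)
                nxt[g] -= 1
                out += p * expect(tuple(nxt), seen)
                continue
            new_seen = seen | (1 << g)
            cov = sum(share_t[i] for i in range(len(share_t))
                      if new_seen & (1 << i))
            k = bin(new_seen).count("1")
            if cov >= q - tol:
                out += p * k
            else:
                nxt = list(remaining)
                nxt[g] -= 1
                out += p * expect(tuple(nxt), new_seen)
        return out

    attainable = float(shares.sum())
    if q > attainable + tol:
        return float(len(n))
    return expect(tuple(n), 0)


def rarefaction_expectation(counts: dict, n_sub: int) -> float:
    """E[richness] at subsample size n via scipy's hypergeometric pmf."""
    sizes = np.array(list(counts.values()), dtype=int)
    total = int(sizes.sum())
    if n_sub >= total:
        return float(len(sizes))
    p_absent = [stats.hypergeom.pmf(0, total, s, n_sub) for s in sizes]
    return float(np.sum(1.0 - np.array(p_absent)))


def rarefaction_mean_var(counts: dict, n_sub: int) -> tuple:
    """Exact mean and variance of rarefied richness from inclusion-
    exclusion over pairwise genus absences (hypergeometric)."""
    sizes = np.array(list(counts.values()), dtype=int)
    total = int(sizes.sum())
    if n_sub >= total:
        return float(len(sizes)), 0.0
    p = np.array([stats.hypergeom.pmf(0, total, s, n_sub) for s in sizes])
    mean = float(np.sum(1.0 - p))
    var = float(np.sum(p * (1.0 - p)))
    for i in range(len(sizes)):
        for j in range(len(sizes)):
            if i == j:
                continue
            rest = total - sizes[i] - sizes[j]
            pij = stats.hypergeom.pmf(0, total, sizes[i] + sizes[j], n_sub) \
                if rest >= 0 else 0.0
            var += float(pij) - float(p[i] * p[j])
    return mean, max(var, 0.0)


def forcing_direct_sum(ages: np.ndarray, sn: np.ndarray, lam: float,
                       grid_step: float = 1.0, c: float = 1.0
                       ) -> np.ndarray:
    """Literal double-loop evaluation of the kernel-normalized trapezoid
    discretization of the exponential-memory forcing, with constant
    padding beyond the oldest point plus the analytic tail."""
    h = grid_step
    n = len(ages)
    n_pad = int(np.ceil(10.0 * lam / h))
    m = n + n_pad
    ext_ages = ages[0] + h * np.arange(m)
    ext_sn = np.concatenate([sn, np.full(n_pad, sn[-1])])
    gamma = np.empty(n)
    for i in range(n):
        num = 0.0
        den = 0.0
        for j in range(i, m):
            k = np.exp(-(ext_ages[j] - ext_ages[i]) / lam)
            w = h
            if j == i:
                w = h / 2.0
            elif j == m - 1:
                w = h / 2.0
            num += w * k * ext_sn[j]
            den += w * k
        tail_k = lam * np.exp(-(ext_ages[-1] - ext_ages[i]) / lam)
        num += tail_k * ext_sn[-1]
        den += tail_k
        gamma[i] = c * lam * num / den
    return gamma
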