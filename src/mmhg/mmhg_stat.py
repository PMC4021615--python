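"""The mmHG score of a permutation and its exact/empirical p-values.

Two rankings of the same N elements are reduced to a single relative
permutation pi = pi2 o pi1^{-1}; mutual enrichment at the top of the two
lists is then the minimum hypergeometric tail over all cutoff pairs:

    mmHG(pi) = min_{1<=n1,n2<=N} HGT(N, n1, n2, b_pi(n1, n2))

with b_pi(n1, n2) the intersection size of {1..n1} with {pi(1)..pi(n2)}.
The score itself is not a significance level (it scans N^2 cutoff pairs);
the p-value is the fraction of uniformly random permutations attaining a
score at least as small, computed exactly for small N by enumeration and
empirically by sampling otherwise.

Permutations are represented as integer numpy arrays holding the values
pi(1)..pi(N); values are 1-based (position i of the array is pi(i+1)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .hypergeom import _logfact, hgt_tail, log_slack

__all__ = [
    "MmhgResult",
    "as_permutation",
    "relative_permutation",
    "permutation_from_rankings",
    "intersection_counts",
    "mmhg_score",
    "mhg_score",
    "exact_pvalue",
    "empirical_pvalue",
    "enumerate_scores",
]

#: ceiling for exhaustive enumeration of S_N (10! ~ 3.6e6 permutations)
EXACT_ENUMERATION_MAX_N = 10

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class MmhgResult:
    """An mmHG score with its minimizing cell (1-based n1*, n2*, b*)."""

    log_score: float
    n1_star: int
    n2_star: int
    b_star: int

    @property
    def score(self) -> float:
        return float(np.exp(self.log_score))


def as_permutation(values) -> np.ndarray:
    """Validate and return a 1-based permutation as an int64 array."""
    pi = np.asarray(values, dtype=np.int64)
    if pi.ndim != 1 or pi.size < 1:
        raise ValueError("permutation must be a non-empty 1-D sequence")
    if not np.array_equal(np.sort(pi), np.arange(1, pi.size + 1)):
        raise ValueError("values are not a bijection on {1..N}")
    return pi


def relative_permutation(pi1, pi2) -> np.ndarray:
    """pi = pi2 o pi1^{-1}, i.e. pi[pi1(j)] = pi2(j) for every j."""
    p1 = as_permutation(pi1)
    p2 = as_permutation(pi2)
    if p1.size != p2.size:
        raise ValueError("permutations must have the same length")
    out = np.empty(p1.size, dtype=np.int64)
    out[p1 - 1] = p2
    return out


def permutation_from_rankings(l1_ids, l2_ids) -> np.ndarray:
    """Relative permutation of ranking L2 w.r.t. ranking L1.

    Both arguments are ordered identifier sequences (best first) over the
    same identifier set.  Entry i of the result is the 1-based position in
    L2 of the element at position i in L1.
    """
    l1 = list(l1_ids)
    l2 = list(l2_ids)
    if len(set(l1)) != len(l1) or len(set(l2)) != len(l2):
        raise ValueError("identifiers within a ranking must be unique")
    if set(l1) != set(l2):
        raise ValueError("the two rankings must cover the same identifiers")
    pos2 = {ident: i + 1 for i, ident in enumerate(l2)}
    return np.array([pos2[ident] for ident in l1], dtype=np.int64)


def intersection_counts(pi) -> np.ndarray:
    """Table b[n1, n2] = |{1..n1} intersect {pi(1)..pi(n2)}| (1-based cells).

    Returned as an (N+1, N+1) int array with row/column 0 equal to 0, so
    ``b[n1, n2]`` addresses the cell directly.  Built incrementally: each
    prefix extension updates one cumulative count.
    """
    p = as_permutation(pi)
    N = p.size
    hit = np.zeros((N + 1, N + 1), dtype=np.int64)
    hit[p, np.arange(1, N + 1)] = 1  # element pi(j)=v enters at column j
    np.cumsum(hit, axis=0, out=hit)
    np.cumsum(hit, axis=1, out=hit)
    return hit


def _lpmf_grid(N: int, b: np.ndarray) -> np.ndarray:
    """Pointwise log pmf at every (n1, n2) cell of an intersection table."""
    lf = _logfact(N)
    n1 = np.arange(1, N + 1)[:, None]
    n2 = np.arange(1, N + 1)[None, :]
    bb = b[1:, 1:]
    return (
        lf[n1] - lf[bb] - lf[n1 - bb]
        + lf[N - n1] - lf[n2 - bb] - lf[N - n1 - (n2 - bb)]
        - (lf[N] - lf[n2] - lf[N - n2])
    )


def mmhg_score(pi) -> MmhgResult:
    """Minimum hypergeometric tail over all (n1, n2) cutoff pairs.

    Ties are broken by the smallest n1, then the smallest n2.  Exact tails
    are evaluated only at cells whose pointwise pmf can still beat the
    running minimum (the tail dominates its own pmf), which keeps the scan
    near O(N^2) in practice.
    """
    p = as_permutation(pi)
    N = p.size
    b = intersection_counts(p)
    lpmf = _lpmf_grid(N, b)
    flat = lpmf.ravel()
    order = np.argsort(flat, kind="stable")
    best = np.inf
    evaluated: list[tuple[float, int, int, int]] = []
    for idx in order:
        lp = flat[idx]
        if lp > best + log_slack(best if np.isfinite(best) else lp):
            break
        n1 = idx // N + 1
        n2 = idx % N + 1
        bb = int(b[n1, n2])
        lt = hgt_tail(N, n1, n2, bb)
        evaluated.append((lt, n1, n2, bb))
        if lt < best:
            best = lt
    eps = log_slack(best)
    ties = [c for c in evaluated if c[0] <= best + eps]
    lt, n1, n2, bb = min(ties, key=lambda c: (c[1], c[2]))
    return MmhgResult(log_score=lt, n1_star=n1, n2_star=n2, b_star=bb)


def _mhg_row_python(lam, K, N):
    """Reference per-row mHG scan (used when numba is unavailable)."""
    import math

    if K == 0 or K == N:
        return 0.0, 1
    pmf = 1.0
    offset = 0.0
    b = 0
    best = 0.0
    bn = 1
    for n in range(N):
        rem = float(N - n)
        if lam[n]:
            pmf = pmf * ((K - b) / (b + 1.0)) * ((n + 1.0) / rem)
            b += 1
        else:
            pmf = pmf * ((N - K - n + b) / (n + 1.0 - b)) * ((n + 1.0) / rem)
        if pmf < 1e-250:
            pmf *= 1e250
            offset -= math.log(1e250)
        nc = n + 1
        if b <= max(0, nc - (N - K)):
            continue  # tail is exactly 1 at the valid floor
        lp = math.log(pmf) + offset
        if lp > best:
            continue  # tail >= pmf cannot beat the running minimum
        q = 1.0
        term = 1.0
        bb = b
        hi = min(K, nc)
        while bb < hi:
            term *= ((K - bb) * (nc - bb)) / ((bb + 1.0) * (N - K - nc + bb + 1.0))
            q += term
            if term < 1e-15 * q:
                break
            bb += 1
        tl = lp + math.log(q)
        slack = 1e-9 * max(1.0, abs(best))
        if tl < best - slack:
            bn = nc
        if tl < best:
            best = tl
    return best, bn


def _mhg_path_python(B, ones):
    scores = np.zeros(B.shape[0])
    cutoffs = np.ones(B.shape[0], dtype=np.int64)
    for row in range(B.shape[0]):
        s, n = _mhg_row_python(B[row], int(ones[row]), B.shape[1])
        scores[row] = s
        cutoffs[row] = n
    return scores, cutoffs


try:  # numba accelerates the per-row scan; the python path is equivalent
    from numba import njit

    @njit(cache=False)
    def _mhg_path_kernel(B, ones, scores, cutoffs):  # pragma: no cover
        m, N = B.shape
        for row in range(m):
            Ki = ones[row]
            if Ki == 0 or Ki == N:
                scores[row] = 0.0
                cutoffs[row] = 1
                continue
            K = float(Ki)
            pmf = 1.0
            offset = 0.0
            b = 0
            best = 0.0
            bn = 1
            for n in range(N):
                rem = float(N - n)
                if B[row, n]:
                    pmf = pmf * ((K - b) / (b + 1.0)) * ((n + 1.0) / rem)
                    b += 1
                else:
                    pmf = pmf * ((N - K - n + b) / (n + 1.0 - b)) \
                        * ((n + 1.0) / rem)
                if pmf < 1e-250:
                    pmf *= 1e250
                    offset -= np.log(1e250)
                nc = n + 1
                floor = nc - (N - Ki)
                if floor < 0:
                    floor = 0
                if b <= floor:
                    continue  # tail is exactly 1 at the valid floor
                lp = np.log(pmf) + offset
                if lp > best:
                    continue  # tail >= pmf cannot beat the running minimum
                q = 1.0
                term = 1.0
                bb = float(b)
                hi = float(min(Ki, nc))
                while bb < hi:
                    term *= ((K - bb) * (nc - bb)) \
                        / ((bb + 1.0) * (N - K - nc + bb + 1.0))
                    q += term
                    if term < 1e-15 * q:
                        break
                    bb += 1.0
                tl = lp + np.log(q)
                slack = 1e-9 * max(1.0, abs(best))
                if tl < best - slack:
                    bn = nc
                if tl < best:
                    best = tl
            scores[row] = best
            cutoffs[row] = bn

    def _mhg_path(B: np.ndarray, ones: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
        scores = np.zeros(B.shape[0])
        cutoffs = np.ones(B.shape[0], dtype=np.int64)
        _mhg_path_kernel(B, ones, scores, cutoffs)
        return scores, cutoffs

except ImportError:  # pragma: no cover
    _mhg_path = _mhg_path_python


def _mhg_batch(memberships: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """mHG scores (log) and minimizing cutoffs for rows of a 0/1 matrix.

    Each row is a binary membership vector over the ranked universe; the
    row's mHG is min_n HGT(N, ones, n, b_n) with b_n the prefix count.
    Tails along the path are maintained incrementally in O(1) per step
    via the one-draw identities

        P(X_{n+1} >= b+1) = (P(X_n >= b) - P(X_n = b))
                            + P(X_n = b) (K-b)/(N-n)        (hit)
        P(X_{n+1} >= b)   = P(X_n >= b)
                            + P(X_n = b-1) (K-b+1)/(N-n)    (miss)

    on the linear scale with periodic rescaling (values below ~1e-250 are
    shifted into a log offset).  Ties go to the smallest cutoff n.
    """
    B = np.asarray(memberships, dtype=bool)
    if B.ndim == 1:
        B = B[None, :]
    ones = B.sum(axis=1).astype(np.int64)
    return _mhg_path(np.ascontiguousarray(B, dtype=np.uint8), ones)


def mhg_score(bits) -> tuple[float, int]:
    """mHG of one binary membership vector: (log score, minimizing n)."""
    v = np.asarray(bits)
    if not np.isin(v, (0, 1)).all():
        raise ValueError("membership vector must be 0/1")
    s, n = _mhg_batch(v.astype(bool))
    return float(s[0]), int(n[0])


# ---------------------------------------------------------------------------
# exact / empirical p-values
# ---------------------------------------------------------------------------

def _scores_for_perm_block(perms: np.ndarray, T: np.ndarray) -> np.ndarray:
    """mmHG log scores for a block of permutations (values 1..N per row).

    ``T[n1-1, n2-1, b]`` must hold ln HGT(N, n1, n2, b) for the given N.
    """
    m, N = perms.shape
    hit = np.zeros((m, N + 1, N), dtype=np.int32)
    rows = np.repeat(np.arange(m), N)
    hit[rows, perms.ravel(), np.tile(np.arange(N), m)] = 1
    np.cumsum(hit, axis=1, out=hit)
    np.cumsum(hit, axis=2, out=hit)
    b = hit[:, 1:, :]  # b[:, n1-1, n2-1]
    n1 = np.arange(N)[None, :, None]
    n2 = np.arange(N)[None, None, :]
    tails = T[n1, n2, b]
    return tails.reshape(m, -1).min(axis=1)


def _full_tail_table(N: int) -> np.ndarray:
    from .hypergeom import tail_grid

    T = np.empty((N, N, N + 1))
    for n1 in range(1, N + 1):
        G, _ = tail_grid(N, n1)
        T[n1 - 1] = G[1:, :]
    return T


@lru_cache(maxsize=4)
def enumerate_scores(N: int) -> np.ndarray:
    """Sorted mmHG log scores of every permutation in S_N (N <= 10)."""
    if N > EXACT_ENUMERATION_MAX_N:
        raise ValueError(
            f"exhaustive enumeration supported only for N <= "
            f"{EXACT_ENUMERATION_MAX_N} (got {N}); use empirical_pvalue"
        )
    T = _full_tail_table(N)
    out = []
    it = itertools.permutations(range(1, N + 1))
    while True:
        block = np.array(list(itertools.islice(it, 120_000)), dtype=np.int64)
        if block.size == 0:
            break
        out.append(_scores_for_perm_block(block, T))
    return np.sort(np.concatenate(out))


def exact_pvalue(score: float, N: int) -> float:
    """P(mmHG(pi) <= score) over uniform pi in S_N, by full enumeration.

    ``score`` is on the linear probability scale; the comparison uses the
    same log-space slack as every other "<= s" test in the package.
    """
    if not 0 < score <= 1:
        raise ValueError("score must be a probability in (0, 1]")
    scores = enumerate_scores(N)
    log_s = float(np.log(score))
    thresh = log_s + log_slack(log_s)
    count = int(np.searchsorted(scores, thresh, side="right"))
    return count / scores.size


def empirical_pvalue(
    score: float, N: int, n_samples: int, seed: int
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo mmHG p-value with a normal-approximation 95% CI.

    Samples ``n_samples`` uniform permutations (Fisher-Yates via the seeded
    generator) and returns the fraction scoring at or below ``score``,
    with the binomial CI ``phat +- 1.96 sqrt(phat(1-phat)/n)``.
    """
    if not 0 < score <= 1:
        raise ValueError("score must be a probability in (0, 1]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    log_s = float(np.log(score))
    thresh = log_s + log_slack(log_s)
    hits = 0
    if N > 150:
        # a full (n1, n2, b) tail table would be too large; score one by one
        for _ in range(n_samples):
            perm = rng.permutation(N).astype(np.int64) + 1
            if mmhg_score(perm).log_score <= thresh:
                hits += 1
    else:
        T = _full_tail_table(N)
        remaining = n_samples
        block_size = max(1, min(50_000, int(2e7 // (N * N + 1))))
        while remaining > 0:
            m = min(block_size, remaining)
            perms = np.argsort(rng.random((m, N)), axis=1).astype(np.int64) + 1
            s = _scores_for_perm_block(perms, T)
            hits += int(np.sum(s <= thresh))
            remaining -= m
    phat = hits / n_samples
    half = 1.96 * np.sqrt(phat * (1.0 - phat) / n_samples)
    return phat, (max(0.0, phat - half), min(1.0, phat + half))
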