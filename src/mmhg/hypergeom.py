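"""Log-space hypergeometric tail computation.

Everything downstream — the mmHG score, its p-value bounds and the motif
finder — reduces to evaluating the hypergeometric tail

    HGT(N, n1, n2, b) = P(X >= b),   X ~ Hypergeometric(N, n1, n2),

i.e. the probability that drawing ``n2`` elements out of ``N`` of which
``n1`` are special yields at least ``b`` special ones.  Because relevant
tails reach below 1e-130, all probabilities are carried as natural-log
values end to end; conversion to the linear scale happens only at
reporting time.

Binomial coefficients use exact log-gamma rather than a Stirling
approximation: it is equally O(1) per coefficient and removes an avoidable
source of error from reported bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "HGTQuery",
    "LOG_REL_SLACK",
    "log_slack",
    "log_le",
    "log_binomial",
    "hgt_tail",
    "hgt_profile",
    "tail_grid",
]

#: Relative slack applied when comparing log-probabilities ("HGT <= s").
#: Boundary cells whose tail equals the attained score up to floating-point
#: noise must qualify deterministically; 1e-9 relative on log values is far
#: below the 3 significant figures at which scores are reported.
LOG_REL_SLACK = 1e-9

_NEG_INF = float("-inf")

# ---------------------------------------------------------------------------
# log-factorial table (grown on demand, shared by every sweep)
# ---------------------------------------------------------------------------

_logfact_cache = np.zeros(1)


def _logfact(n: int) -> np.ndarray:
    """Return an array ``lf`` with ``lf[k] = ln k!`` for ``0 <= k <= n``."""
    global _logfact_cache
    if _logfact_cache.size <= n:
        _logfact_cache = gammaln(np.arange(max(n + 1, 1024)) + 1.0)
    return _logfact_cache


@dataclass(frozen=True)
class HGTQuery:
    """A single cell (N, n1, n2, b) at which the hypergeometric tail is taken.

    The valid intersection range is ``max(0, n2 - N + n1) <= b <= min(n1, n2)``;
    by convention a ``b`` below that range has tail 1 and above it tail 0.
    """

    N: int
    n1: int
    n2: int
    b: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not (0 <= self.n1 <= self.N and 0 <= self.n2 <= self.N):
            raise ValueError(f"n1, n2 must lie in [0, N]: {self}")


def log_slack(log_value: float) -> float:
    """Absolute slack used when comparing ``log_value`` against another log."""
    return LOG_REL_SLACK * max(1.0, abs(log_value))


def log_le(log_a: float, log_b: float) -> bool:
    """``exp(log_a) <= exp(log_b)`` with the module's relative log slack."""
    return log_a <= log_b + log_slack(log_b)


def log_binomial(n: int, k) -> float | np.ndarray:
    """Natural log of C(n, k); ``-inf`` for k outside [0, n].

    ``k`` may be a scalar or an integer array.  Negative ``n`` is invalid.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    lf = _logfact(n)
    k_arr = np.asarray(k)
    valid = (k_arr >= 0) & (k_arr <= n)
    kc = np.clip(k_arr, 0, n)
    out = np.where(valid, lf[n] - lf[kc] - lf[n - kc], _NEG_INF)
    if np.isscalar(k) or k_arr.ndim == 0:
        return float(out)
    return out


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v)
    if m == _NEG_INF:
        return _NEG_INF
    return float(m + np.log(np.sum(np.exp(v - m))))


def hgt_tail(N: int, n1: int, n2: int, b: int) -> float:
    """ln HGT(N, n1, n2, b) = ln P(X >= b), symmetric in (n1, n2).

    Out-of-range conventions: ``b`` at or below the valid lower bound gives
    ln 1 = 0; ``b`` above ``min(n1, n2)`` gives -inf (probability 0).
    """
    q = HGTQuery(N, n1, n2, b)  # validates ranges
    lo = max(0, q.n2 - q.N + q.n1)
    hi = min(q.n1, q.n2)
    if b <= lo:
        return 0.0
    if b > hi:
        return _NEG_INF
    lf = _logfact(N)
    i = np.arange(b, hi + 1)
    terms = (
        lf[q.n1] - lf[i] - lf[q.n1 - i]
        + lf[N - q.n1] - lf[q.n2 - i] - lf[N - q.n1 - q.n2 + i]
        - (lf[N] - lf[q.n2] - lf[N - q.n2])
    )
    return min(0.0, _logsumexp(terms))


def hgt_profile(N: int, n1: int, n2: int) -> np.ndarray:
    """Vector of ln HGT(N, n1, n2, b) for every valid b (ascending).

    Built from the pmf via suffix log-summation, so all ``min(n1, n2) + 1``
    tails cost what one direct tail evaluation would.  The first entry (at
    the minimal valid b) is ln 1 = 0 and entries are non-increasing.
    """
    HGTQuery(N, n1, n2, min(n1, n2))
    lo = max(0, n2 - N + n1)
    hi = min(n1, n2)
    lf = _logfact(N)
    i = np.arange(lo, hi + 1)
    lpmf = (
        lf[n1] - lf[i] - lf[n1 - i]
        + lf[N - n1] - lf[n2 - i] - lf[N - n1 - n2 + i]
        - (lf[N] - lf[n2] - lf[N - n2])
    )
    tails = np.logaddexp.accumulate(lpmf[::-1])[::-1]
    return np.minimum(tails, 0.0)


from functools import lru_cache


def tail_grid(N: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached dispatcher for :func:`_tail_grid`; see its docstring.

    Grids are memoized only for moderate N (the repeated-lookup regime of
    the statistics); large-N bound sweeps visit each n1 once and would
    only thrash the cache.
    """
    if N <= 600:
        return _tail_grid_cached(N, n1)
    return _tail_grid(N, n1)


@lru_cache(maxsize=96)
def _tail_grid_cached(N: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    return _tail_grid(N, n1)


def _tail_grid(N: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """All tails and pmfs for one n1: arrays of shape (N+1, N+1).

    ``T[n2, b] = ln HGT(N, n1, n2, b)`` and ``P[n2, b]`` the log pmf, for
    ``n2 = 0..N`` (row) and ``b = 0..N`` (column).  Cells outside the valid
    b range follow the tail conventions (1 below, 0 above) automatically.
    This is the workhorse of the O(N^3) bound sweeps: one call amortizes
    the whole (n2, b) plane for a fixed n1; results are cached (read-only).

    The suffix summation runs on the linear scale after subtracting the
    per-row maximum; tails smaller than ~1e-300 relative to the row's
    modal pmf underflow to -inf, far below anything the statistics or
    bounds compare against.
    """
    lf = _logfact(N)
    n2 = np.arange(N + 1)[:, None]
    b = np.arange(N + 1)[None, :]
    valid = (b <= n1) & (b <= n2) & (n2 - b <= N - n1)
    bc = np.where(valid, b, 0)
    lpmf = np.where(
        valid,
        lf[n1] - lf[bc] - lf[n1 - bc]
        + lf[N - n1] - lf[np.where(valid, n2 - b, 0)]
        - lf[np.where(valid, N - n1 - (n2 - b), 0)]
        - (lf[N] - lf[n2] - lf[N - n2]),
        _NEG_INF,
    )
    row_max = lpmf.max(axis=1, keepdims=True)
    row_max[row_max == _NEG_INF] = 0.0
    lin = np.exp(lpmf - row_max)
    suffix = np.cumsum(lin[:, ::-1], axis=1)[:, ::-1]
    with np.errstate(divide="ignore"):
        T = np.log(suffix) + row_max
    np.minimum(T, 0.0, out=T)
    T.setflags(write=False)
    lpmf.setflags(write=False)
    return T, lpmf
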