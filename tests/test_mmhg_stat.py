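"""The mmHG/mHG statistics and their exact and empirical p-values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmhg import (
    as_permutation,
    empirical_pvalue,
    exact_pvalue,
    intersection_counts,
    mhg_score,
    mmhg_score,
    permutation_from_rankings,
    relative_permutation,
)
from mmhg.hypergeom import hgt_tail
from mmhg.mmhg_stat import enumerate_scores


def test_permutation_validation():
    with pytest.raises(ValueError):
        as_permutation([1, 1, 3])
    with pytest.raises(ValueError):
        as_permutation([0, 1, 2])
    with pytest.raises(ValueError):
        relative_permutation([1, 2], [1, 2, 3])


@pytest.mark.parametrize(
    "pi1,pi2,expected",
    [
        ([1, 2, 3], [3, 1, 2], [3, 1, 2]),   # identity pi1 -> pi2
        ([3, 1, 2], [3, 1, 2], [1, 2, 3]),   # self-relative -> identity
        ([2, 3, 1], [3, 1, 2], [2, 3, 1]),   # pi(2)=3, pi(3)=1, pi(1)=2
    ],
)
def test_relative_permutation(pi1, pi2, expected):
    assert relative_permutation(pi1, pi2).tolist() == expected


def test_relative_permutation_defining_property():
    rng = np.random.default_rng(3)
    for _ in range(20):
        N = int(rng.integers(2, 30))
        p1 = rng.permutation(N) + 1
        p2 = rng.permutation(N) + 1
        pi = relative_permutation(p1, p2)
        for j in range(N):
            assert pi[p1[j] - 1] == p2[j]


def test_intersection_counts_examples_and_invariants():
    b = intersection_counts([2, 3, 1])
    assert b[2, 2] == 1 and b[1, 3] == 1 and b[2, 1] == 1
    ident = intersection_counts([1, 2, 3, 4, 5])
    for n1 in range(1, 6):
        for n2 in range(1, 6):
            assert ident[n1, n2] == min(n1, n2)
    rng = np.random.default_rng(4)
    for _ in range(20):
        N = int(rng.integers(2, 40))
        b = intersection_counts(rng.permutation(N) + 1)
        steps = np.diff(b[1:, :], axis=1)
        assert np.isin(steps, (0, 1)).all()
        assert (b[N, 1:] == np.arange(1, N + 1)).all()


def test_mmhg_score_examples():
    r = mmhg_score([1, 2, 3, 4])
    assert r.score == pytest.approx(1 / 6, rel=1e-12)
    assert (r.n1_star, r.n2_star, r.b_star) == (2, 2, 2)
    assert mmhg_score([2, 1]).score == pytest.approx(1.0)


def test_mmhg_identity_closed_form():
    """Identity permutation scores 1/C(N, floor(N/2)); brute force confirms."""
    for N in range(2, 13):
        r = mmhg_score(list(range(1, N + 1)))
        assert r.score == pytest.approx(1 / math.comb(N, N // 2), rel=1e-9)
    # brute force over all cells for small N
    for N in range(2, 7):
        pi = np.arange(1, N + 1)
        b = intersection_counts(pi)
        brute = min(
            hgt_tail(N, n1, n2, int(b[n1, n2]))
            for n1 in range(1, N + 1) for n2 in range(1, N + 1)
        )
        assert mmhg_score(pi).log_score == pytest.approx(brute, rel=1e-9,
                                                         abs=1e-12)


def test_mmhg_matches_cell_brute_force_random():
    rng = np.random.default_rng(5)
    for _ in range(25):
        N = int(rng.integers(2, 15))
        pi = rng.permutation(N) + 1
        b = intersection_counts(pi)
        cells = [
            (hgt_tail(N, n1, n2, int(b[n1, n2])), n1, n2)
            for n1 in range(1, N + 1) for n2 in range(1, N + 1)
        ]
        best = min(c[0] for c in cells)
        r = mmhg_score(pi)
        assert r.log_score == pytest.approx(best, rel=1e-9, abs=1e-12)
        # tie rule: smallest n1 then n2 among cells within slack
        eps = 1e-9 * max(1.0, abs(best))
        tie = min((c for c in cells if c[0] <= best + eps),
                  key=lambda c: (c[1], c[2]))
        assert (r.n1_star, r.n2_star) == (tie[1], tie[2])


def test_mmhg_score_invariant_under_common_relabeling(rng):
    """mmHG(pi2 o pi1^-1) only depends on the relative order, so composing
    both rankings with a common permutation leaves the score unchanged."""
    for _ in range(10):
        N = int(rng.integers(3, 20))
        p1 = rng.permutation(N) + 1
        p2 = rng.permutation(N) + 1
        sigma = rng.permutation(N) + 1
        a = mmhg_score(relative_permutation(p1, p2)).log_score
        sp1 = p1[sigma - 1]  # relabel the underlying elements by sigma
        sp2 = p2[sigma - 1]
        b = mmhg_score(relative_permutation(sp1, sp2)).log_score
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)


def test_mhg_score_examples_and_oracle():
    s, n = mhg_score([1, 1, 0, 0])
    assert math.exp(s) == pytest.approx(1 / 6, rel=1e-9) and n == 2
    assert mhg_score([0, 0, 0])[0] == 0.0
    assert mhg_score([1, 1, 1])[0] == 0.0
    with pytest.raises(ValueError):
        mhg_score([0, 2, 1])
    rng = np.random.default_rng(6)
    for _ in range(150):
        N = int(rng.integers(2, 35))
        lam = (rng.random(N) < rng.random()).astype(int)
        s, n = mhg_score(lam)
        ones = int(lam.sum())
        b = np.cumsum(lam)
        tails = [hgt_tail(N, ones, j + 1, int(b[j])) for j in range(N)]
        best = min(tails)
        assert s == pytest.approx(best, rel=1e-9, abs=1e-12)
        eps = 1e-9 * max(1.0, abs(best))
        assert n == min(j + 1 for j in range(N) if tails[j] <= best + eps)


@given(st.integers(2, 8))
@settings(deadline=None, max_examples=7)
def test_score_is_probability(N):
    rng = np.random.default_rng(N)
    for _ in range(20):
        s = mmhg_score(rng.permutation(N) + 1).score
        assert 0 < s <= 1


def test_exact_pvalue_s3_enumeration():
    assert exact_pvalue(1 / 3, 3) == pytest.approx(0.5)
    assert exact_pvalue(2 / 3, 3) == pytest.approx(5 / 6)
    assert exact_pvalue(1.0, 3) == 1.0
    assert exact_pvalue(1.0, 7) == 1.0


def test_exact_pvalue_guard():
    with pytest.raises(ValueError):
        exact_pvalue(0.5, 11)
    with pytest.raises(ValueError):
        exact_pvalue(0.0, 3)


def test_score_lower_bounds_pvalue_exhaustive():
    """Every attainable score is at most its own exact p-value (N <= 8)."""
    for N in range(2, 9):
        scores = enumerate_scores(N)
        for s in np.unique(scores):
            p = exact_pvalue(float(np.exp(s)), N)
            assert np.exp(s) <= p + 1e-12


def test_empirical_pvalue_matches_exact_and_is_deterministic():
    p1, ci1 = empirical_pvalue(1 / 3, 3, 100_000, seed=7)
    p2, _ = empirical_pvalue(1 / 3, 3, 100_000, seed=7)
    assert p1 == p2
    assert ci1[0] <= 0.5 <= ci1[1]
    assert empirical_pvalue(1.0, 5, 1000, seed=1)[0] == 1.0


def test_empirical_pvalue_large_n_path():
    # N > 150 uses the per-permutation scorer; determinism still holds
    p1, _ = empirical_pvalue(0.5, 160, 20, seed=3)
    p2, _ = empirical_pvalue(0.5, 160, 20, seed=3)
    assert p1 == p2


def test_permutation_from_rankings():
    pi = permutation_from_rankings(["a", "b", "c"], ["c", "a", "b"])
    assert pi.tolist() == [2, 3, 1]
    with pytest.raises(ValueError):
        permutation_from_rankings(["a", "b"], ["a", "c"])
    with pytest.raises(ValueError):
        permutation_from_rankings(["a", "a"], ["a", "a"])
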