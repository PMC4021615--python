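"""The motif-discovery pipeline against naive oracles on small inputs."""

import numpy as np
import pytest

from mmhg import (
    FinderConfig,
    IUPACPattern,
    ScoredSequence,
    assess_candidate,
    build_index,
    expand_hamming,
    find_motifs,
    from_target_background,
    iupac_match,
    mhg_score,
    rank_kmers,
    refine_iupac,
    select_seeds,
)
from mmhg.hypergeom import hgt_tail
from mmhg.mmhg_stat import exact_pvalue


def _as_scored(ds):
    return [ScoredSequence(i, s) for i, s in zip(ds.identifiers,
                                                 ds.sequences)]


def test_build_index_validation():
    with pytest.raises(ValueError):
        build_index([ScoredSequence("a", "ACGT")])
    with pytest.raises(ValueError):
        build_index([ScoredSequence("a", "ACGT"), ScoredSequence("b", "")])


def test_index_enumeration_and_flags(toy_index):
    assert set(toy_index.distinct_kmers(2)) >= {"AC", "GG", "TT"}
    assert toy_index.kmer_flags("AC").tolist() == [True, True, False, False]
    assert toy_index.kmer_flags("ZZ").tolist() == [False] * 4
    # per-sequence flags agree with naive substring search
    for w in toy_index.distinct_kmers(3):
        naive = [w in s.sequence for s in toy_index.sequences]
        assert toy_index.kmer_flags(w).tolist() == naive


def test_index_enumeration_matches_bruteforce(rng):
    seqs = [ScoredSequence(f"r{i}",
                           "".join(rng.choice(list("ACGT"), size=30)))
            for i in range(20)]
    index = build_index(seqs)
    for k in (2, 5):
        brute = set()
        for s in seqs:
            brute |= {s.sequence[i:i + k]
                      for i in range(len(s.sequence) - k + 1)}
        assert set(index.distinct_kmers(k)) == brute
        for w in sorted(brute)[:40]:
            naive = [w in s.sequence for s in seqs]
            assert index.kmer_flags(w).tolist() == naive


def test_index_iupac_traversal(toy_index):
    pat = IUPACPattern("RC")  # {A,G}C
    words = toy_index.pattern_words(pat)
    assert all(iupac_match(pat, w) for w in words)
    assert "AC" in words
    flags = toy_index.pattern_flags(pat)
    naive = np.zeros(4, dtype=bool)
    for w in words:
        naive |= toy_index.kmer_flags(w)
    assert (flags == naive).all()


def test_rank_kmers_oracle(toy_index):
    ranked = rank_kmers(toy_index, 2)
    assert ranked == sorted(ranked, key=lambda t: (t[1], t[0]))
    scores = dict(ranked)
    s, _ = mhg_score(toy_index.kmer_flags("AC").astype(int))
    assert scores["AC"] == pytest.approx(s, rel=1e-9, abs=1e-12)
    # a k-mer present in every sequence is unenriched
    idx = build_index([ScoredSequence("a", "AAC"), ScoredSequence("b", "ACA")])
    assert dict(rank_kmers(idx, 2))["AC"] == 0.0


def test_select_seeds_diversity():
    cfg = FinderConfig(n_seeds=3, min_seed_distance=2)
    ranked = [("AAAA", -5.0), ("AAAT", -4.0), ("TTTT", -3.0), ("GGCC", -2.0)]
    assert select_seeds(ranked, cfg) == ["AAAA", "TTTT", "GGCC"]
    assert select_seeds([("AAAA", -1.0)], cfg) == ["AAAA"]
    cfg1 = FinderConfig(n_seeds=2)
    assert select_seeds(ranked, cfg1) == ["AAAA", "TTTT"]


def test_refine_never_worsens_and_fixed_point(small_planted):
    index = build_index(_as_scored(small_planted))
    cfg = FinderConfig(k1=6, k2=6, refinement_passes=2)
    for seed in ["ACGTAC", "GGGGGG"]:
        s0, _ = mhg_score(index.kmer_flags(seed).astype(int))
        pat = refine_iupac(seed, index, cfg)
        s1, _ = mhg_score(index.pattern_flags(pat).astype(int))
        assert s1 <= s0 + 1e-12
        # refining the refined pattern's own consensus changes nothing more
        pat2 = refine_iupac(str(pat), index, cfg) if pat.n_words() == 1 \
            else pat
        assert len(pat2) == 6


def test_expand_hamming_contract(small_planted):
    index = build_index(_as_scored(small_planted))
    cfg = FinderConfig(k1=6, k2=6)
    pat = IUPACPattern("ACGTAC")
    words = expand_hamming(pat, index, cfg)
    assert "ACGTAC" in words
    flags = index.kmer_flags(words[0]).copy()
    for w in words[1:]:
        flags |= index.kmer_flags(w)
    s_set, _ = mhg_score(flags.astype(int))
    s_pat, _ = mhg_score(index.pattern_flags(pat).astype(int))
    assert s_set <= s_pat + 1e-12  # additions only ever improved the set


def test_expand_similarity_guard(small_planted):
    index = build_index(_as_scored(small_planted))
    strict = FinderConfig(k1=6, k2=6, similarity_threshold=6.0)
    words = expand_hamming(IUPACPattern("ACGTAC"), index, strict)
    # identity threshold k forbids any non-identical addition
    assert set(words) == set(index.pattern_words(IUPACPattern("ACGTAC")))


def test_assess_candidate_bound_dominates_score(small_planted):
    index = build_index(_as_scored(small_planted))
    cfg = FinderConfig(k1=6, k2=6, bound_method="b4")
    cand = assess_candidate(["ACGTAC"], index, cfg)
    assert cand.pvalue_bound.bound >= cand.mmhg.score - 1e-15
    assert cand.bonferroni.bound >= cand.mmhg.score - 1e-15
    assert cand.pwm.width == 6
    with pytest.raises(ValueError):
        assess_candidate([], index, cfg)


def test_reported_bound_is_valid_on_toy_input():
    """On 8 sequences, exhaustive enumeration of S_8 confirms that the
    reported bound dominates the exact p-value of the reported score."""
    rng = np.random.default_rng(11)
    seqs = []
    for i in range(8):
        body = "".join(rng.choice(list("ACGT"), size=30))
        if i < 3:
            body = "ACGTA" + body[5:]
        seqs.append(ScoredSequence(f"t{rng.integers(1e6)}_{i}", body))
    cfg = FinderConfig(k1=5, k2=5, n_seeds=5, bound_method="b2", top=3)
    for cand in find_motifs(seqs, cfg):
        p_exact = exact_pvalue(cand.mmhg.score, 8)
        assert cand.pvalue_bound.bound >= p_exact - 1e-12


def test_find_motifs_recovers_exact_planted_word(small_planted):
    cfg = FinderConfig(k1=6, k2=6, n_seeds=10, top=2)
    cands = find_motifs(_as_scored(small_planted), cfg)
    assert cands, "no motifs reported"
    top = cands[0]
    assert top.pwm.consensus() == "ACGTAC"
    assert top.pvalue_bound.bound < 0.05
    assert top.mmhg.score <= top.pvalue_bound.bound


def test_find_motifs_deterministic(small_planted):
    cfg = FinderConfig(k1=6, k2=6, n_seeds=8, top=3)
    a = find_motifs(_as_scored(small_planted), cfg)
    b = find_motifs(_as_scored(small_planted), cfg)
    assert [str(c.iupac) for c in a] == [str(c.iupac) for c in b]
    assert [c.words for c in a] == [c.words for c in b]
    assert [c.mmhg.log_score for c in a] == [c.mmhg.log_score for c in b]


def test_from_target_background():
    t = [ScoredSequence("t1", "AC"), ScoredSequence("t2", "GT"),
         ScoredSequence("t3", "CC")]
    b = [ScoredSequence("b1", "AA"), ScoredSequence("b2", "GG")]
    merged = from_target_background(t, b)
    assert [s.identifier for s in merged] == ["t1", "t2", "t3", "b1", "b2"]
    with pytest.raises(ValueError):
        from_target_background(t, [ScoredSequence("t1", "AA")])
    with pytest.raises(ValueError):
        from_target_background([], b)
    # a word present in all targets and no background scores HGT(5,3,3,3)
    index = build_index(merged)
    s, n = mhg_score(index.kmer_flags("ZZ").astype(int))  # absent: score 1
    assert s == 0.0
    idx2 = build_index(from_target_background(
        [ScoredSequence("t1", "ACG"), ScoredSequence("t2", "ACG"),
         ScoredSequence("t3", "ACG")],
        [ScoredSequence("b1", "GGT"), ScoredSequence("b2", "TTA")]))
    s, n = mhg_score(idx2.kmer_flags("AC").astype(int))
    assert s == pytest.approx(hgt_tail(5, 3, 3, 3), rel=1e-9)
    assert n == 3


def test_finder_config_validation():
    with pytest.raises(ValueError):
        FinderConfig(k1=3, k2=2)
    with pytest.raises(ValueError):
        FinderConfig(n_seeds=0)
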