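"""De-novo PWM motif discovery in ranked sequence lists.

The pipeline works on a list of sequences already ordered by the
experimental measurement (best first, the L1 ranking):

1. index every k-mer of the input (occurrence positions plus per-sequence
   presence flags);
2. for each width k in the configured range, rank all k-mers by the mHG
   enrichment of their presence vector at the top of L1, pick a diverse
   set of top seeds, greedily degenerate each seed over the IUPAC
   alphabet (coordinate ascent on mHG), then expand the refined pattern
   with enrichment-improving Hamming-1 neighbors;
3. convert each expanded word set to a PWM from its actual occurrences,
   rank the sequences by PWM score (the L2 ranking), and assess L2
   against L1 with the mmHG statistic; an upper bound on the mmHG
   p-value is reported per returned motif.

The index is a hash-map over k-mers; any structure honoring the same
enumeration/traversal contract (e.g. a generalized suffix tree) would do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bounds import BoundResult, bonferroni_bound, compute_bound
from .mmhg_stat import (
    MmhgResult,
    _mhg_batch,
    mmhg_score,
    permutation_from_rankings,
)
from .pwm import (
    IUPAC_SETS,
    IUPACPattern,
    PWM,
    ScoredSequence,
    pwm_from_occurrences,
    rank_by_pwm,
)

__all__ = [
    "FinderConfig",
    "SequenceIndex",
    "MotifCandidate",
    "build_index",
    "rank_kmers",
    "select_seeds",
    "refine_iupac",
    "expand_hamming",
    "assess_candidate",
    "find_motifs",
    "from_target_background",
]

logger = logging.getLogger("mmhg.finder")


@dataclass(frozen=True)
class FinderConfig:
    """Tunable knobs of the motif search.

    k1..k2        motif width range (default 6..8).
    n_seeds       diverse top k-mers kept as starting points (default 50).
    min_seed_distance  a k-mer within this Hamming distance of an already
                  selected seed is skipped (default 2: "quite different").
    refinement_passes  full left-to-right position sweeps of IUPAC
                  coordinate ascent (default 3; stops early on no change).
    similarity_threshold  minimum average pairwise identity (matching
                  positions) a word set may reach during Hamming expansion;
                  None means 0.5 * k.
    max_expansion  safety cap on accepted neighbor additions.
    pseudocount   per-base pseudocount when converting occurrences to a PWM.
    bound_method  which p-value bound is reported (default b4).
    both_strands  score PWMs on both DNA strands.
    top           number of motifs returned.
    seed          RNG seed recorded in reports (the search itself is
                  deterministic; the seed also drives any downstream use).
    """

    k1: int = 6
    k2: int = 8
    n_seeds: int = 50
    min_seed_distance: int = 2
    refinement_passes: int = 3
    similarity_threshold: float | None = None
    max_expansion: int = 100
    pseudocount: float = 0.5
    bound_method: str = "b4"
    both_strands: bool = False
    top: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k1 <= self.k2:
            raise ValueError("need 1 <= k1 <= k2")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class SequenceIndex:
    """K-mer index of a ranked sequence list (order = L1).

    ``occurrences[k]`` maps each distinct k-mer to its (sequence, offset)
    positions; ``flags[k]`` stacks per-sequence presence rows aligned with
    ``kmers[k]`` (the sorted distinct k-mer list).  IUPAC patterns are
    resolved by filtering the distinct k-mers position-wise, vectorized
    over a base-index encoding of the k-mer table.
    """

    sequences: list[ScoredSequence]
    occurrences: dict[int, dict[str, list[tuple[int, int]]]] = field(
        default_factory=dict)
    kmers: dict[int, list[str]] = field(default_factory=dict)
    flags: dict[int, np.ndarray] = field(default_factory=dict)
    _encoded: dict[int, np.ndarray] = field(default_factory=dict)
    _kmer_row: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def ensure_k(self, k: int) -> None:
        if k in self.kmers:
            return
        occ: dict[str, list[tuple[int, int]]] = {}
        for si, rec in enumerate(self.sequences):
            s = rec.sequence
            for off in range(len(s) - k + 1):
                w = s[off : off + k]
                if "ACGT".find(w[0]) >= 0 and all(c in "ACGT" for c in w):
                    occ.setdefault(w, []).append((si, off))
        kmers = sorted(occ)
        n = len(self.sequences)
        flags = np.zeros((len(kmers), n), dtype=bool)
        lut = np.full(256, -1, dtype=np.int8)
        for i, c in enumerate("ACGT"):
            lut[ord(c)] = i
        enc = np.zeros((len(kmers), k), dtype=np.int8)
        for r, w in enumerate(kmers):
            enc[r] = lut[np.frombuffer(w.encode(), dtype=np.uint8)]
            for si, _ in occ[w]:
                flags[r, si] = True
        self.occurrences[k] = occ
        self.kmers[k] = kmers
        self.flags[k] = flags
        self._encoded[k] = enc
        self._kmer_row[k] = {w: r for r, w in enumerate(kmers)}

    def distinct_kmers(self, k: int) -> list[str]:
        self.ensure_k(k)
        return self.kmers[k]

    def kmer_flags(self, word: str) -> np.ndarray:
        """Per-sequence presence vector of an exact word (all False if absent)."""
        k = len(word)
        self.ensure_k(k)
        r = self._kmer_row[k].get(word.upper())
        if r is None:
            return np.zeros(self.n_sequences, dtype=bool)
        return self.flags[k][r]

    def contains(self, word: str) -> bool:
        k = len(word)
        self.ensure_k(k)
        return word.upper() in self._kmer_row[k]

    def match_pattern(self, pattern: IUPACPattern) -> np.ndarray:
        """Row mask over ``kmers[k]`` of the k-mers matching the pattern."""
        k = len(pattern)
        self.ensure_k(k)
        enc = self._encoded[k]
        mask = np.zeros((k, 4), dtype=bool)
        for j, sset in enumerate(pattern.symbol_sets):
            for c in sset:
                mask[j, "ACGT".index(c)] = True
        return mask[np.arange(k)[None, :], enc].all(axis=1)

    def pattern_words(self, pattern: IUPACPattern) -> list[str]:
        """Distinct input k-mers matching the pattern."""
        rows = np.nonzero(self.match_pattern(pattern))[0]
        return [self.kmers[len(pattern)][r] for r in rows]

    def pattern_flags(self, pattern: IUPACPattern) -> np.ndarray:
        """Per-sequence presence vector of any word matching the pattern."""
        rows = self.match_pattern(pattern)
        if not rows.any():
            return np.zeros(self.n_sequences, dtype=bool)
        return self.flags[len(pattern)][rows].any(axis=0)

    def word_occurrences(self, words) -> list[str]:
        """All matched substrings of the input, one entry per window."""
        out: list[str] = []
        for w in sorted(set(words)):
            k = len(w)
            self.ensure_k(k)
            out.extend([w] * len(self.occurrences[k].get(w, ())))
        return out


@dataclass
class MotifCandidate:
    """A discovered motif: degenerate pattern, word set, PWM, statistics."""

    iupac: IUPACPattern
    words: tuple[str, ...]
    pwm: PWM
    log_mhg: float
    mmhg: MmhgResult | None = None
    pvalue_bound: BoundResult | None = None
    bonferroni: BoundResult | None = None

    @property
    def width(self) -> int:
        return len(self.iupac)


def build_index(sequences: list[ScoredSequence]) -> SequenceIndex:
    """Index a ranked sequence list (>= 2 non-empty sequences)."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if any(not s.sequence for s in sequences):
        raise ValueError("sequences must be non-empty")
    seqs = [
        ScoredSequence(s.identifier, s.sequence.upper().replace("U", "T"),
                       s.score)
        for s in sequences
    ]
    return SequenceIndex(sequences=seqs)


def rank_kmers(index: SequenceIndex, k: int) -> list[tuple[str, float]]:
    """All distinct k-mers with their mHG log scores, best (smallest) first.

    The membership vector marks sequences with at least one occurrence
    (zero-or-one-occurrence semantics); ties sort lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    index.ensure_k(k)
    kmers = index.kmers[k]
    if not kmers:
        return []
    scores, _ = _mhg_batch(index.flags[k])
    order = sorted(range(len(kmers)), key=lambda r: (scores[r], kmers[r]))
    return [(kmers[r], float(scores[r])) for r in order]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def select_seeds(ranked, config: FinderConfig) -> list[str]:
    """Greedy diverse selection: walk the ranking, skip any k-mer within
    Hamming distance < ``min_seed_distance`` of an already chosen seed."""
    seeds: list[str] = []
    for word, _score in ranked:
        if all(_hamming(word, s) >= config.min_seed_distance for s in seeds):
            seeds.append(word)
        if len(seeds) >= config.n_seeds:
            break
    return seeds


_IUPAC_ORDER = sorted(IUPAC_SETS, key=lambda c: (len(IUPAC_SETS[c]), c))


def refine_iupac(seed: str, index: SequenceIndex,
                 config: FinderConfig) -> IUPACPattern:
    """Coordinate-wise greedy IUPAC degeneration of a seed word.

    Sweeps positions left to right; at each position every IUPAC letter is
    tried and the replacement improving the pattern's mHG the most is
    accepted (strict improvement only; ties prefer fewer bases, then
    alphabetical).  Up to ``refinement_passes`` full sweeps, stopping
    early when a sweep changes nothing.  The result never scores worse
    than the seed word.
    """
    pattern = IUPACPattern(seed.upper().replace("U", "T"))
    k = len(pattern)
    index.ensure_k(k)
    enc = index._encoded[k]
    flags = index.flags[k]
    # letter -> per-kmer boolean of one position matching that letter
    letter_base = np.zeros((len(_IUPAC_ORDER), 4), dtype=bool)
    for li, letter in enumerate(_IUPAC_ORDER):
        for c in IUPAC_SETS[letter]:
            letter_base[li, "ACGT".index(c)] = True
    best, _ = _mhg_batch(index.pattern_flags(pattern))
    best = float(best[0])
    for _ in range(config.refinement_passes):
        changed = False
        for pos in range(k):
            cur_letter = pattern.letters[pos]
            # AND of the position matches at every position except pos
            rest = np.ones(enc.shape[0], dtype=bool)
            for j in range(k):
                if j != pos:
                    rest &= letter_base[
                        _IUPAC_ORDER.index(pattern.letters[j]), enc[:, j]]
            cand_letters = [c for c in _IUPAC_ORDER if c != cur_letter]
            memberships = np.zeros((len(cand_letters), index.n_sequences),
                                   dtype=bool)
            for ci, letter in enumerate(cand_letters):
                match = rest & letter_base[_IUPAC_ORDER.index(letter),
                                           enc[:, pos]]
                if match.any():
                    memberships[ci] = flags[match].any(axis=0)
            s, _ = _mhg_batch(memberships)
            ci = int(np.argmin(s))  # _IUPAC_ORDER ties: fewer bases first
            if float(s[ci]) < best:
                best = float(s[ci])
                pattern = IUPACPattern(
                    pattern.letters[:pos] + cand_letters[ci]
                    + pattern.letters[pos + 1:]
                )
                changed = True
        if not changed:
            break
    return pattern


def _identity(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def expand_hamming(pattern: IUPACPattern, index: SequenceIndex,
                   config: FinderConfig) -> tuple[str, ...]:
    """Grow the pattern's word set with enrichment-improving neighbors.

    Starts from the concrete input k-mers matching the pattern; repeatedly
    adds the Hamming-distance-1 neighbor (of any member, present in the
    input) that most improves the set's mHG, as long as the average
    pairwise identity stays at or above the similarity threshold
    (default 0.5 * k).  Stops when no addition improves.
    """
    k = len(pattern)
    threshold = (config.similarity_threshold
                 if config.similarity_threshold is not None else 0.5 * k)
    words = sorted(index.pattern_words(pattern))
    if not words:
        return ()
    members = set(words)
    flags = index.kmer_flags(words[0]).copy()
    for w in words[1:]:
        flags |= index.kmer_flags(w)
    best, _ = _mhg_batch(flags)
    best = float(best[0])
    ident_sum = sum(
        _identity(a, b) for i, a in enumerate(words) for b in words[i + 1:]
    )
    for _ in range(config.max_expansion):
        candidates: set[str] = set()
        for w in members:
            for pos in range(k):
                for c in "ACGT":
                    if c != w[pos]:
                        nb = w[:pos] + c + w[pos + 1:]
                        if nb not in members and index.contains(nb):
                            candidates.add(nb)
        if not candidates:
            break
        cand_list = sorted(candidates)
        rows = np.stack([index.kmer_flags(w) for w in cand_list])
        union = rows | flags[None, :]
        scores, _ = _mhg_batch(union)
        order = sorted(range(len(cand_list)),
                       key=lambda i: (scores[i], cand_list[i]))
        accepted = False
        for i in order:
            if scores[i] >= best:
                break  # no candidate improves
            w = cand_list[i]
            new_sum = ident_sum + sum(_identity(w, m) for m in members)
            m = len(members) + 1
            if m > 1 and new_sum / (m * (m - 1) / 2) < threshold:
                continue  # would dilute the set below the similarity guard
            members.add(w)
            flags |= rows[i]
            best = float(scores[i])
            ident_sum = new_sum
            accepted = True
            break
        if not accepted:
            break
    return tuple(sorted(members))


def assess_candidate(words, index: SequenceIndex, config: FinderConfig,
                     compute_pvalue_bound: bool = True,
                     pattern: IUPACPattern | None = None) -> MotifCandidate:
    """PWM conversion and mmHG assessment of an expanded word set.

    Builds the PWM from every matching window of every sequence, ranks the
    sequences by PWM score (ties by identifier), forms the relative
    permutation of the PWM ranking w.r.t. the input ranking, and computes
    the mmHG score plus the configured p-value bound (and Bonferroni,
    always, for transparency).
    """
    words = tuple(sorted(set(words)))
    if not words:
        raise ValueError("need a non-empty word set")
    occurrences = index.word_occurrences(words)
    pwm = pwm_from_occurrences(occurrences, pseudocount=config.pseudocount)
    ranked = rank_by_pwm(pwm, index.sequences,
                         both_strands=config.both_strands)
    l1_ids = [s.identifier for s in index.sequences]
    l2_ids = [s.identifier for s in ranked]
    pi = permutation_from_rankings(l1_ids, l2_ids)
    res = mmhg_score(pi)
    flags = index.kmer_flags(words[0]).copy()
    for w in words[1:]:
        flags |= index.kmer_flags(w)
    mhg, _ = _mhg_batch(flags)
    N = index.n_sequences
    bonf = bonferroni_bound(res.score, N)
    bound = None
    if compute_pvalue_bound:
        bound = compute_bound(res.score, N, config.bound_method, pi=pi)
    return MotifCandidate(
        iupac=pattern if pattern is not None else IUPACPattern.from_words(words),
        words=words,
        pwm=pwm,
        log_mhg=float(mhg[0]),
        mmhg=res,
        pvalue_bound=bound,
        bonferroni=bonf,
    )


def find_motifs(sequences: list[ScoredSequence],
                config: FinderConfig | None = None) -> list[MotifCandidate]:
    """Run the full pipeline and return the top motifs, best bound first.

    For each width k: rank k-mers by mHG, select diverse seeds, refine
    each seed over the IUPAC alphabet, expand with Hamming neighbors, and
    assess.  Candidates are pooled across widths, deduplicated by word
    set, ordered by mmHG score (all score->bound maps are monotone, so
    this is the bound order), and the configured p-value bound is
    computed for the returned top set.
    """
    config = config or FinderConfig()
    index = build_index(sequences)
    N = index.n_sequences
    logger.info("indexed %d sequences (k range %d..%d)", N, config.k1,
                config.k2)
    pool: dict[tuple[str, ...], MotifCandidate] = {}
    for k in range(config.k1, config.k2 + 1):
        ranked = rank_kmers(index, k)
        logger.info("k=%d: %d distinct k-mers", k, len(ranked))
        if not ranked:
            continue
        seeds = select_seeds(ranked, config)
        logger.info("k=%d: %d seeds selected", k, len(seeds))
        for seed in seeds:
            pattern = refine_iupac(seed, index, config)
            words = expand_hamming(pattern, index, config)
            if not words or words in pool:
                continue
            pool[words] = assess_candidate(words, index, config,
                                           compute_pvalue_bound=False,
                                           pattern=pattern)
    candidates = sorted(pool.values(),
                        key=lambda c: (c.mmhg.log_score, c.iupac.letters))
    top = candidates[: config.top]
    for c in top:
        l1_ids = [s.identifier for s in index.sequences]
        ranked_seqs = rank_by_pwm(c.pwm, index.sequences,
                                  both_strands=config.both_strands)
        pi = permutation_from_rankings(
            l1_ids, [s.identifier for s in ranked_seqs])
        c.pvalue_bound = compute_bound(c.mmhg.score, N, config.bound_method,
                                       pi=pi)
        logger.info("motif %s: mmHG score %.3g, %s bound %.3g",
                    c.iupac, c.mmhg.score, config.bound_method,
                    c.pvalue_bound.bound)
    return top


def from_target_background(targets: list[ScoredSequence],
                           backgrounds: list[ScoredSequence]
                           ) -> list[ScoredSequence]:
    """L1 ordering for target/background input: targets first, input order.

    Enrichment "at the top" then means enrichment in the target set
    against the background.  Duplicate identifiers across the two sets
    are invalid.
    """
    if not targets or not backgrounds:
        raise ValueError("both target and background sets must be non-empty")
    ids = [s.identifier for s in targets] + [s.identifier for s in backgrounds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate identifiers across target/background sets")
    return list(targets) + list(backgrounds)
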