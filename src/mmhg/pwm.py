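"""Position weight matrices, IUPAC patterns, and PWM-induced rankings.

A PWM of width K assigns each window of length K the product of its
per-position base probabilities; a sequence scores as its best window
(optionally over both strands for DNA).  Scores are plain likelihoods in
[0, 1] — no background normalization — so a consensus-only PWM scores its
consensus 1 and any mismatching window 0.

IUPAC degenerate patterns (the 15-letter nucleotide code) are the search
alphabet of the motif finder; a pattern matches a k-mer when every base
belongs to the position's symbol set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IUPAC_SETS",
    "IUPACPattern",
    "iupac_match",
    "iupac_letter",
    "PWM",
    "ScoredSequence",
    "pwm_score_window",
    "pwm_score_sequence",
    "pwm_from_occurrences",
    "rank_by_pwm",
    "reverse_complement",
    "encode_sequences",
]

DNA = "ACGT"
RNA = "ACGU"

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_SET_TO_LETTER = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def iupac_letter(bases) -> str:
    """The IUPAC letter for a non-empty set of DNA bases."""
    key = frozenset(str(b).upper().replace("U", "T") for b in bases)
    try:
        return _SET_TO_LETTER[key]
    except KeyError:
        raise ValueError(f"no IUPAC letter for base set {sorted(key)}") from None


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate nucleotide pattern over the 15-symbol IUPAC code."""

    letters: str

    def __post_init__(self) -> None:
        bad = [c for c in self.letters.upper() if c not in IUPAC_SETS]
        if bad or not self.letters:
            raise ValueError(f"invalid IUPAC pattern {self.letters!r}")
        object.__setattr__(self, "letters", self.letters.upper())

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters

    @property
    def symbol_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(IUPAC_SETS[c] for c in self.letters)

    @classmethod
    def from_words(cls, words) -> "IUPACPattern":
        """Consensus pattern: per position, the union of observed bases."""
        words = [w.upper().replace("U", "T") for w in words]
        if not words or len({len(w) for w in words}) != 1:
            raise ValueError("need a non-empty set of equal-length words")
        return cls(
            "".join(
                iupac_letter({w[j] for w in words})
                for j in range(len(words[0]))
            )
        )

    def matches(self, kmer: str) -> bool:
        return iupac_match(self, kmer)

    def n_words(self) -> int:
        """Number of concrete words the pattern expands to."""
        n = 1
        for s in self.symbol_sets:
            n *= len(s)
        return n

    def expand(self) -> list[str]:
        """All concrete words matching the pattern (lexicographic)."""
        words = [""]
        for s in self.symbol_sets:
            words = [w + c for w in words for c in sorted(s)]
        return sorted(words)


def iupac_match(pattern: IUPACPattern | str, kmer: str) -> bool:
    """True iff each base of ``kmer`` lies in the pattern's position set."""
    pat = pattern if isinstance(pattern, IUPACPattern) else IUPACPattern(pattern)
    k = kmer.upper().replace("U", "T")
    if len(k) != len(pat):
        raise ValueError("pattern and k-mer lengths differ")
    return all(c in s for c, s in zip(k, pat.symbol_sets))


@dataclass
class ScoredSequence:
    identifier: str
    sequence: str
    score: float = 0.0


@dataclass(frozen=True)
class PWM:
    """A K x 4 matrix of per-position base probabilities.

    ``weights[j, a]`` is the probability of alphabet symbol ``a`` at
    position ``j``; every position (column of the field's conventional
    symbols-by-positions matrix) sums to 1.
    """

    weights: np.ndarray
    alphabet: str = DNA

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError("weights must be a (K, 4) matrix with K >= 1")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position must sum to 1")
        if self.alphabet not in (DNA, RNA):
            raise ValueError("alphabet must be DNA (ACGT) or RNA (ACGU)")
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    def consensus(self) -> str:
        return "".join(self.alphabet[i] for i in np.argmax(self.weights, axis=1))


def _base_indices(seq: str, alphabet: str) -> np.ndarray:
    """Map a sequence to 0..3 indices; characters outside the alphabet -> -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    if alphabet == DNA:
        lut[ord("U")] = 3  # tolerate RNA letters in DNA mode
    elif alphabet == RNA:
        lut[ord("T")] = 3
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return lut[arr]


def encode_sequences(seqs: list[str], alphabet: str = DNA) -> list[np.ndarray]:
    """Encode sequences as 0..3 index arrays (-1 for non-alphabet chars)."""
    return [_base_indices(s, alphabet) for s in seqs]


def pwm_score_window(pwm: PWM, substring: str) -> float:
    """Product of position probabilities; 0 if any char is off-alphabet."""
    if len(substring) != pwm.width:
        raise ValueError(
            f"window length {len(substring)} != PWM width {pwm.width}"
        )
    idx = _base_indices(substring, pwm.alphabet)
    if np.any(idx < 0):
        return 0.0
    return float(np.prod(pwm.weights[np.arange(pwm.width), idx]))


def _best_window(pwm: PWM, idx: np.ndarray) -> float:
    K = pwm.width
    M = idx.size
    if M < K:
        return 0.0
    windows = np.lib.stride_tricks.sliding_window_view(idx, K)
    ok = np.all(windows >= 0, axis=1)
    if not ok.any():
        return 0.0
    w = windows[ok]
    scores = np.prod(pwm.weights[np.arange(K)[None, :], w], axis=1)
    return float(scores.max())


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def pwm_score_sequence(
    pwm: PWM, seq: str, identifier: str = "", both_strands: bool = False,
    sum_mode: bool = False, sum_threshold: float = 0.0,
) -> ScoredSequence:
    """Best-window PWM score of a sequence (0 when shorter than the PWM).

    ``both_strands`` also scans the reverse complement (DNA only).
    ``sum_mode`` replaces the max with the sum of windows scoring at least
    ``sum_threshold`` (a multi-occurrence variant, not the default model).
    """
    idx = _base_indices(seq, pwm.alphabet)
    strands = [idx]
    if both_strands:
        if pwm.alphabet != DNA:
            raise ValueError("both-strand scoring applies to DNA only")
        strands.append(_base_indices(reverse_complement(seq), pwm.alphabet))
    if sum_mode:
        # multi-occurrence variant: not a probability, may exceed 1;
        # downstream ranking only uses the order
        score = sum(_sum_windows(pwm, s, sum_threshold) for s in strands)
    else:
        score = max(_best_window(pwm, s) for s in strands)
    return ScoredSequence(identifier=identifier, sequence=seq, score=score)


def _sum_windows(pwm: PWM, idx: np.ndarray, threshold: float) -> float:
    K = pwm.width
    if idx.size < K:
        return 0.0
    windows = np.lib.stride_tricks.sliding_window_view(idx, K)
    ok = np.all(windows >= 0, axis=1)
    if not ok.any():
        return 0.0
    scores = np.prod(pwm.weights[np.arange(K)[None, :], windows[ok]], axis=1)
    return float(scores[scores >= threshold].sum())


def pwm_from_occurrences(
    occurrences, pseudocount: float = 0.5, alphabet: str = DNA
) -> PWM:
    """PWM of per-position base frequencies over matched substrings.

    weight(base, j) = (count(base, j) + pseudocount)
                      / (n_occurrences + 4 * pseudocount).
    Every occurrence must have the same length; at least one is required.
    """
    occ = [o.upper().replace("U", "T" if alphabet == DNA else "U")
           for o in occurrences]
    if not occ:
        raise ValueError("at least one occurrence is required")
    if len({len(o) for o in occ}) != 1:
        raise ValueError("occurrences must all have the same length")
    K = len(occ[0])
    counts = np.zeros((K, 4))
    for o in occ:
        idx = _base_indices(o, alphabet)
        if np.any(idx < 0):
            raise ValueError(f"occurrence {o!r} has off-alphabet characters")
        counts[np.arange(K), idx] += 1
    weights = (counts + pseudocount) / (len(occ) + 4.0 * pseudocount)
    return PWM(weights=weights, alphabet=alphabet)


def rank_by_pwm(pwm: PWM, sequences: list[ScoredSequence], tie_key=None,
                **score_kwargs) -> list[ScoredSequence]:
    """Sequences sorted by descending PWM score; ties by a deterministic key.

    The default tie key is the identifier (lexicographic).  Tie-breaking
    must never use the input (affinity) order — ranking ties by the
    partner list inflates mutual enrichment; the same inflation occurs
    when identifiers themselves encode the input ranking, in which case a
    rank-uncorrelated ``tie_key`` should be supplied.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    tie_key = tie_key or (lambda s: s.identifier)
    scored = [
        pwm_score_sequence(pwm, s.sequence, identifier=s.identifier,
                           **score_kwargs)
        for s in sequences
    ]
    return sorted(scored, key=lambda r: (-r.score, tie_key(r)))
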