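"""Planted-motif benchmark datasets and random permutations.

The generator reproduces the benchmark layout used to validate ranked-list
motif discovery: 500 i.i.d. random sequences of 100 bp, with one concrete
variant of a degenerate IUPAC motif planted (replacing a window, so length
is preserved) in each of the top 64 sequences of the ranking.  Ground
truth records every planted word and its position, so recovery can be
checked programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pwm import DNA, IUPACPattern

__all__ = ["PlantSpec", "PlantedDataset", "generate_planted_dataset",
           "generate_random_permutation"]


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of a planted-motif dataset.

    Defaults are the benchmark conditions: 500 sequences of 100 bp with
    plants in the top 64.  ``gc_content`` shapes the i.i.d. background
    (0.5 = uniform ACGT); ``plants_per_sequence`` > 1 enables multi-plant
    sequences (off by default).
    """

    motif: IUPACPattern
    n_sequences: int = 500
    length: int = 100
    n_planted: int = 64
    gc_content: float = 0.5
    plants_per_sequence: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.motif, str):
            object.__setattr__(self, "motif", IUPACPattern(self.motif))
        if self.n_planted > self.n_sequences:
            raise ValueError("n_planted must be <= n_sequences")
        if len(self.motif) > self.length:
            raise ValueError("motif is wider than the sequences")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class PlantedDataset:
    identifiers: list[str]
    sequences: list[str]
    ground_truth: list[dict] = field(default_factory=list)
    spec: PlantSpec | None = None


def _draw_word(pattern: IUPACPattern, rng: np.random.Generator) -> str:
    """One concrete variant, each position drawn uniformly from its set."""
    return "".join(rng.choice(sorted(s)) for s in pattern.symbol_sets)


def generate_planted_dataset(spec: PlantSpec) -> PlantedDataset:
    """Ranked dataset (best first) with motif variants planted at the top.

    Sequences are i.i.d. draws with base probabilities derived from
    ``gc_content``; for each of the first ``n_planted`` sequences a
    uniformly sampled concrete word of the motif replaces a uniformly
    chosen window.  Byte-identical across runs for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    width = len(spec.motif)
    n_digits = len(str(spec.n_sequences))
    # identifiers are assigned in a shuffled order so that lexicographic
    # tie-breaking downstream never correlates with the ranking itself
    labels = rng.permutation(spec.n_sequences)
    identifiers = [f"seq{str(labels[i] + 1).zfill(n_digits)}"
                   for i in range(spec.n_sequences)]
    base = rng.choice(list(DNA), size=(spec.n_sequences, spec.length),
                      p=probs)
    sequences: list[str] = []
    ground_truth: list[dict] = []
    for i in range(spec.n_sequences):
        chars = list(base[i])
        if i < spec.n_planted:
            plants = []
            for _ in range(spec.plants_per_sequence):
                word = _draw_word(spec.motif, rng)
                pos = int(rng.integers(0, spec.length - width + 1))
                chars[pos : pos + width] = list(word)
                plants.append({"word": word, "position": pos})
            for p in plants:
                ground_truth.append({"identifier": identifiers[i], **p})
        sequences.append("".join(chars))
    return PlantedDataset(identifiers=identifiers, sequences=sequences,
                          ground_truth=ground_truth, spec=spec)


def generate_random_permutation(N: int, seed: int) -> np.ndarray:
    """A uniform permutation of {1..N} (1-based values), seeded."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.permutation(N).astype(np.int64) + 1
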