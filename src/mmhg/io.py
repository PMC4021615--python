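"""Readers and writers: FASTA, rank tables, MEME motifs, JSON reports.

Ranking convention throughout the package: position 1 is the strongest
measurement ("top" of the list).  The mmHG statistic is orientation
sensitive, so a score table given with ascending-is-better semantics must
be negated by the caller.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motif_finder import FinderConfig, MotifCandidate
from .pwm import DNA, PWM, ScoredSequence

__all__ = [
    "read_ranked_fasta",
    "read_score_table",
    "read_identifier_list",
    "write_fasta",
    "write_meme",
    "read_meme",
    "write_motif_report",
]

logger = logging.getLogger("mmhg.io")


def read_score_table(path) -> dict[str, float]:
    """Two-column delimited text: identifier, score (higher = better)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (identifier, score)")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate identifier {dup!r}")
    return dict(zip(ids, df.iloc[:, 1].astype(float)))


def read_identifier_list(path) -> list[str]:
    """One identifier per line, best first."""
    out = [line.strip() for line in Path(path).read_text().splitlines()
           if line.strip() and not line.startswith("#")]
    if len(set(out)) != len(out):
        raise ValueError(f"{path}: duplicate identifiers")
    return out


def read_ranked_fasta(fasta_path, score_table_path=None
                      ) -> list[ScoredSequence]:
    """Ranked sequence list from FASTA, best first.

    Without a score table the file order is the ranking.  With one, the
    records are reordered by descending score (ties by identifier, never
    by file order).  Identifiers are the description up to the first
    whitespace; sequences are uppercased, U accepted.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: empty FASTA file")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"{fasta_path}: duplicate identifier {dup!r}")
    seqs = [
        ScoredSequence(identifier=r.id, sequence=str(r.seq).upper())
        for r in records
    ]
    if score_table_path is None:
        return seqs
    table = read_score_table(score_table_path)
    missing = [s.identifier for s in seqs if s.identifier not in table]
    if missing:
        raise ValueError(
            f"{score_table_path}: missing score for identifier "
            f"{missing[0]!r}"
        )
    for s in seqs:
        s.score = table[s.identifier]
    return sorted(seqs, key=lambda s: (-s.score, s.identifier))


def write_fasta(path, identifiers, sequences, width: int = 70) -> None:
    with open(path, "w") as fh:
        for ident, seq in zip(identifiers, sequences):
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(path, motifs: list[tuple[str, PWM]],
               nsites: dict[str, int] | None = None) -> None:
    """Write PWMs in MEME minimal motif format (one letter-probability
    matrix per motif, positions as rows)."""
    nsites = nsites or {}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        alphabet = motifs[0][1].alphabet if motifs else DNA
        fh.write(f"ALPHABET= {alphabet}\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} 0.25000" for c in alphabet) + "\n\n")
        for name, pwm in motifs:
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width}"
                f" nsites= {nsites.get(name, 20)} E= 0\n"
            )
            for row in pwm.weights:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[tuple[str, PWM]]:
    """Parse a MEME minimal motif file back into named PWMs."""
    motifs: list[tuple[str, PWM]] = []
    alphabet = DNA
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET="):
            alphabet = line.split("=", 1)[1].strip()
        elif line.startswith("MOTIF"):
            name = line.split(None, 2)[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability"):
                i += 1
            header = lines[i].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(i + 1, i + 1 + w):
                rows.append([float(x) for x in lines[j].split()])
            matrix = np.array(rows)
            matrix = matrix / matrix.sum(axis=1, keepdims=True)
            motifs.append((name, PWM(weights=matrix, alphabet=alphabet)))
            i += w
        i += 1
    return motifs


# ---------------------------------------------------------------------------
# motif report
# ---------------------------------------------------------------------------

def _log10(x: float) -> float:
    return float(np.log10(x)) if x > 0 else float("-inf")


def _candidate_payload(c: MotifCandidate) -> dict:
    d = {
        "iupac": str(c.iupac),
        "consensus": c.pwm.consensus(),
        "width": c.width,
        "words": list(c.words),
        "pwm": [[float(v) for v in row] for row in c.pwm.weights],
        "mhg_seed_score": float(np.exp(c.log_mhg)),
        "mmhg": {
            "score": float(c.mmhg.score),
            "log10_score": _log10(c.mmhg.score),
            "n1_star": int(c.mmhg.n1_star),
            "n2_star": int(c.mmhg.n2_star),
            "b_star": int(c.mmhg.b_star),
        },
    }
    if c.pvalue_bound is not None:
        d["pvalue_bound"] = {
            "method": c.pvalue_bound.method,
            "bound": float(c.pvalue_bound.bound),
            "log10_bound": _log10(c.pvalue_bound.bound),
            "cells_counted": int(c.pvalue_bound.cells_counted),
        }
    if c.bonferroni is not None:
        d["bonferroni"] = {
            "bound": float(c.bonferroni.bound),
            "log10_bound": _log10(c.bonferroni.bound),
        }
    return d


def write_motif_report(candidates: list[MotifCandidate], out_dir,
                       config: FinderConfig | None = None,
                       n_sequences: int | None = None) -> dict:
    """Write report.json, motifs.meme and summary.txt; return the payload.

    The JSON echoes the configuration (including the RNG seed) so that a
    run is reproducible from its own report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or FinderConfig()
    payload = {
        "config": {k: getattr(config, k) for k in (
            "k1", "k2", "n_seeds", "min_seed_distance", "refinement_passes",
            "similarity_threshold", "max_expansion", "pseudocount",
            "bound_method", "both_strands", "top", "seed")},
        "n_sequences": n_sequences,
        "n_motifs": len(candidates),
        "motifs": [_candidate_payload(c) for c in candidates],
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2) + "\n")
    write_meme(
        out / "motifs.meme",
        [(f"motif_{i+1}_{c.iupac}", c.pwm)
         for i, c in enumerate(candidates)],
        {f"motif_{i+1}_{c.iupac}": len(c.words)
         for i, c in enumerate(candidates)},
    )
    with open(out / "summary.txt", "w") as fh:
        fh.write("rank\tiupac\tconsensus\tmmhg_score\tbound_method\t"
                 "pvalue_bound\tlog10_bound\n")
        for i, c in enumerate(candidates):
            b = c.pvalue_bound
            fh.write(
                f"{i+1}\t{c.iupac}\t{c.pwm.consensus()}\t"
                f"{c.mmhg.score:.4g}\t"
                f"{b.method if b else 'NA'}\t"
                f"{b.bound if b else float('nan'):.4g}\t"
                f"{_log10(b.bound) if b else float('nan'):.4f}\n"
            )
    logger.info("wrote report for %d motifs to %s", len(candidates), out)
    return payload
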