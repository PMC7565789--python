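"""Per-column sequence-conservation scoring of aligned rRNA 3' termini.

Cross-species conservation of the last ~100 bases of 16S/23S rRNA determines
whether a single 3'-end blocking primer can transfer between species.  Each
alignment column is scored by Shannon entropy over the five symbols
{A, T, C, G, -}, normalized by log 5 so a uniform column scores 1 and a
monomorphic column 0.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

ALPHABET = ("A", "T", "C", "G", "-")
_SYMBOL_INDEX = {c: i for i, c in enumerate(ALPHABET)}


def conservation_entropy(msa: Sequence[str], tail_cols: int = 100) -> np.ndarray:
    """Normalized base-5 Shannon entropy per column of the alignment tail.

    Parameters
    ----------
    msa:
        Aligned sequences of equal length over {A, T, C, G, -}; ``U`` is
        accepted and mapped to ``T`` on ingest. At least two rows required.
    tail_cols:
        Number of 3'-terminal columns to score (all columns if the alignment
        is shorter).

    Returns
    -------
    Array of per-column entropies in [0, 1], ordered 5'->3' over the scored
    tail; H = -sum_c f_c log5 f_c with 0·log 0 = 0.
    """
    if len(msa) < 2:
        raise ValueError("alignment must contain at least 2 rows")
    rows = [s.upper().replace("U", "T") for s in msa]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    bad = set("".join(rows)) - set(ALPHABET)
    if bad:
        raise ValueError(f"alignment contains symbols outside {{A,T,C,G,-}}: {sorted(bad)}")
    if tail_cols < 1:
        raise ValueError("tail_cols must be >= 1")

    start = max(0, ncol - tail_cols)
    mat = np.array([[_SYMBOL_INDEX[c] for c in r[start:]] for r in rows], dtype=np.int8)
    counts = np.stack([(mat == i).sum(axis=0) for i in range(len(ALPHABET))]).astype(float)
    freqs = counts / counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
    return -terms.sum(axis=0) / np.log(len(ALPHABET))


def read_alignment_fasta(path: str | Path) -> list[str]:
    """Read an aligned FASTA (rows must be equal length; checked by the caller)."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def write_entropy_tsv(entropies: np.ndarray, path: str | Path) -> None:
    """TSV with 1-based column index counted from the 3' end, and entropy."""
    n = len(entropies)
    with open(path, "w") as fh:
        fh.write("position_from_3prime\tentropy\n")
        for i, h in enumerate(entropies):
            fh.write(f"{n - i}\t{h:.6f}\n")
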