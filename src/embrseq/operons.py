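"""Operon 3'-bias metagene profiles.

Poly-A-tail capture reads preferentially from 3' ends, so positional bias is
audited by a metagene profile over multi-gene operons: each read mapping
wholly within an operon contributes its strand-aware distance from the operon
3' end, distances are discretized into 50 equal-width bins per operon,
per-operon bin vectors are normalized to sum to 1, and the profile is the
per-bin mean over operons with more than a minimum number of unique reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from embrseq.align import AlignmentRecord


@dataclass(frozen=True)
class OperonRecord:
    name: str
    ref_id: str
    left: int      # 1-based closed genomic interval
    right: int
    strand: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.left <= self.right:
            raise ValueError(f"operon {self.name}: invalid interval [{self.left}, {self.right}]")
        if self.strand not in "+-":
            raise ValueError(f"operon {self.name}: strand must be + or -")
        if len(self.gene_ids) < 1:
            raise ValueError(f"operon {self.name}: at least one gene required")

    @property
    def length(self) -> int:
        return self.right - self.left + 1


@dataclass
class OperonBiasProfile:
    bins: np.ndarray          # mean relative read fraction per bin, 5'->3'
    n_operons_used: int
    per_operon: dict[str, np.ndarray]


def operon_profile(
    alignments: Iterable[AlignmentRecord],
    operons: Sequence[OperonRecord],
    nbins: int = 50,
    min_genes: int = 2,
    min_reads: int = 200,
    dedupe: bool = True,
) -> OperonBiasProfile:
    """Metagene 3'-bias profile over multi-gene operons.

    Reads must map wholly within an operon to count; reads straddling a
    boundary are excluded.  "Unique reads" deduplicates by (start, strand)
    within each operon (``dedupe=False`` disables).  Operons with fewer than
    ``min_genes`` genes or not more than ``min_reads`` unique reads are
    dropped; if none survive, raises.  Bin 1 is 5'-most, bin ``nbins``
    3'-most.
    """
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    eligible = [op for op in operons if len(op.gene_ids) >= min_genes]
    alns = [a for a in alignments if a.mapped]

    per_operon: dict[str, np.ndarray] = {}
    for op in eligible:
        lo0, hi0 = op.left - 1, op.right - 1
        seen: set[tuple[int, str]] = set()
        hist = np.zeros(nbins)
        n_used = 0
        binw = op.length / nbins
        for a in alns:
            if a.ref_id != op.ref_id:
                continue
            start, end = a.pos, a.pos + a.aln_len - 1
            if start < lo0 or end > hi0:
                continue
            if dedupe:
                key = (start, a.strand or "+")
                if key in seen:
                    continue
                seen.add(key)
            three_prime = end if (a.strand or "+") == "+" else start
            dist = (hi0 - three_prime) if op.strand == "+" else (three_prime - lo0)
            bin_from3 = min(int(dist / binw), nbins - 1)
            hist[nbins - 1 - bin_from3] += 1
            n_used += 1
        if n_used > min_reads:
            per_operon[op.name] = hist / n_used

    if not per_operon:
        raise ValueError(
            f"no operon retained ({len(eligible)} with >= {min_genes} genes, "
            f"none with more than {min_reads} unique reads)"
        )
    mean_bins = np.mean(np.stack(list(per_operon.values())), axis=0)
    return OperonBiasProfile(mean_bins, len(per_operon), per_operon)


# ------------------------------------------------------------------- I/O


def read_operon_table(path: str | Path) -> list[OperonRecord]:
    """RegulonDB-style TSV: name, ref, left, right, strand, comma-separated genes."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["name", "ref_id", "left", "right", "strand", "genes"]
        if header[: len(expected)] != expected:
            raise ValueError(f"unexpected operon table header in {path}: {header}")
        for line in fh:
            if not line.strip():
                continue
            name, ref_id, left, right, strand, genes = line.rstrip("\n").split("\t")[:6]
            out.append(
                OperonRecord(name, ref_id, int(left), int(right), strand,
                             tuple(g for g in genes.split(",") if g))
            )
    return out


def write_operon_table(operons: Sequence[OperonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tref_id\tleft\tright\tstrand\tgenes\n")
        for op in operons:
            fh.write(
                f"{op.name}\t{op.ref_id}\t{op.left}\t{op.right}\t{op.strand}\t"
                f"{','.join(op.gene_ids)}\n"
            )


def write_profile_tsv(profile: OperonBiasProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin\tmean_fraction\n")
        for i, v in enumerate(profile.bins, start=1):
            fh.write(f"{i}\t{v:.6f}\n")
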