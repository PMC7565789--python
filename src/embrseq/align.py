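"""Right-mate alignment: minimal exact-seed matcher and SAM ingestion.

Production runs map reads with an external aligner and feed the SAM here via
:func:`read_sam`; :func:`align_exact` is a deterministic k-mer-seed, ungapped
matcher sufficient for synthetic data, where reads are sense-strand substrings
of the reference with rare substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from embrseq.reference import ReferenceSet


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's best placement. ``pos`` is the 0-based leftmost reference coordinate."""

    read_id: str
    ref_id: Optional[str]
    pos: Optional[int]
    strand: Optional[str]
    aln_len: int
    mismatches: int
    mapped: bool

    @classmethod
    def unmapped(cls, read_id: str) -> "AlignmentRecord":
        return cls(read_id, None, None, None, 0, 0, False)


def _read_seq(read) -> tuple[str, str]:
    """Accept (read_id, seq) tuples or objects with read_id/right_seq attributes."""
    if isinstance(read, tuple):
        return read
    return read.read_id, read.right_seq


def align_exact(
    reads: Iterable, ref: ReferenceSet, k: int = 25
) -> list[AlignmentRecord]:
    """Seed-and-extend exact matcher: k-mer seeds on the sense strand, ungapped
    full-length extension, best hit by fewest mismatches.

    Ties between references are reported as unmapped (ambiguous); ties within
    one reference resolve to the leftmost position.  Reads shorter than ``k``
    raise; references must be ACGT-only (guaranteed by ReferenceSet).
    """
    if k < 1:
        raise ValueError("seed length k must be >= 1")
    index: dict[str, list[tuple[int, int]]] = {}
    seqs = [rec.sequence for rec in ref]
    ids = [rec.ref_id for rec in ref]
    for ri, seq in enumerate(seqs):
        for p in range(len(seq) - k + 1):
            index.setdefault(seq[p : p + k], []).append((ri, p))

    out: list[AlignmentRecord] = []
    for read in reads:
        read_id, seq = _read_seq(read)
        n = len(seq)
        if k > n:
            raise ValueError(f"seed length {k} exceeds read length {n} ({read_id})")
        candidates: set[tuple[int, int]] = set()
        offsets = list(range(0, n - k + 1, k))
        if offsets[-1] != n - k:
            offsets.append(n - k)
        for off in offsets:
            for ri, p in index.get(seq[off : off + k], ()):
                start = p - off
                if 0 <= start and start + n <= len(seqs[ri]):
                    candidates.add((ri, start))
        if not candidates:
            out.append(AlignmentRecord.unmapped(read_id))
            continue
        best: list[tuple[int, int]] = []
        best_mm = n + 1
        for ri, start in sorted(candidates):
            target = seqs[ri][start : start + n]
            mm = sum(a != b for a, b in zip(seq, target))
            if mm < best_mm:
                best_mm, best = mm, [(ri, start)]
            elif mm == best_mm:
                best.append((ri, start))
        refs_hit = {ri for ri, _ in best}
        if len(refs_hit) > 1:
            out.append(AlignmentRecord.unmapped(read_id))  # ambiguous across references
            continue
        ri, start = min(best)
        out.append(AlignmentRecord(read_id, ids[ri], start, "+", n, best_mm, True))
    return out


# ------------------------------------------------------------------- SAM I/O


def write_sam(
    alignments: Sequence[AlignmentRecord], ref: ReferenceSet, path: str | Path
) -> None:
    """Write alignments as SAM with a minimal @HD/@SQ header."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": rec.ref_id, "LN": len(rec)} for rec in ref],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for aln in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = aln.read_id
            if aln.mapped:
                seg.reference_id = fh.header.references.index(aln.ref_id)
                seg.reference_start = aln.pos
                seg.cigarstring = f"{aln.aln_len}M"
                seg.flag = 16 if aln.strand == "-" else 0
                seg.mapping_quality = 60
                seg.set_tag("NM", aln.mismatches)
            else:
                seg.flag = 4
                seg.mapping_quality = 0
            fh.write(seg)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Ingest primary alignments from a SAM file.

    SAM 1-based coordinates become internal 0-based; FLAG bits decode mapped
    state and strand; secondary/supplementary records are skipped.  Malformed
    input raises ValueError naming the file and offending content.
    """
    records: list[AlignmentRecord] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
            if not fh.header.get("SQ"):
                raise ValueError(f"{path}: SAM header missing @SQ lines")
            for seg in fh:
                if seg.is_secondary or seg.is_supplementary:
                    continue
                if seg.is_unmapped:
                    records.append(AlignmentRecord.unmapped(seg.query_name))
                else:
                    mm = seg.get_tag("NM") if seg.has_tag("NM") else 0
                    records.append(
                        AlignmentRecord(
                            read_id=seg.query_name,
                            ref_id=seg.reference_name,
                            pos=seg.reference_start,
                            strand="-" if seg.is_reverse else "+",
                            aln_len=seg.reference_length or 0,
                            mismatches=int(mm),
                            mapped=True,
                        )
                    )
    except (ValueError, OSError) as exc:
        raise ValueError(f"SAM parse error in {path}: {exc}") from exc
    return records


def truth_alignments(truth) -> list[AlignmentRecord]:
    """Convert a simulator TruthTable into perfect alignment records."""
    return [
        AlignmentRecord(
            read_id=row.read_id,
            ref_id=row.ref_id,
            pos=int(row.read_start),
            strand="+",
            aln_len=int(row.read_end - row.read_start),
            mismatches=0,
            mapped=True,
        )
        for row in truth.itertuples(index=False)
    ]
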