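"""Barcode demultiplexing of paired reads.

The left mate of each pair begins with a 6-nt sample barcode (the overhang of
the poly-T reverse-transcription primer); the right mate is transcript-derived.
Only reads whose barcode matches a whitelisted sample are retained.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

BARCODE_LEN = 6

# the five sample barcodes used in the reference protocol
DEFAULT_WHITELIST = ("AGACTC", "AGCTTC", "CATGAG", "CAGATC", "TCACAG")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    left_seq: str
    right_seq: str
    left_qual: str = ""
    right_qual: str = ""

    def __post_init__(self) -> None:
        if self.left_qual and len(self.left_qual) != len(self.left_seq):
            raise ValueError(f"{self.read_id}: left qual/seq length mismatch")
        if self.right_qual and len(self.right_qual) != len(self.right_seq):
            raise ValueError(f"{self.read_id}: right qual/seq length mismatch")


def _open_maybe_gzip(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_paired_fastq(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files (plain or gzip), stripping /1 and /2."""
    with _open_maybe_gzip(r1_path) as f1, _open_maybe_gzip(r2_path) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1, _, q1 = (f1.readline().rstrip("\n") for _ in range(3))
            h2 = f2.readline()
            if not h2:
                raise ValueError("mate files out of sync: R2 ended early")
            s2, _, q2 = (f2.readline().rstrip("\n") for _ in range(3))
            rid1 = h1.rstrip("\n").lstrip("@").split()[0].removesuffix("/1")
            rid2 = h2.rstrip("\n").lstrip("@").split()[0].removesuffix("/2")
            if rid1 != rid2:
                raise ValueError(f"mate names differ: {rid1!r} vs {rid2!r}")
            yield ReadPair(rid1, s1, s2, q1, q2)


def _validate_whitelist(whitelist: Iterable[str]) -> list[str]:
    wl = list(whitelist)
    if len(wl) != len(set(wl)):
        raise ValueError("whitelist contains duplicate barcodes")
    for bc in wl:
        if len(bc) != BARCODE_LEN or not set(bc) <= set("ACGT"):
            raise ValueError(f"invalid barcode {bc!r}: must be 6 nt over ACGT")
    return wl


def _hamming1_neighbors(bc: str) -> set[str]:
    out = set()
    for i, orig in enumerate(bc):
        for base in "ACGT":
            if base != orig:
                out.add(bc[:i] + base + bc[i + 1 :])
    return out


def demultiplex(
    pairs: Iterable[ReadPair],
    whitelist: Iterable[str] = DEFAULT_WHITELIST,
    allow_one_mismatch: bool = False,
) -> tuple[dict[str, list[ReadPair]], int]:
    """Partition read pairs by the first 6 nt of the left mate.

    Exact whitelist match by default.  With ``allow_one_mismatch`` a barcode
    at Hamming distance 1 from exactly one whitelisted barcode is rescued;
    ambiguous rescues (distance 1 from several) are discarded.  Returns
    ``(assignments, n_discarded)`` with assigned + discarded = input count.
    """
    wl = _validate_whitelist(whitelist)
    lookup: dict[str, str | None] = {bc: bc for bc in wl}
    if allow_one_mismatch:
        for bc in wl:
            for nb in _hamming1_neighbors(bc):
                if nb in lookup and lookup[nb] != bc:
                    lookup[nb] = None  # ambiguous: reachable from two barcodes
                elif nb not in lookup:
                    lookup[nb] = bc
    out: dict[str, list[ReadPair]] = {bc: [] for bc in wl}
    discarded = 0
    for pair in pairs:
        observed = pair.left_seq[:BARCODE_LEN]
        target = lookup.get(observed)
        if target is None:
            discarded += 1
        else:
            out[target].append(pair)
    return out, discarded


def write_demux_report(
    assignments: dict[str, list[ReadPair]], discarded: int, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tn_reads\n")
        for bc, reads in assignments.items():
            fh.write(f"{bc}\t{len(reads)}\n")
        fh.write(f"discarded\t{discarded}\n")
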