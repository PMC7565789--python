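"""Blocking-primer design against rRNA targets.

Two kinds of blockers are designed as DNA reverse complements of a target
interval: *3'-end blockers* are fixed-length (30 nt) oligos against the
3'-terminal bases of each rRNA, and *hotspot blockers* anneal ~100 nt
downstream (3') of a read-start hotspot — where the capturable fragment 3'
ends created at the hotspot actually lie — with position and length adjusted
until the nearest-neighbor Tm clears a threshold (65 °C by default), matching
how such primers are designed by hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from embrseq.reference import revcomp
from embrseq.thermo import DEFAULT_CONDITIONS, ThermoConditions, tm_nearest_neighbor

MIN_PRIMER_LEN = 8

# Published E. coli blocking-primer set: fixed 30-mers against the 3' termini
# of the three rRNA species, and hotspot blockers keyed by (rRNA, hotspot
# coordinate), each annealing ~100 nt downstream of its hotspot.
THREE_PRIME_BLOCKERS = {
    "5S": "ATGCCTGGCAGTTCCCTACTCTCGCATGGG",
    "16S": "TAAGGAGGTGATCCAACCGCAGGTTCCCCT",
    "23S": "AAGGTTAAGCCTCACGGTTCATTAGTACCG",
}

HOTSPOT_BLOCKERS = {
    ("16S", 107): "GGCACATCCGATGGCAAGAGGCCCGAAGGT",
    ("16S", 682): "TCCTGTTTGCTCCCCACGCTTTCGCACCTG",
    ("16S", 1241): "CCGTGGCATTCTGATCCACGATTACTAGCGATTCCG",
    ("23S", 375): "CGCCTTTCCCTCACGGTACTGGTTCACTATCGG",
    ("23S", 1421): "TTGCTTCAGCACCGTAGTGCCTCGTCATCA",
    ("23S", 1641): "GCAGCCAGCTGGTATCTTCGACTGATTTCAGC",
}


@dataclass(frozen=True)
class PrimerCandidate:
    """A designed blocker: DNA oligo, its 1-based closed annealing interval on
    the target, and its duplex Tm."""

    sequence: str
    target_ref: Optional[str]
    anneal_interval: tuple[int, int]
    tm: float
    kind: str  # "three_prime" | "hotspot"

    def __post_init__(self) -> None:
        lo, hi = self.anneal_interval
        if hi - lo + 1 != len(self.sequence):
            raise ValueError("primer length does not match annealing interval")


@dataclass(frozen=True)
class DesignResult:
    """Outcome of a thresholded design search; on failure ``candidate`` is the
    best (highest-Tm) design found within the search bounds."""

    accepted: bool
    candidate: PrimerCandidate


def _candidate(target_seq: str, start0: int, length: int, kind: str,
               cond: ThermoConditions, target_ref: Optional[str]) -> PrimerCandidate:
    sub = target_seq[start0 : start0 + length]
    return PrimerCandidate(
        sequence=revcomp(sub),
        target_ref=target_ref,
        anneal_interval=(start0 + 1, start0 + length),
        tm=tm_nearest_neighbor(revcomp(sub), cond),
        kind=kind,
    )


def design_3prime_blocker(
    target_seq: str,
    length: int = 30,
    cond: ThermoConditions = DEFAULT_CONDITIONS,
    target_ref: Optional[str] = None,
) -> PrimerCandidate:
    """Blocker for the 3' terminus: reverse complement of the last ``length``
    bases of the target.  Fixed-length by design (no Tm thresholding)."""
    if length < MIN_PRIMER_LEN:
        raise ValueError(f"blocker length must be >= {MIN_PRIMER_LEN}")
    if len(target_seq) < length:
        raise ValueError("target shorter than requested blocker length")
    target_seq = target_seq.upper()
    return _candidate(target_seq, len(target_seq) - length, length, "three_prime", cond, target_ref)


def design_hotspot_blocker(
    target_seq: str,
    hotspot_coord: int,
    offset: int = 100,
    length: int = 30,
    max_length: int = 36,
    shift_tolerance: int = 20,
    tm_min: float = 65.0,
    cond: ThermoConditions = DEFAULT_CONDITIONS,
    target_ref: Optional[str] = None,
) -> DesignResult:
    """Design a hotspot blocker annealing ~``offset`` nt downstream of
    ``hotspot_coord`` (1-based) on the target.

    The nominal interval starts at ``hotspot_coord + offset`` with length
    ``length``; candidates vary the length up to ``max_length`` and the start
    within ±``shift_tolerance`` nt (shifted into the target if the nominal
    interval runs off its end).  Among Tm-satisfying candidates the smallest
    design wins — shortest length, then least shifted, ties to the downstream
    shift.  If no candidate reaches ``tm_min`` the result is flagged
    unaccepted and carries the best (highest-Tm) candidate.
    """
    target_seq = target_seq.upper()
    if not 1 <= hotspot_coord <= len(target_seq):
        raise ValueError("hotspot_coord outside target")
    if length < MIN_PRIMER_LEN or max_length < length:
        raise ValueError("invalid length bounds")
    nominal0 = hotspot_coord - 1 + offset
    nominal0 = min(nominal0, len(target_seq) - length)  # shift in if it runs off the 3' end
    if nominal0 < 0:
        raise ValueError("target too short for any design at this hotspot")

    best: Optional[PrimerCandidate] = None
    for L in range(length, max_length + 1):
        for absshift in range(0, shift_tolerance + 1):
            for shift in ([0] if absshift == 0 else [absshift, -absshift]):
                start0 = nominal0 + shift
                if start0 < 0 or start0 + L > len(target_seq):
                    continue
                cand = _candidate(target_seq, start0, L, "hotspot", cond, target_ref)
                if cand.tm >= tm_min:
                    return DesignResult(True, cand)
                if best is None or cand.tm > best.tm:
                    best = cand
    if best is None:
        raise ValueError("no feasible candidate interval within search bounds")
    return DesignResult(False, best)


def anneal_interval(primer_seq: str, target_seq: str) -> Optional[tuple[int, int]]:
    """1-based closed interval where ``primer_seq`` anneals (its reverse
    complement occurs) on the sense-strand target, or None; leftmost match."""
    site = revcomp(primer_seq.upper())
    idx = target_seq.upper().find(site)
    if idx < 0:
        return None
    return idx + 1, idx + len(site)


def write_primers_tsv(primers: Sequence[PrimerCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target_ref\tkind\tstart\tend\tlength\ttm_celsius\tsequence\n")
        for p in primers:
            fh.write(
                f"{p.target_ref or '.'}\t{p.kind}\t{p.anneal_interval[0]}\t{p.anneal_interval[1]}\t"
                f"{len(p.sequence)}\t{p.tm:.2f}\t{p.sequence}\n"
            )
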