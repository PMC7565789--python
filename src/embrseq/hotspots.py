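"""Read-start hotspot profiling and calling on rRNA references.

Residual rRNA reads are not uniform along the transcript: besides the 3' end,
narrow "hotspot" regions contribute a disproportionate share of read starts
(a footprint of fragmentation plus capture bias).  The profile is the
per-position read-start histogram and its 5'->3' cumulative percentage curve;
hotspots are called where a sliding window holds several-fold more than its
uniform share of reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from embrseq.align import AlignmentRecord


@dataclass
class HotspotProfile:
    ref_id: str
    starts: np.ndarray          # per-position read-start counts, length = ref length
    cumulative: np.ndarray      # cumulative percentage 5'->3'; NaN-flagged when empty
    n_reads: int

    @property
    def defined(self) -> bool:
        return self.n_reads > 0


@dataclass(frozen=True)
class Hotspot:
    ref_id: str
    coordinate: int             # 1-based position of the read-start peak
    window: tuple[int, int]     # 1-based closed merged candidate region
    share: float                # fraction of the reference's reads starting in the region
    fold_over_uniform: float    # best single-window share over the uniform expectation


def readstart_profile(
    alignments: Iterable[AlignmentRecord],
    ref_id: str,
    ref_len: int,
    use_end: bool = False,
) -> HotspotProfile:
    """Per-position read-start histogram on one reference with its cumulative curve.

    ``use_end`` profiles the 3'-most aligned base instead of the start.  A
    zero-read profile is returned flagged (all-zero starts, NaN cumulative).
    """
    starts = np.zeros(ref_len, dtype=np.int64)
    for aln in alignments:
        if not aln.mapped or aln.ref_id != ref_id:
            continue
        pos = aln.pos + aln.aln_len - 1 if use_end else aln.pos
        if not 0 <= pos < ref_len:
            raise ValueError(f"alignment position {pos} outside reference of length {ref_len}")
        starts[pos] += 1
    n = int(starts.sum())
    if n == 0:
        cumulative = np.full(ref_len, np.nan)
    else:
        cumulative = 100.0 * np.cumsum(starts) / n
    return HotspotProfile(ref_id, starts, cumulative, n)


def call_hotspots(
    profile: HotspotProfile,
    window: int = 50,
    min_fold: float = 5.0,
    min_share: float = 0.02,
) -> list[Hotspot]:
    """Call hotspots from a read-start profile.

    Sliding windows of width ``window`` are candidates when their read share
    exceeds ``max(min_fold * window / ref_len, min_share)``; overlapping
    candidate windows are merged and each merged region is reported at the
    position of its read-start maximum (1-based), sorted by coordinate.
    """
    L = len(profile.starts)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > L:
        raise ValueError(f"window {window} exceeds reference length {L}")
    if min_fold <= 1:
        raise ValueError("min_fold must be > 1")
    if profile.n_reads == 0:
        return []

    counts = profile.starts.astype(float)
    win_counts = np.convolve(counts, np.ones(window), mode="valid")  # win_counts[i] = sum i..i+w-1
    shares = win_counts / profile.n_reads
    cutoff = max(min_fold * window / L, min_share)
    cand = np.flatnonzero(shares > cutoff)
    if cand.size == 0:
        return []

    # merge candidate windows that overlap (start gaps < window)
    regions: list[tuple[int, int]] = []
    region_start = int(cand[0])
    prev = int(cand[0])
    for i in cand[1:]:
        if i - prev < window:
            prev = int(i)
        else:
            regions.append((region_start, prev + window - 1))
            region_start = prev = int(i)
    regions.append((region_start, prev + window - 1))

    out = []
    for lo, hi in regions:
        region = profile.starts[lo : hi + 1]
        peak = lo + int(np.argmax(region))
        share = float(region.sum()) / profile.n_reads
        in_region = (cand >= lo) & (cand <= hi)
        fold = float(shares[cand[in_region]].max()) / (window / L)
        out.append(Hotspot(profile.ref_id, peak + 1, (lo + 1, hi + 1), share, fold))
    return sorted(out, key=lambda h: h.coordinate)


# ------------------------------------------------------------------- outputs


def write_profile_tsv(profile: HotspotProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tstarts\tcumulative_pct\n")
        for i, (c, cum) in enumerate(zip(profile.starts, profile.cumulative), start=1):
            fh.write(f"{i}\t{c}\t{cum:.4f}\n")


def write_hotspots_tsv(hotspots: Sequence[Hotspot], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_id\tcoordinate\twindow_lo\twindow_hi\tshare\tfold_over_uniform\n")
        for h in hotspots:
            fh.write(
                f"{h.ref_id}\t{h.coordinate}\t{h.window[0]}\t{h.window[1]}\t"
                f"{h.share:.6f}\t{h.fold_over_uniform:.3f}\n"
            )


def plot_cumulative(profiles: Sequence[HotspotProfile], path: str | Path) -> None:
    """Optional static figure of 5'->3' cumulative curves (one line per profile)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        if p.defined:
            ax.plot(np.arange(1, len(p.cumulative) + 1), p.cumulative, label=p.ref_id)
    ax.set_xlabel("position (5'->3')")
    ax.set_ylabel("cumulative % of reads")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
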