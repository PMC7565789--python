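"""Simulation configuration: the full parameterization of the capture model."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

_CLASSES = ("rRNA", "tRNA", "mRNA")


@dataclass(frozen=True)
class HotspotSpec:
    """A planted read-start hotspot: 1-based coordinate on a reference, with mixture weight."""

    ref_id: str
    coordinate: int  # 1-based
    weight: float

    def __post_init__(self) -> None:
        if self.coordinate < 1:
            raise ValueError("hotspot coordinate is 1-based and must be >= 1")
        if self.weight < 0:
            raise ValueError("hotspot weight must be non-negative")


@dataclass(frozen=True)
class Blocker:
    """A blocking-primer annealing interval (1-based closed) with suppression efficiency beta."""

    ref_id: str
    start: int
    end: int
    beta: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid blocker interval [{self.start}, {self.end}]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("blocker efficiency beta must lie in [0, 1]")


@dataclass
class SimConfig:
    """Generative-model parameters for simulated blocked-rRNA capture sequencing.

    Molecules are drawn from an RNA pool dominated by rRNA (``class_abundance``),
    poly-adenylated and captured with class-dependent probability
    (``polyA_baseline``; mRNA is preferentially tailed), optionally from
    fragment 3' ends (``frag_rate``) concentrated at read-start hotspots, and
    suppressed by blocking primers (``blockers``) whenever the molecule's 3'
    end falls within ``block_tolerance`` nt of a blocker interval.
    """

    # reference composition
    n_tRNA: int = 8
    n_mRNA: int = 60
    rRNA_lengths: tuple[int, ...] = (120, 1542, 2904)  # 5S/16S/23S-like
    tRNA_length: int = 76
    mRNA_length_range: tuple[int, int] = (300, 2000)

    # pool and capture
    class_abundance: dict[str, float] = field(
        default_factory=lambda: {"rRNA": 0.95, "tRNA": 0.03, "mRNA": 0.02}
    )
    per_gene_sigma: float = 1.0  # log-normal shape of mRNA gene weights
    polyA_baseline: dict[str, float] = field(
        default_factory=lambda: {"rRNA": 0.04, "tRNA": 0.01, "mRNA": 1.0}
    )

    # fragmentation / hotspots
    frag_rate: float = 0.0           # delta: P(3' end is a fragment end)
    hotspots: list[HotspotSpec] = field(default_factory=list)
    frag_uniform_weight: float = 1.5  # weight of the uniform fragment-end background per reference
    hotspot_jitter: int = 5           # tau_j, nt

    # blocking
    blockers: list[Blocker] = field(default_factory=list)
    block_tolerance: int = 20         # tau_b, nt

    # reads
    fragment_len: tuple[int, int] = (60, 160)
    read_len: int = 50
    error_rate: float = 0.001
    barcode: str = "AGACTC"
    n_reads: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_tRNA < 0 or self.n_mRNA < 0:
            raise ValueError("record counts must be non-negative")
        if any(l <= 0 for l in self.rRNA_lengths) or self.tRNA_length <= 0:
            raise ValueError("reference lengths must be positive")
        if self.mRNA_length_range[0] <= 0 or self.mRNA_length_range[0] > self.mRNA_length_range[1]:
            raise ValueError("invalid mRNA length range")
        for cls in _CLASSES:
            if cls not in self.class_abundance or cls not in self.polyA_baseline:
                raise ValueError(f"class_abundance/polyA_baseline must cover {cls}")
        if any(w < 0 for w in self.class_abundance.values()):
            raise ValueError("class abundances must be non-negative")
        if any(not 0.0 <= p <= 1.0 for p in self.polyA_baseline.values()):
            raise ValueError("polyA_baseline probabilities must lie in [0, 1]")
        if not 0.0 <= self.frag_rate <= 1.0:
            raise ValueError("frag_rate must lie in [0, 1]")
        if self.frag_uniform_weight < 0 or self.hotspot_jitter < 0 or self.block_tolerance < 0:
            raise ValueError("weights and tolerances must be non-negative")
        fmin, fmax = self.fragment_len
        if not (0 < fmin <= fmax):
            raise ValueError("invalid fragment_len range")
        if self.read_len <= 0:
            raise ValueError("read_len must be positive")
        if self.read_len > fmin:
            raise ValueError("read_len must not exceed the minimum fragment length")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if len(self.barcode) != 6 or not set(self.barcode) <= set("ACGT"):
            raise ValueError("barcode must be a 6-nt ACGT string")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")

    # ------------------------------------------------------------- serialization

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["rRNA_lengths"] = list(self.rRNA_lengths)
        d["mRNA_length_range"] = list(self.mRNA_length_range)
        d["fragment_len"] = list(self.fragment_len)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        for key, tup in (("rRNA_lengths", None), ("mRNA_length_range", None), ("fragment_len", None)):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "hotspots" in d:
            d["hotspots"] = [
                h if isinstance(h, HotspotSpec) else HotspotSpec(**h) for h in d["hotspots"]
            ]
        if "blockers" in d:
            d["blockers"] = [b if isinstance(b, Blocker) else Blocker(**b) for b in d["blockers"]]
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
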