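"""Read classification and rRNA-depletion / mRNA-enrichment quantification.

Mapped reads are classified rRNA/tRNA/mRNA by their reference's annotation;
class fractions use mapped reads as the denominator.  Depletion is the ratio
of control to treated rRNA fractions (e.g. 64% -> 16% is a 4-fold depletion),
enrichment the ratio of treated to control mRNA fractions.  Per-gene counts
feed RPM-threshold gene-detection curves, downsampling comparisons,
detection-overlap tallies and cross-sample expression correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from embrseq.align import AlignmentRecord

CLASSES = ("rRNA", "tRNA", "mRNA")


@dataclass
class ClassCounts:
    """Per-class and per-gene mapped-read tallies for one sample."""

    sample_id: str
    per_class: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASSES})
    per_gene: dict[str, int] = field(default_factory=dict)
    total_mapped: int = 0

    @property
    def fractions(self) -> dict[str, float]:
        if self.total_mapped == 0:
            return {c: float("nan") for c in CLASSES}
        return {c: self.per_class[c] / self.total_mapped for c in CLASSES}

    def rpm(self, gene_id: str, denominator: str = "mapped") -> float:
        """Reads-per-million for a gene; denominator 'mapped' (all classes) or 'mRNA'."""
        denom = self.total_mapped if denominator == "mapped" else self.per_class["mRNA"]
        if denom == 0:
            return float("nan")
        return self.per_gene.get(gene_id, 0) * 1e6 / denom

    def detected_genes(self) -> set[str]:
        return {g for g, n in self.per_gene.items() if n > 0}


def classify_and_count(
    alignments: Iterable[AlignmentRecord],
    annotation: Mapping[str, tuple[str, str]],
    sample_id: str = "sample",
) -> ClassCounts:
    """Tally mapped reads by class and by gene.

    ``annotation`` maps ref_id -> (class_label, gene_id) (see
    :func:`embrseq.reference.annotation_from_records`).  Unmapped records are
    ignored; a mapped record whose reference is unannotated raises, listing
    the offending ids.
    """
    counts = ClassCounts(sample_id)
    missing: set[str] = set()
    for aln in alignments:
        if not aln.mapped:
            continue
        entry = annotation.get(aln.ref_id)
        if entry is None:
            missing.add(aln.ref_id)
            continue
        class_label, gene_id = entry
        counts.per_class[class_label] = counts.per_class.get(class_label, 0) + 1
        counts.total_mapped += 1
        counts.per_gene[gene_id] = counts.per_gene.get(gene_id, 0) + 1
    if missing:
        raise ValueError(f"mapped reads hit unannotated references: {sorted(missing)}")
    return counts


@dataclass(frozen=True)
class DepletionMetrics:
    fold_rRNA_depletion: float
    fold_mRNA_enrichment: float
    infinite_depletion: bool = False


def depletion_metrics(test: ClassCounts, control: ClassCounts) -> DepletionMetrics:
    """Fold rRNA depletion (control/test rRNA fraction) and mRNA enrichment
    (test/control mRNA fraction).  Zero test rRNA reports infinite depletion
    with a flag rather than raising."""
    if test.total_mapped == 0 or control.total_mapped == 0:
        raise ValueError("both samples must have mapped reads")
    fc, ft = control.fractions, test.fractions
    if fc["rRNA"] == 0:
        raise ValueError("control rRNA fraction is zero; depletion undefined")
    if ft["rRNA"] == 0:
        depletion, infinite = float("inf"), True
    else:
        depletion, infinite = fc["rRNA"] / ft["rRNA"], False
    enrichment = ft["mRNA"] / fc["mRNA"] if fc["mRNA"] > 0 else float("inf")
    return DepletionMetrics(depletion, enrichment, infinite)


def downsample(
    alignments: Sequence[AlignmentRecord], depth: int, seed: int
) -> list[AlignmentRecord]:
    """Uniform sampling of exactly ``depth`` alignments without replacement."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if depth > len(alignments):
        raise ValueError(f"depth {depth} exceeds available reads ({len(alignments)})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(alignments), size=depth, replace=False)
    return [alignments[i] for i in sorted(idx)]


@dataclass
class DetectionCurve:
    thresholds: list[float]
    genes_detected: list[int]


def detection_curve(counts: ClassCounts, thresholds: Sequence[float]) -> DetectionCurve:
    """Genes with RPM strictly above each threshold (threshold 0 counts genes
    with at least one read).  RPM denominator is total mapped reads."""
    if counts.per_class["mRNA"] <= 0:
        raise ValueError("no mRNA reads; detection curve undefined")
    if any(t < 0 for t in thresholds):
        raise ValueError("thresholds must be non-negative")
    rpm = np.array([counts.rpm(g) for g in counts.per_gene])
    detected = [int((rpm > t).sum()) for t in thresholds]
    return DetectionCurve(list(thresholds), detected)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_genes: int
    defined: bool


def expression_correlation(a: ClassCounts, b: ClassCounts) -> CorrelationResult:
    """Pearson r of log10(RPM + 1) over the union of genes detected in either sample.

    Zero variance in either sample yields a flagged undefined result.
    """
    genes = sorted(a.detected_genes() | b.detected_genes())
    if len(genes) < 3:
        raise ValueError("need at least 3 genes detected in the union")
    xa = np.log10(np.array([a.rpm(g) for g in genes]) + 1.0)
    xb = np.log10(np.array([b.rpm(g) for g in genes]) + 1.0)
    if np.std(xa) < 1e-12 or np.std(xb) < 1e-12:
        return CorrelationResult(float("nan"), len(genes), False)
    r, _ = stats.pearsonr(xa, xb)
    return CorrelationResult(float(r), len(genes), True)


def detection_overlap(a: ClassCounts, b: ClassCounts) -> tuple[int, int, int]:
    """(only_a, only_b, both) gene counts over genes with >= 1 read."""
    ga, gb = a.detected_genes(), b.detected_genes()
    return len(ga - gb), len(gb - ga), len(ga & gb)


def pool_counts(samples: Sequence[ClassCounts], sample_id: str = "pooled") -> ClassCounts:
    """Sum counts across replicates (detection analyses pool replicates before thresholding)."""
    pooled = ClassCounts(sample_id)
    for s in samples:
        for c, n in s.per_class.items():
            pooled.per_class[c] = pooled.per_class.get(c, 0) + n
        for g, n in s.per_gene.items():
            pooled.per_gene[g] = pooled.per_gene.get(g, 0) + n
        pooled.total_mapped += s.total_mapped
    return pooled


# ------------------------------------------------------------------- outputs


def write_class_fractions(samples: Sequence[ClassCounts], path: str | Path) -> None:
    rows = []
    for s in samples:
        f = s.fractions
        rows.append({"sample_id": s.sample_id, "total_mapped": s.total_mapped, **f})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gene_matrix(samples: Sequence[ClassCounts], path: str | Path) -> None:
    genes = sorted(set().union(*(s.per_gene for s in samples))) if samples else []
    mat = pd.DataFrame(
        {s.sample_id: [s.per_gene.get(g, 0) for g in genes] for s in samples},
        index=pd.Index(genes, name="gene_id"),
    )
    mat.to_csv(path, sep="\t")
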