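"""Annotated reference transcriptomes: sequences with rRNA/tRNA/mRNA class labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

VALID_CLASSES = ("rRNA", "tRNA", "mRNA")
_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceRecord:
    ref_id: str
    sequence: str
    class_label: str
    gene_id: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for reference {self.ref_id!r}")
        if not _ALPHABET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _ALPHABET)
            raise ValueError(f"reference {self.ref_id!r} contains non-ACGT symbols: {bad}")
        if self.class_label not in VALID_CLASSES:
            raise ValueError(
                f"reference {self.ref_id!r}: class {self.class_label!r} not in {VALID_CLASSES}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSet:
    """An ordered collection of annotated transcript references.

    Invariants: ref_ids unique, sequences non-empty and A/C/G/T only
    (enforced at construction).
    """

    records: Sequence[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.ref_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ref_ids: {dup}")
        self._by_id = {r.ref_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    def __getitem__(self, ref_id: str) -> ReferenceRecord:
        return self._by_id[ref_id]

    @property
    def ref_ids(self) -> list[str]:
        return [r.ref_id for r in self.records]

    def by_class(self, class_label: str) -> list[ReferenceRecord]:
        return [r for r in self.records if r.class_label == class_label]

    def class_of(self, ref_id: str) -> str:
        return self._by_id[ref_id].class_label

    def length_of(self, ref_id: str) -> int:
        return len(self._by_id[ref_id])

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.ref_id}\n")
                for i in range(0, len(rec.sequence), width):
                    fh.write(rec.sequence[i : i + width] + "\n")

    def write_annotation(self, path: str | Path) -> None:
        """Tab-separated annotation: ref_id, class, gene_id."""
        with open(path, "w") as fh:
            fh.write("ref_id\tclass\tgene_id\n")
            for rec in self.records:
                fh.write(f"{rec.ref_id}\t{rec.class_label}\t{rec.gene_id}\n")

    @classmethod
    def read(cls, fasta_path: str | Path, annotation_path: str | Path) -> "ReferenceSet":
        """Load a reference set from FASTA + tab-separated annotation."""
        from Bio import SeqIO

        ann: dict[str, tuple[str, str]] = {}
        with open(annotation_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["ref_id", "class", "gene_id"]:
                raise ValueError(f"unexpected annotation header in {annotation_path}: {header}")
            for line in fh:
                if not line.strip():
                    continue
                ref_id, class_label, gene_id = line.rstrip("\n").split("\t")[:3]
                ann[ref_id] = (class_label, gene_id)
        records = []
        for seqrec in SeqIO.parse(str(fasta_path), "fasta"):
            if seqrec.id not in ann:
                raise ValueError(f"reference {seqrec.id!r} missing from annotation")
            class_label, gene_id = ann[seqrec.id]
            records.append(
                ReferenceRecord(seqrec.id, str(seqrec.seq).upper(), class_label, gene_id)
            )
        return cls(records)


def annotation_from_records(records: Iterable[ReferenceRecord]) -> dict[str, tuple[str, str]]:
    """Mapping ref_id -> (class_label, gene_id), the in-memory annotation form."""
    return {r.ref_id: (r.class_label, r.gene_id) for r in records}
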