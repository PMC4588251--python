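"""Reference genome container and FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """An in-memory reference: ordered map of contig name -> sequence.

    Sequences are uppercase strings over {A, C, G, T, N}.  Contig order is
    preserved and defines the sort order used downstream (SAM header order).
    """

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.contigs)
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
        self.contigs = {n: s.upper() for n, s in self.contigs.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.contigs.items()}

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        """0-based half-open subsequence, clamped to contig bounds."""
        seq = self.contigs[contig]
        return seq[max(0, start):min(len(seq), end)]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            contigs[rec.id] = str(rec.seq).upper()
        if not contigs:
            raise ValueError(f"no sequences found in {path}")
        return cls(contigs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")
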