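"""Core record types shared across the pipeline.

Coordinates are 1-based and inclusive throughout, matching the conventions
of gene-annotation tables (ORF intervals, signal-peptide ranges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class GeneRecord:
    """A coding nucleotide sequence with its annotated ORF interval.

    ``orf`` is a 1-based inclusive (start, end) interval on the forward
    strand of ``nt_seq``; the stop codon, when present, is included.
    ``complete5``/``complete3`` record whether the ORF begins with ATG and
    ends with a stop codon inside the given sequence (cloned cDNAs are
    frequently truncated at one end).
    """

    id: str
    nt_seq: str
    orf: Optional[tuple[int, int]] = None
    accession: str = ""
    complete5: bool = True
    complete3: bool = True

    def __post_init__(self) -> None:
        self.nt_seq = self.nt_seq.upper()
        bad = set(self.nt_seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: non-DNA characters {sorted(bad)}")
        if self.orf is not None:
            s, e = self.orf
            if not (1 <= s <= e <= len(self.nt_seq)):
                raise ValueError(f"record {self.id!r}: ORF {self.orf} out of bounds")
            if self.complete5 and self.complete3 and (e - s + 1) % 3:
                raise ValueError(f"record {self.id!r}: complete ORF length not a multiple of 3")

    @property
    def orf_seq(self) -> str:
        if self.orf is None:
            raise ValueError(f"record {self.id!r} has no ORF interval")
        s, e = self.orf
        return self.nt_seq[s - 1 : e]

    @property
    def orf_bp(self) -> int:
        s, e = self.orf
        return e - s + 1

    @property
    def is_complete(self) -> bool:
        return self.complete5 and self.complete3


@dataclass
class ProteinRecord:
    """A deduced protein sequence tied back to its source gene."""

    id: str
    aa_seq: str
    source_gene: str = ""

    def __post_init__(self) -> None:
        self.aa_seq = self.aa_seq.upper().rstrip("*")
        if not self.aa_seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if "*" in self.aa_seq:
            raise ValueError(f"protein {self.id!r}: internal stop symbol")

    def __len__(self) -> int:
        return len(self.aa_seq)


@dataclass
class SignalAnnotation:
    """An N-terminal signal peptide spanning residues 1..sp_end (1-based)."""

    protein_id: str
    sp_end: int
    source: str = "given"  # "given" | "predicted"
    score: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.sp_end < 1:
            raise ValueError("signal peptide length must be >= 1")
        if self.source not in ("given", "predicted"):
            raise ValueError(f"unknown annotation source {self.source!r}")
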