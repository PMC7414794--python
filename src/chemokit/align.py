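"""Protein-guided codon alignment of ortholog pairs.

Coding sequences are translated, the proteins globally aligned, and the
protein gaps projected back onto the codons ("back-translation"
alignment), so every alignment gap is codon-phased and the degapped rows
reproduce the inputs exactly. The protein alignment uses a fixed scoring
scheme (BLOSUM62, affine gaps) so results are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .orf import translate

GAP_CODON = "---"


@dataclass(frozen=True)
class CodonAlignment:
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned rows differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]

    def degapped(self) -> tuple[str, str]:
        return self.seq_a.replace("-", ""), self.seq_b.replace("-", "")


def _make_aligner(match_open: float = -11.0, extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = match_open
    aligner.extend_gap_score = extend
    aligner.mode = "global"
    return aligner


def codon_align(nt_a: str, nt_b: str, gap_open: float = -11.0,
                gap_extend: float = -1.0) -> CodonAlignment:
    """Codon-aware alignment of two coding sequences.

    Both inputs must translate cleanly (a terminal stop codon is allowed
    and is kept, aligned as its own column against a gap or another stop).
    """
    nt_a, nt_b = nt_a.upper(), nt_b.upper()
    stop_a = nt_a[-3:] if _has_terminal_stop(nt_a) else ""
    stop_b = nt_b[-3:] if _has_terminal_stop(nt_b) else ""
    core_a = nt_a[: len(nt_a) - len(stop_a)]
    core_b = nt_b[: len(nt_b) - len(stop_b)]
    aa_a, aa_b = translate(core_a, ambiguous="X"), translate(core_b, ambiguous="X")

    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(aa_a, aa_b)[0]  # first optimal alignment: deterministic
    row_a, row_b = str(aln[0]), str(aln[1])

    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        out_a.append(GAP_CODON if ca == "-" else core_a[3 * ia : 3 * ia + 3])
        out_b.append(GAP_CODON if cb == "-" else core_b[3 * ib : 3 * ib + 3])
        ia += ca != "-"
        ib += cb != "-"
    if stop_a or stop_b:
        out_a.append(stop_a or GAP_CODON)
        out_b.append(stop_b or GAP_CODON)
    return CodonAlignment("".join(out_a), "".join(out_b))


def _has_terminal_stop(nt: str) -> bool:
    return len(nt) % 3 == 0 and nt[-3:] in ("TAA", "TAG", "TGA")
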