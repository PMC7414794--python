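"""Open-reading-frame finding and translation.

ORFs are reported on the forward strand (cloned cDNA input), stop codon
included, as 1-based inclusive intervals. Truncated clones are common in
PCR-validated transcript sets, so runs cut off by the sequence ends can
be reported as partial ORFs with the matching completeness flag cleared.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .records import GeneRecord, ProteinRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


@dataclass(frozen=True)
class OrfHit:
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive; stop codon included when present
    frame: int          # 0, 1, 2 (offset of the first codon)
    complete5: bool     # starts with ATG
    complete3: bool     # ends with a stop codon

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_aa(self) -> int:
        """Amino acids encoded (the stop codon, if present, excluded)."""
        return (self.length - 3) // 3 if self.complete3 else self.length // 3


def translate(codon_seq: str, ambiguous: str = "error") -> str:
    """Translate a coding sequence with the standard genetic code.

    A terminal stop codon is dropped; an internal stop raises. ``ambiguous``
    is "error" (default) or "X" (N-containing codons become X).
    """
    seq = codon_seq.upper()
    if len(seq) % 3:
        raise ValueError(f"length {len(seq)} not divisible by 3")
    if "N" in seq and ambiguous != "X":
        raise ValueError("ambiguous base in coding sequence (policy 'error')")
    aa = str(Seq(seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(f"internal stop codon at aa position {aa.index('*') + 1}")
    return aa


def find_orfs(nt_seq: str, min_aa: int = 1, allow_partial: bool = False) -> list[OrfHit]:
    """Scan the three forward frames for ORFs.

    Complete ORFs run ATG -> stop inclusive (the longest per stop-free
    segment, i.e. from the first ATG). With ``allow_partial``, runs
    truncated at the 5' end (leading in-frame segment without a start) or
    at the 3' end (open run off the sequence end) are reported with the
    corresponding flag cleared. Results are sorted longest first, ties
    broken 5'-most.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = nt_seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    hits: list[OrfHit] = []
    for frame in range(3):
        codon_starts = range(frame, len(seq) - 2, 3)
        codons = [seq[i : i + 3] for i in codon_starts]
        # split the frame's codon string into stop-delimited segments
        seg_start = 0
        for k, codon in enumerate(codons + [None]):
            terminal = codon is None
            if not terminal and codon not in STOP_CODONS:
                continue
            seg = codons[seg_start:k]
            if seg or not terminal:
                hits.extend(
                    _segment_orfs(seg, seg_start, k, frame, terminal, allow_partial)
                )
            seg_start = k + 1
    hits = [h for h in hits if h.n_aa >= min_aa]
    hits.sort(key=lambda h: (-h.length, h.start))
    return hits


def _segment_orfs(seg, seg_start, seg_end, frame, terminal, allow_partial):
    """ORFs within one stop-free codon segment of a frame."""
    out = []
    pos = lambda ci: frame + 3 * ci + 1  # codon index -> 1-based nt position
    has_stop = not terminal
    atg = next((i for i, c in enumerate(seg) if c == START_CODON), None)
    if atg is not None:
        start = pos(seg_start + atg)
        if has_stop:
            out.append(OrfHit(start, pos(seg_end) + 2, frame, True, True))
        elif allow_partial and seg_end > seg_start + atg:
            out.append(OrfHit(start, pos(seg_end) - 1, frame, True, False))
    if allow_partial and seg_start == 0 and (atg is None or atg > 0):
        # leading in-frame run truncated at the 5' end
        if has_stop:
            out.append(OrfHit(pos(0), pos(seg_end) + 2, frame, False, True))
        elif seg:
            out.append(OrfHit(pos(0), pos(seg_end) - 1, frame, False, False))
    return out


def annotate_orf(record: GeneRecord, min_aa: int = 1, allow_partial: bool = True) -> GeneRecord:
    """Set the record's ORF to its longest ORF (ties: 5'-most start).

    Complete ORFs are preferred; a truncated run is used only when no
    complete ORF of at least ``min_aa`` exists (truncated clones).
    """
    hits = find_orfs(record.nt_seq, min_aa=min_aa, allow_partial=allow_partial)
    if not hits:
        record.orf = None
        return record
    complete = [h for h in hits if h.complete5 and h.complete3]
    top = complete[0] if complete else hits[0]
    record.orf = (top.start, top.end)
    record.complete5 = top.complete5
    record.complete3 = top.complete3
    return record


def deduce_protein(record: GeneRecord, ambiguous: str = "X") -> ProteinRecord:
    """Translate the record's annotated ORF into a ProteinRecord."""
    seq = record.orf_seq
    if not record.complete5:
        seq = seq[len(seq) % 3 :] if len(seq) % 3 else seq
    return ProteinRecord(id=record.id, aa_seq=translate(seq, ambiguous=ambiguous),
                         source_gene=record.id)
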