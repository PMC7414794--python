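"""Cysteine-signature extraction and OBP/CSP subclass assignment.

Insect odorant-binding proteins fall into subclasses defined by the
number and spacing of their conserved cysteines; chemosensory proteins
carry a distinct four-cysteine signature. The spacing patterns used here
(X_n = number of residues strictly between consecutive labelled
cysteines; X_a-b = an inclusive range):

    Classic OBP  C1-X22-32-C2-X3-C3-X30-47-C4-X8-10-C5-X8-C6
    Minus-C OBP  C1-X32-C3-X36-46-C4-X18-C6          (C2, C5 absent)
    Plus-C  OBP  C1-X22-35-C2-X3-C3-X43-C4-X23-25-C4a-X9-C5-X8-C6-P-X9-C6a-X13-26
    CSP          C1-X6-C2-X18-C3-X2-C4

Two assignment modes are provided. ``count_based`` (default) assigns by
cysteine count — six for Classic, four for Minus-C (disambiguated from
CSP by the CSP gap check), eight to ten with the conserved
cysteine-proline dyad for Plus-C. ``strict`` additionally requires every
inter-cysteine spacing to satisfy the pattern, with singleton printed
spacings widened by a +/- tolerance (default 2) because such patterns
summarize an alignment of real, slightly variable sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import ProteinRecord, SignalAnnotation
from .signal import trim_signal

LABEL_CLASSIC = "Classic"
LABEL_MINUS_C = "Minus-C"
LABEL_PLUS_C = "Plus-C"
LABEL_CSP = "CSP"
LABEL_UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class CysteineSignature:
    """Ordered cysteine positions (1-based) in a mature protein and the
    residue counts strictly between consecutive cysteines."""

    positions: tuple[int, ...]
    spacings: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ClassMotif:
    """Declarative spacing constraints for one subclass.

    ``gap_constraints`` are (min, max) inclusive residue counts between
    consecutive labelled cysteines. ``singleton`` marks gaps printed as a
    single value, which receive the strict-mode tolerance window.
    """

    name: str
    required_cys: int
    gap_constraints: tuple[tuple[int, int], ...]
    singleton: tuple[bool, ...]
    proline_after: int | None = None      # labelled cysteine index (0-based) with P at +1
    tail_range: tuple[int, int] | None = None  # residues after the last cysteine

    def widened(self, tol: int) -> list[tuple[int, int]]:
        return [
            (max(0, lo - tol), hi + tol) if single else (lo, hi)
            for (lo, hi), single in zip(self.gap_constraints, self.singleton)
        ]


CLASSIC_MOTIF = ClassMotif(
    LABEL_CLASSIC, 6,
    gap_constraints=((22, 32), (3, 3), (30, 47), (8, 10), (8, 8)),
    singleton=(False, True, False, False, True),
)
MINUS_C_MOTIF = ClassMotif(
    LABEL_MINUS_C, 4,
    gap_constraints=((32, 32), (36, 46), (18, 18)),
    singleton=(True, False, True),
)
# Labelled order C1 C2 C3 C4 C4a C5 C6 C6a; the C6-C6a gap of 10 residues
# is the conserved proline plus nine others.
PLUS_C_MOTIF = ClassMotif(
    LABEL_PLUS_C, 8,
    gap_constraints=((22, 35), (3, 3), (43, 43), (23, 25), (9, 9), (8, 8), (10, 10)),
    singleton=(False, True, True, False, True, True, True),
    proline_after=6,
    tail_range=(13, 26),
)
CSP_MOTIF = ClassMotif(
    LABEL_CSP, 4,
    gap_constraints=((6, 6), (18, 18), (2, 2)),
    singleton=(True, True, True),
)

CLASS_MOTIFS = {
    m.name: m for m in (CLASSIC_MOTIF, MINUS_C_MOTIF, PLUS_C_MOTIF, CSP_MOTIF)
}

DEFAULT_TOLERANCE = 2


@dataclass
class ClassAssignment:
    protein_id: str
    label: str
    mode: str
    diagnostics: dict = field(default_factory=dict)


def cys_signature(mature: str) -> CysteineSignature:
    """Positions and spacings of every cysteine in a mature protein."""
    if not mature:
        raise ValueError("empty mature protein")
    positions = tuple(i + 1 for i, a in enumerate(mature.upper()) if a == "C")
    spacings = tuple(
        positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)
    )
    return CysteineSignature(positions, spacings)


def motif_diagnostics(sig: CysteineSignature, mature: str, motif: ClassMotif,
                      tol: int = DEFAULT_TOLERANCE) -> dict:
    """Per-constraint pass/fail of a signature against one class pattern."""
    diag: dict = {"count": sig.count == motif.required_cys}
    if sig.count == motif.required_cys:
        for i, ((lo, hi), gap) in enumerate(zip(motif.widened(tol), sig.spacings)):
            diag[f"gap_{i + 1}"] = lo <= gap <= hi
    if motif.proline_after is not None and sig.count == motif.required_cys:
        cpos = sig.positions[motif.proline_after]
        diag["proline_after_c6"] = cpos < len(mature) and mature[cpos] == "P"
    if motif.tail_range is not None and sig.count == motif.required_cys:
        lo, hi = motif.tail_range
        tail = len(mature) - sig.positions[-1]
        diag["tail"] = lo - tol <= tail <= hi + tol
    return diag


def matches_strict(sig: CysteineSignature, mature: str, motif: ClassMotif,
                   tol: int = DEFAULT_TOLERANCE) -> bool:
    return all(motif_diagnostics(sig, mature, motif, tol).values())


def check_csp(sig: CysteineSignature, mature: str,
              tol: int = DEFAULT_TOLERANCE) -> tuple[bool, dict]:
    """True iff exactly four cysteines spaced per the CSP signature."""
    diag = motif_diagnostics(sig, mature, CSP_MOTIF, tol)
    return all(diag.values()), diag


def _has_cys_pro_dyad(sig: CysteineSignature, mature: str) -> bool:
    """Conserved proline immediately after a non-terminal cysteine (the
    Plus-C C6-P hallmark)."""
    return any(
        p < len(mature) and mature[p] == "P" for p in sig.positions[:-1]
    )


def assign_class(sig: CysteineSignature, mature: str, mode: str = "count_based",
                 family_hint: str | None = None,
                 tol: int = DEFAULT_TOLERANCE) -> ClassAssignment:
    """Assign an OBP subclass or CSP status to one mature protein.

    ``family_hint`` ("OBP" or "CSP") settles the four-cysteine ambiguity
    when the candidate family is known; otherwise the CSP gap check wins
    if it passes strictly.
    """
    if mode not in ("count_based", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    if family_hint not in (None, "OBP", "CSP"):
        raise ValueError(f"unknown family hint {family_hint!r}")
    if sig.positions and sig.positions[-1] > len(mature):
        raise ValueError("signature extends beyond the mature protein")

    label = LABEL_UNCLASSIFIED
    if sig.count == 6:
        label = LABEL_CLASSIC
    elif sig.count == 4:
        if family_hint == "OBP":
            label = LABEL_MINUS_C
        elif family_hint == "CSP":
            label = LABEL_CSP
        else:
            csp_ok, _ = check_csp(sig, mature, tol)
            label = LABEL_CSP if csp_ok else LABEL_MINUS_C
    elif 8 <= sig.count <= 10 and _has_cys_pro_dyad(sig, mature):
        label = LABEL_PLUS_C

    diagnostics = {}
    if label != LABEL_UNCLASSIFIED:
        diagnostics = motif_diagnostics(sig, mature, CLASS_MOTIFS[label], tol)
    if mode == "strict":
        if label == LABEL_UNCLASSIFIED or not all(diagnostics.values()):
            label = LABEL_UNCLASSIFIED
    return ClassAssignment(protein_id="", label=label, mode=mode,
                           diagnostics=diagnostics)


def classify_family(
    proteins: list[ProteinRecord],
    annotations: dict[str, SignalAnnotation] | None = None,
    mode: str = "count_based",
    family_hints: dict[str, str] | None = None,
    partial_ids: set[str] | None = None,
    tol: int = DEFAULT_TOLERANCE,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify a set of proteins; returns the per-protein table and the
    class counts over full-length proteins.

    ``annotations`` maps protein id to a signal-peptide annotation (the
    mature region is classified); un-annotated proteins are taken as
    already mature. Partial proteins (``partial_ids``) are flagged and
    excluded from the counts.
    """
    annotations = annotations or {}
    family_hints = family_hints or {}
    partial_ids = partial_ids or set()
    rows = []
    for prot in proteins:
        ann = annotations.get(prot.id)
        mature = trim_signal(prot, ann) if ann is not None else prot.aa_seq
        sig = cys_signature(mature)
        asg = assign_class(sig, mature, mode=mode,
                           family_hint=family_hints.get(prot.id), tol=tol)
        rows.append({
            "protein_id": prot.id,
            "label": asg.label,
            "n_cys": sig.count,
            "spacings": "-".join(map(str, sig.spacings)),
            "partial": prot.id in partial_ids,
        })
    table = pd.DataFrame(
        rows, columns=["protein_id", "label", "n_cys", "spacings", "partial"]
    )
    if table.empty:
        return table, {}
    full = table[~table["partial"].astype(bool)]
    counts = full["label"].value_counts().to_dict()
    return table, counts
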