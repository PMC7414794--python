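"""Signal-peptide handling: trimming annotated peptides and a light
position-weight-matrix cleavage predictor.

Secretory signal peptides of odorant-binding and chemosensory proteins
are short N-terminal tags (typically 15-27 residues in these families)
with a hydrophobic core and small residues at the -3 and -1 positions
relative to the cleavage site (the classical (-3,-1) rule). Externally
supplied annotations are the primary path; the predictor is a fallback
and its output is always labelled ``source="predicted"``.
"""

from __future__ import annotations

import warnings

from .records import ProteinRecord, SignalAnnotation

# Kyte-Doolittle hydropathy, used for the hydrophobic-core term.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

# Log-odds for the -3 and -1 positions: small/neutral residues favoured.
SMALL_RESIDUE_LOGODDS = {
    "A": 1.4, "G": 1.1, "S": 1.1, "C": 0.7, "T": 0.5,
}
_DEFAULT_PENALTY = -1.5
CORE_WEIGHT = 0.5
DEFAULT_WINDOW = (10, 40)


def trim_signal(protein: ProteinRecord, ann: SignalAnnotation) -> str:
    """Mature protein: residues sp_end+1 .. end."""
    k = ann.sp_end
    if k >= len(protein.aa_seq):
        raise ValueError(
            f"{protein.id}: signal peptide ({k} aa) covers the whole protein"
        )
    mature = protein.aa_seq[k:]
    if len(mature) == 1:
        warnings.warn(f"{protein.id}: single-residue mature protein", stacklevel=2)
    return mature


def _position_score(aa_seq: str, k: int, matrix: dict[str, float]) -> float:
    """Score cleavage after residue k: (-3,-1) box + hydrophobic core."""
    box = matrix.get(aa_seq[k - 3], _DEFAULT_PENALTY) + matrix.get(
        aa_seq[k - 1], _DEFAULT_PENALTY
    )
    core = aa_seq[max(1, k - 13) : k - 3]
    core_term = 0.0
    if core:
        core_term = CORE_WEIGHT * sum(KYTE_DOOLITTLE.get(a, 0.0) for a in core) / len(core)
    return box + core_term


def predict_cleavage(
    protein: ProteinRecord,
    weight_matrix: dict[str, float] | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> SignalAnnotation | None:
    """Predict the signal-peptide cleavage position within ``window``.

    Returns the highest-scoring position (signal peptide = residues
    1..k), or None when no position scores above zero ("no signal").
    Deterministic for a fixed matrix and input; ties go to the 5'-most
    position.
    """
    lo, hi = window
    if lo < 4:
        raise ValueError("window start must leave room for the -3..-1 box")
    if len(protein.aa_seq) <= lo:
        raise ValueError(f"{protein.id}: protein shorter than the search window")
    matrix = SMALL_RESIDUE_LOGODDS if weight_matrix is None else weight_matrix
    hi = min(hi, len(protein.aa_seq) - 1)
    best_k, best_score = None, 0.0
    for k in range(lo, hi + 1):
        s = _position_score(protein.aa_seq, k, matrix)
        if s > best_score:
            best_k, best_score = k, s
    if best_k is None:
        return None
    return SignalAnnotation(protein.id, best_k, source="predicted", score=best_score)
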