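"""Theoretical molecular mass and isoelectric point of proteins.

Molecular mass is the sum of average (not monoisotopic) residue masses
plus one water, as standard proteomics servers report it. The
isoelectric point solves net charge = 0 under Henderson-Hasselbalch
with the Bjellqvist pKa set (side chains D, E, C, Y, H, K, R plus the
termini; the N-terminal pKa depends on the first residue). Net charge
is strictly decreasing in pH, so the root is unique and bisection
suffices.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

# Average residue masses, Da.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# Bjellqvist pKa values.
BJELLQVIST_PKA = {
    "side": {"C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0,
             "Y": 10.0},
    "cterm": 3.55,
    "nterm_default": 7.5,
    "nterm": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44,
              "E": 7.7, "G": 7.5},
}

NEGATIVE = ("D", "E", "C", "Y")
POSITIVE = ("H", "K", "R")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up rounding for table reporting (0.125 -> 0.13 at 2 dp)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _check(aa_seq: str) -> str:
    seq = aa_seq.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - set(AVERAGE_RESIDUE_MASS)
    if bad:
        raise ValueError(f"nonstandard residues {sorted(bad)}")
    return seq


def molecular_weight(aa_seq: str) -> float:
    """Average molecular mass in daltons."""
    seq = _check(aa_seq)
    return sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_MASS


def net_charge(aa_seq: str, ph: float, pka: dict = BJELLQVIST_PKA) -> float:
    """Net protein charge at a given pH (Henderson-Hasselbalch)."""
    seq = _check(aa_seq)
    side = pka["side"]
    nterm_pka = pka["nterm"].get(seq[0], pka["nterm_default"])
    charge = 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    charge -= 1.0 / (1.0 + 10 ** (pka["cterm"] - ph))
    for aa in seq:
        if aa in POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - side[aa]))
        elif aa in NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (side[aa] - ph))
    return charge


def isoelectric_point(aa_seq: str, tol: float = 1e-4, pka: dict = BJELLQVIST_PKA) -> float:
    """pH at which the net charge crosses zero, by bisection."""
    seq = _check(aa_seq)
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def physchem_profile(protein_id: str, aa_seq: str) -> dict:
    """Reported-profile dict: MW in kDa and pI, both half-up at 2 dp."""
    return {
        "protein_id": protein_id,
        "mw_kda": round_half_up(molecular_weight(aa_seq) / 1000.0),
        "pi": round_half_up(isoelectric_point(aa_seq)),
    }
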