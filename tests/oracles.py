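"""Independent reference implementations used only by the tests.

Each oracle re-derives an expected result by a different route than the
package (brute-force scans, exhaustive enumeration, grid search,
textbook two-step formulas) so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


# ---------------------------------------------------------------- ORFs
def orf_scan_oracle(seq: str, min_aa: int = 1, allow_partial: bool = False):
    """Exhaustive forward-frame ORF scan; returns tuples
    (start, end, frame, complete5, complete3), sorted like find_orfs."""
    seq = seq.upper()
    hits = []
    for frame in range(3):
        starts = list(range(frame, len(seq) - 2, 3))
        codons = [seq[i : i + 3] for i in starts]
        segments = []  # (codon indices, stop index or None)
        cur = []
        for ci, c in enumerate(codons):
            if c in STOPS:
                segments.append((cur, ci))
                cur = []
            else:
                cur.append(ci)
        segments.append((cur, None))
        for seg_i, (content, stop_ci) in enumerate(segments):
            leading = seg_i == 0
            atgs = [ci for ci in content if codons[ci] == "ATG"]
            if stop_ci is not None:
                if atgs:
                    hits.append((starts[atgs[0]] + 1, starts[stop_ci] + 3,
                                 frame, True, True))
                if allow_partial and leading and content and (
                    not atgs or atgs[0] != content[0]
                ):
                    hits.append((frame + 1, starts[stop_ci] + 3, frame, False, True))
                if allow_partial and leading and not content:
                    pass  # stop in the first codon: nothing before it
            else:
                if not content:
                    continue
                last_end = starts[content[-1]] + 3
                if allow_partial and atgs:
                    hits.append((starts[atgs[0]] + 1, last_end, frame, True, False))
                if allow_partial and leading and (not atgs or atgs[0] != content[0]):
                    hits.append((frame + 1, last_end, frame, False, False))
    kept = []
    for s, e, f, c5, c3 in hits:
        length = e - s + 1
        n_aa = (length - 3) // 3 if c3 else length // 3
        if n_aa >= min_aa:
            kept.append((s, e, f, c5, c3))
    kept.sort(key=lambda h: (-(h[1] - h[0] + 1), h[0]))
    return kept


# ------------------------------------------------------ classification
SPACING_PATTERNS = {
    "Classic": {"gaps": [(22, 32), (3, 3), (30, 47), (8, 10), (8, 8)],
                "single": [False, True, False, False, True], "cys": 6},
    "Minus-C": {"gaps": [(32, 32), (36, 46), (18, 18)],
                "single": [True, False, True], "cys": 4},
    "Plus-C": {"gaps": [(22, 35), (3, 3), (43, 43), (23, 25), (9, 9), (8, 8), (10, 10)],
               "single": [False, True, True, False, True, True, True], "cys": 8,
               "tail": (13, 26)},
    "CSP": {"gaps": [(6, 6), (18, 18), (2, 2)],
            "single": [True, True, True], "cys": 4},
}


def strict_label_oracle(mature: str, tol: int = 2) -> str:
    """Declarative pattern match over the cysteine spacing vector."""
    positions = [i + 1 for i, a in enumerate(mature) if a == "C"]
    gaps = [b - a - 1 for a, b in zip(positions, positions[1:])]
    for name, pat in SPACING_PATTERNS.items():
        if len(positions) != pat["cys"]:
            continue
        ok = True
        for (lo, hi), single, g in zip(pat["gaps"], pat["single"], gaps):
            if single:
                lo, hi = lo - tol, hi + tol
            if not lo <= g <= hi:
                ok = False
                break
        if name == "Plus-C" and ok:
            c6 = positions[-2]
            ok = c6 < len(mature) and mature[c6] == "P"
            tail = len(mature) - positions[-1]
            lo, hi = pat["tail"]
            ok = ok and (lo - tol <= tail <= hi + tol)
        if ok:
            return name
    return "Unclassified"


# ----------------------------------------------------------- NG86 sites
def ng86_codon_sites_oracle(codon: str) -> tuple[float, float]:
    """Enumerate all nine single-base changes explicitly."""
    aa = GENETIC_CODE[codon]
    syn = sense = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mut] == "*":
                continue
            sense += 1
            if GENETIC_CODE[mut] == aa:
                syn += 1
    return syn / 3.0, (sense - syn) / 3.0


def ng86_pair_differences_oracle(c1: str, c2: str):
    """Path-averaged (Sd, Nd), dropping stop-crossing paths."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    return (sum(t[0] for t in totals) / len(totals),
            sum(t[1] for t in totals) / len(totals))


# ------------------------------------------------------------------ pI
def pi_grid_oracle(aa_seq: str, pka: dict, step: float = 0.001) -> float:
    """Grid scan for the zero crossing of the net charge."""
    grid = np.arange(0.0, 14.0 + step, step)
    seq = aa_seq.upper()
    nterm = pka["nterm"].get(seq[0], pka["nterm_default"])
    charge = 1.0 / (1.0 + 10 ** (grid - nterm))
    charge -= 1.0 / (1.0 + 10 ** (pka["cterm"] - grid))
    for aa, k in pka["side"].items():
        count = seq.count(aa)
        if not count:
            continue
        if aa in ("H", "K", "R"):
            charge += count / (1.0 + 10 ** (grid - k))
        else:
            charge -= count / (1.0 + 10 ** (k - grid))
    return float(grid[np.argmin(np.abs(charge))])


# --------------------------------------------------------- nested ANOVA
def nested_anova_f_oracle(values: np.ndarray) -> float:
    """Two-step nested ANOVA F (tissues / bioreps-within-tissue) on a
    balanced (tissue, bio_rep, tech_rep) array."""
    a, b, t = values.shape
    grand = values.mean()
    tissue_means = values.mean(axis=(1, 2))
    cell_means = values.mean(axis=2)
    ss_a = b * t * ((tissue_means - grand) ** 2).sum()
    ss_b = t * ((cell_means - tissue_means[:, None]) ** 2).sum()
    ms_a = ss_a / (a - 1)
    ms_b = ss_b / (a * (b - 1))
    return float(ms_a / ms_b)


# -------------------------------------------- best non-overlapping hits
def best_nonoverlap_oracle(hits):
    """Exhaustive search: the non-overlapping subset whose descending
    score vector is lexicographically maximal (hits = (start, width,
    score) with distinct scores)."""
    n = len(hits)
    best_key, best_set = None, []
    for mask in range(1 << n):
        chosen = [hits[i] for i in range(n) if mask >> i & 1]
        spans = sorted((h[0], h[0] + h[1]) for h in chosen)
        if any(b1 > a2 for (_, b1), (a2, _) in zip(spans, spans[1:])):
            continue
        key = tuple(sorted((h[2] for h in chosen), reverse=True))
        if best_key is None or key > best_key:
            best_key, best_set = key, chosen
    return sorted(best_set)
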