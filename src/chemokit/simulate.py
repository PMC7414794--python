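"""Synthetic data with planted ground truth for every pipeline stage.

Generators emulate the structure of an insect OBP/CSP gene set: mature
proteins whose cysteines are placed by sampling spacings inside each
subclass's signature ranges, signal peptides with a hydrophobic core
and small residues at the -3/-1 positions (15-27 aa), coding sequences
by random synonymous back-translation, codon ortholog pairs evolved
under a chosen dN/dS, planted motif architectures, and long-format Ct
tables with planted tissue effects.

Randomness: one seed in SimSpec; each generator draws from its own
substream derived by stable hashing of the operation name, so adding a
generator does not shift the streams of the others. Same spec, same
bytes out.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CLASS_MOTIFS, LABEL_PLUS_C
from .records import GeneRecord, ProteinRecord
from .align import CodonAlignment
from .kaks import OrthologPair, _codon_table

# mature-region / flank background: all standard residues except C, so
# planted cysteines are exactly the signature
BACKGROUND_AA = "ADEFGHIKLMNPQRSTVWY"
HYDROPHOBIC_CORE = "LIVF"
SMALL_MINUS = "AGS"      # -3 / -1 residues of the cleavage box
POLAR = "DENQST"

SENSE_CODONS = None
STOP_CODONS = ("TAA", "TAG", "TGA")


def _sense_codons() -> list[str]:
    global SENSE_CODONS
    if SENSE_CODONS is None:
        code = _codon_table()
        SENSE_CODONS = sorted(c for c, aa in code.items() if aa != "*")
    return SENSE_CODONS


@dataclass
class SimSpec:
    """Study-condition parameters for the generators.

    Defaults mirror the real gene set: signal peptides 15-27 aa,
    full-length proteins 124-260 aa, three biological x three technical
    qPCR replicates, leg as the calibrator tissue.
    """

    seed: int = 0
    n: int = 50
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"Classic": 26 / 38, "Minus-C": 10 / 38, "Plus-C": 2 / 38}
    )
    sp_len_range: tuple[int, int] = (15, 27)
    protein_len_range: tuple[int, int] = (124, 260)
    # ortholog-pair evolution
    n_pairs: int = 50
    n_codons: int = 300
    omega: float = 0.2
    branch_len: float = 0.4        # expected mutation proposals per base
    # Ct table design
    tissues: tuple[str, ...] = ("antennae", "head", "thorax", "abdomen", "leg")
    calibrator: str = "leg"
    reference_gene: str = "rps3"
    ct_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    bio_reps: int = 3
    tech_reps: int = 3
    ct_noise_sd: float = 0.2

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")


def substream(spec_seed: int, op_name: str) -> np.random.Generator:
    """Deterministic per-operation RNG substream."""
    return np.random.default_rng(
        (int(spec_seed) & 0x7FFFFFFF, zlib.crc32(op_name.encode()) & 0x7FFFFFFF)
    )


def _draw(rng, letters: str, n: int) -> str:
    return "".join(rng.choice(list(letters), size=n))


def _sample_spacings(rng, motif) -> list[int]:
    return [int(rng.integers(lo, hi + 1)) for lo, hi in motif.gap_constraints]


def _mature_protein(rng, label: str, target_len: int) -> str:
    """Mature protein with the class's cysteine signature planted."""
    motif = CLASS_MOTIFS[label]
    for _ in range(100):
        spacings = _sample_spacings(rng, motif)
        parts = []
        for gap in spacings:
            parts.append("C")
            parts.append(_draw(rng, BACKGROUND_AA, gap))
        parts.append("C")
        core = "".join(parts)
        if label == LABEL_PLUS_C:
            # conserved proline immediately after C6 (second-to-last C)
            c_positions = [i for i, a in enumerate(core) if a == "C"]
            p_at = c_positions[-2] + 1
            core = core[:p_at] + "P" + core[p_at + 1 :]
            tail_lo, tail_hi = motif.tail_range
            tail = int(rng.integers(tail_lo, tail_hi + 1))
        else:
            tail = None
        lead_max = target_len - len(core) - (tail if tail is not None else 3)
        if lead_max < 2:
            continue
        lead = int(rng.integers(2, min(lead_max, 20) + 1))
        if tail is None:
            tail = target_len - len(core) - lead
            if tail < 3:
                continue
        return _draw(rng, BACKGROUND_AA, lead) + core + _draw(rng, BACKGROUND_AA, tail)
    raise RuntimeError(f"could not place {label} signature in {target_len} residues")


def _signal_peptide(rng, length: int) -> str:
    """M + charged n-region + hydrophobic core + (-3,-1)-rule box."""
    n_region = _draw(rng, "KRNQ", 2)
    core_len = length - 1 - len(n_region) - 3
    core = _draw(rng, HYDROPHOBIC_CORE, core_len)
    box = rng.choice(list(SMALL_MINUS)) + rng.choice(list(POLAR)) + rng.choice(list(SMALL_MINUS))
    return "M" + n_region + core + box


def back_translate(rng, aa_seq: str, add_stop: bool = True) -> str:
    """Random synonymous back-translation with the standard code."""
    code = _codon_table()
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(code.items()):
        if aa != "*":
            by_aa.setdefault(aa, []).append(codon)
    codons = [by_aa[a][rng.integers(0, len(by_aa[a]))] for a in aa_seq]
    if add_stop:
        codons.append(STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def gen_family(spec: SimSpec) -> tuple[list[GeneRecord], list[ProteinRecord], pd.DataFrame]:
    """Gene + protein records with a planted truth table (class,
    signal-peptide end, mature segment)."""
    rng = substream(spec.seed, "gen_family")
    labels = list(spec.class_mix)
    probs = np.array([spec.class_mix[l] for l in labels])
    genes, proteins, truth = [], [], []
    for i in range(spec.n):
        label = labels[rng.choice(len(labels), p=probs)]
        sp_len = int(rng.integers(spec.sp_len_range[0], spec.sp_len_range[1] + 1))
        motif = CLASS_MOTIFS[label]
        min_mature = (
            motif.required_cys
            + sum(lo for lo, _ in motif.gap_constraints)
            + (motif.tail_range[0] if motif.tail_range else 3)
            + 2
        )
        lo_total = max(spec.protein_len_range[0], min_mature + sp_len)
        if lo_total > spec.protein_len_range[1]:
            raise ValueError(
                f"{label}: protein_len_range too short for the class signature"
            )
        total_len = int(rng.integers(lo_total, spec.protein_len_range[1] + 1))
        mature = _mature_protein(rng, label, total_len - sp_len)
        sp = _signal_peptide(rng, sp_len)
        aa = sp + mature
        pid = f"sim{i + 1:03d}"
        nt = back_translate(rng, aa)
        genes.append(GeneRecord(id=pid, nt_seq=nt, orf=(1, len(nt))))
        proteins.append(ProteinRecord(id=pid, aa_seq=aa, source_gene=pid))
        truth.append({"protein_id": pid, "class": label, "sp_end": sp_len,
                      "mature": mature})
    return genes, proteins, pd.DataFrame(
        truth, columns=["protein_id", "class", "sp_end", "mature"]
    )


def _evolve_codon(rng, codon: str, omega: float, n_events: int, code) -> str:
    cur = codon
    for _ in range(n_events):
        pos = int(rng.integers(0, 3))
        base = "ACGT"[rng.integers(0, 4)]
        if base == cur[pos]:
            continue
        cand = cur[:pos] + base + cur[pos + 1 :]
        if code[cand] == "*":
            continue  # stop-creating proposals rejected
        if code[cand] == code[cur] or rng.random() < omega:
            cur = cand
    return cur


def gen_ortholog_pairs(spec: SimSpec) -> tuple[list[OrthologPair], float]:
    """Codon ortholog pairs evolved under dN/dS = spec.omega.

    The ancestor is sampled from the sense codons; the descendant
    receives Poisson(3 x branch_len) single-base proposals per codon,
    synonymous proposals always accepted, nonsynonymous with
    probability omega, stop-creating proposals rejected.
    """
    if spec.omega < 0:
        raise ValueError("omega must be >= 0")
    rng = substream(spec.seed, "gen_ortholog_pairs")
    code = _codon_table()
    sense = _sense_codons()
    pairs = []
    for p in range(spec.n_pairs):
        anc_codons = [sense[rng.integers(0, len(sense))] for _ in range(spec.n_codons)]
        n_events = rng.poisson(3.0 * spec.branch_len, size=spec.n_codons)
        desc = [
            _evolve_codon(rng, c, spec.omega, int(k), code)
            for c, k in zip(anc_codons, n_events)
        ]
        aln = CodonAlignment("".join(anc_codons), "".join(desc))
        pairs.append(OrthologPair(f"anc{p + 1:03d}", f"desc{p + 1:03d}", aln))
    return pairs, spec.omega


def truth_category(folds: dict[str, float], fold_specific: float = 50.0,
                   enrich_min: float = 4.0) -> str:
    """Planted-truth enrichment category implied by a fold vector."""
    items = sorted(folds.items(), key=lambda kv: -kv[1])
    top, top_fold = items[0]
    others = [f for _, f in items[1:]]
    if not others:
        return "broad"
    ratios = [top_fold / f for f in others]
    if min(ratios) >= fold_specific:
        return f"tissue_specific({top})"
    if min(ratios) >= enrich_min:
        return f"tissue_enriched({top})"
    return "broad"


def gen_ct_table(spec: SimSpec) -> tuple[pd.DataFrame, dict[str, str]]:
    """Long-format Ct table with planted tissue effects.

    Fold effects are planted on the Ct scale (one doubling = -1 cycle):
    target Ct = base - log2(fold_tissue) + noise. The reference gene is
    flat across tissues. Returns (table, truth category per gene).
    """
    if spec.bio_reps < 2 or spec.tech_reps < 1:
        raise ValueError("need >= 2 biological and >= 1 technical replicates")
    rng = substream(spec.seed, "gen_ct_table")
    genes = spec.ct_genes or {"gene1": {t: 1.0 for t in spec.tissues}}
    rows = []
    for tissue in spec.tissues:
        for b in range(1, spec.bio_reps + 1):
            for t in range(1, spec.tech_reps + 1):
                rows.append({"gene": spec.reference_gene, "tissue": tissue,
                             "bio_rep": b, "tech_rep": t,
                             "ct": 16.0 + rng.normal(0.0, spec.ct_noise_sd)})
    for gene, folds in genes.items():
        for tissue in spec.tissues:
            fold = folds.get(tissue, 1.0)
            for b in range(1, spec.bio_reps + 1):
                for t in range(1, spec.tech_reps + 1):
                    rows.append({
                        "gene": gene, "tissue": tissue, "bio_rep": b,
                        "tech_rep": t,
                        "ct": 24.0 - np.log2(fold) + rng.normal(0.0, spec.ct_noise_sd),
                    })
    truth = {g: truth_category(f) for g, f in genes.items()}
    return pd.DataFrame(rows), truth


def plant_motifs(
    spec: SimSpec,
    consensus: dict[int, str],
    architectures: list[tuple[str, float]],
    seq_len: tuple[int, int] = (80, 140),
    mutate_prob: float = 0.05,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Proteins with planted motif architectures.

    ``consensus`` maps motif id to a consensus k-mer (widths 6-10);
    ``architectures`` is a list of ("3-1-2", proportion) mixtures. Each
    planted occurrence copies the consensus with per-position mutation
    probability ``mutate_prob``. Returns records plus a truth table
    with the planted pattern and positions.
    """
    for mid, kmer in consensus.items():
        if not 6 <= len(kmer) <= 10:
            raise ValueError(f"motif {mid}: width {len(kmer)} outside 6-10")
    for arch, _ in architectures:
        for tok in arch.split("-"):
            if int(tok) not in consensus:
                raise ValueError(f"architecture {arch!r} references undefined motif {tok}")
    if seq_len[0] < 1:
        raise ValueError("zero-length background")
    total = sum(p for _, p in architectures)
    if abs(total - 1.0) > 1e-9:
        raise ValueError("architecture proportions must sum to 1")
    rng = substream(spec.seed, "plant_motifs")
    arch_names = [a for a, _ in architectures]
    arch_probs = np.array([p for _, p in architectures])
    records, truth = [], []
    for i in range(spec.n):
        arch = arch_names[rng.choice(len(arch_names), p=arch_probs)]
        motif_ids = [int(t) for t in arch.split("-")]
        length = int(rng.integers(seq_len[0], seq_len[1] + 1))
        need = sum(len(consensus[m]) for m in motif_ids)
        if length < need + 2 * len(motif_ids):
            length = need + 2 * len(motif_ids)
        seq = list(_draw(rng, BACKGROUND_AA, length))
        # one slot per motif keeps the planted order
        bounds = np.linspace(0, length, len(motif_ids) + 1).astype(int)
        starts = []
        for m, lo, hi in zip(motif_ids, bounds[:-1], bounds[1:]):
            kmer = consensus[m]
            start = int(rng.integers(lo, max(lo, hi - len(kmer)) + 1))
            start = min(start, length - len(kmer))
            for k, a in enumerate(kmer):
                if rng.random() < mutate_prob:
                    a = BACKGROUND_AA[rng.integers(0, len(BACKGROUND_AA))]
                seq[start + k] = a
            starts.append(start + 1)
        pid = f"mot{i + 1:03d}"
        records.append(ProteinRecord(id=pid, aa_seq="".join(seq)))
        truth.append({"protein_id": pid, "pattern": arch,
                      "starts": ",".join(map(str, starts))})
    return records, pd.DataFrame(truth, columns=["protein_id", "pattern", "starts"])
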