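"""End-to-end stage orchestration: FASTA + annotation inputs in,
annotation / Ka-Ks / expression reports out, with a run manifest.

Every run writes ``manifest.json`` (inputs, config hash, seed, package
version) into the output directory; reruns with an identical manifest
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import codon_align
from .classify import classify_family
from .io import (
    read_annotation_table, read_ct_table, read_fasta, read_pair_list,
    write_annotation_table, ANNOTATION_COLUMNS,
)
from .kaks import OrthologPair, kaks, kaks_table
from .orf import annotate_orf, deduce_protein
from .physchem import isoelectric_point, molecular_weight, round_half_up
from .qpcr import enrichment_call, relative_expression, tissue_anova
from .records import SignalAnnotation
from .signal import predict_cleavage
from .trees import bootstrap_nj, to_newick

log = logging.getLogger("chemokit")


@dataclass
class RunConfig:
    out_dir: str
    fasta: str | None = None
    sp_table: str | None = None
    pairs: str | None = None
    ct_table: str | None = None
    alignment: str | None = None
    mode: str = "count_based"
    family_hint: str | None = None
    alpha: float = 0.05
    fold_specific: float = 50.0
    scan_threshold: float = 0.0
    tolerance: int = 2
    reference_gene: str = "rps3"
    calibrator_tissue: str = "leg"
    bootstrap_replicates: int = 1000
    seed: int = 0
    extras: dict = field(default_factory=dict)


def _write_manifest(config: RunConfig, out_dir: Path, stage: str) -> None:
    payload = asdict(config)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    manifest = {"stage": stage, "config": payload, "config_sha256": digest,
                "seed": config.seed, "chemokit_version": __version__}
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _sp_annotations(config: RunConfig) -> dict[str, SignalAnnotation]:
    if config.sp_table is None:
        return {}
    df = read_annotation_table(config.sp_table)
    anns = {}
    for _, row in df.iterrows():
        try:
            anns[row["gene"]] = SignalAnnotation(row["gene"], int(float(row["sp_end"])))
        except (ValueError, TypeError):
            continue  # partial record / signal not found
    return anns


def run_annotate(config: RunConfig) -> pd.DataFrame:
    """Annotate a coding FASTA: ORF, signal peptide, MW, pI, class."""
    if config.fasta is None:
        raise ValueError("run_annotate needs a FASTA input")
    out_dir = Path(config.out_dir)
    genes = read_fasta(config.fasta, kind="dna")
    given = _sp_annotations(config)
    rows, proteins, anns, partial = [], [], {}, set()
    for gene in genes:
        annotate_orf(gene, min_aa=30, allow_partial=True)
        row = {"gene": gene.id, "accession": gene.accession or "-"}
        if gene.orf is None:
            rows.append({**row, "orf_bp": "-", "sp_start": "-", "sp_end": "-",
                         "mw_kda": "-", "pi": "-", "class": "-"})
            continue
        if not gene.is_complete:
            flag = "5'missing" if not gene.complete5 else "3'missing"
            row["orf_bp"] = flag
            partial.add(gene.id)
        else:
            row["orf_bp"] = str(gene.orf_bp)
        prot = deduce_protein(gene)
        ann = given.get(gene.id)
        if ann is None and gene.complete5:
            ann = predict_cleavage(prot)
        if ann is not None:
            row["sp_start"], row["sp_end"] = "1", str(ann.sp_end)
            anns[gene.id] = ann
        else:
            row["sp_start"] = row["sp_end"] = "-"
        row["mw_kda"] = f"{round_half_up(molecular_weight(prot.aa_seq.replace('X', '')) / 1000.0):.2f}"
        row["pi"] = f"{round_half_up(isoelectric_point(prot.aa_seq.replace('X', ''))):.2f}"
        proteins.append(prot)
        rows.append(row)
    table, counts = classify_family(
        proteins, anns, mode=config.mode,
        family_hints={p.id: config.family_hint for p in proteins} if config.family_hint else None,
        partial_ids=partial, tol=config.tolerance,
    )
    labels = table.set_index("protein_id")["label"]
    for row in rows:
        if "class" not in row:
            row["class"] = labels.get(row["gene"], "-")
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    _write_manifest(config, out_dir, "annotate")
    write_annotation_table(df, out_dir / "annotation.tsv")
    log.info("annotate: %d genes, class counts %s", len(df), counts)
    return df


def run_evolution(config: RunConfig) -> pd.DataFrame:
    """Per-pair NG86 Ka/Ks with a trailing median row; optionally an NJ
    tree with bootstrap support when an aligned FASTA is supplied."""
    out_dir = Path(config.out_dir)
    if config.pairs is None or config.fasta is None:
        raise ValueError("run_evolution needs --pairs and --fasta")
    genes = {g.id: g for g in read_fasta(config.fasta, kind="dna")}
    pair_df = read_pair_list(config.pairs)
    results, unresolved = [], []
    for _, row in pair_df.iterrows():
        a, b = row["id_a"], row["id_b"]
        if a not in genes or b not in genes:
            unresolved.append((a, b))
            continue
        aln = codon_align(genes[a].nt_seq, genes[b].nt_seq)
        results.append(kaks(OrthologPair(a, b, aln)))
    for a, b in unresolved:
        log.warning("pair %s-%s: unresolved ids, skipped", a, b)
    if not results:
        raise ValueError("no resolvable ortholog pairs")
    df = kaks_table(results)
    _write_manifest(config, out_dir, "evolution")
    df.to_csv(out_dir / "kaks.tsv", sep="\t", index=False, float_format="%.5f")
    if config.alignment:
        aligned = {p.id: p.aa_seq for p in read_fasta(config.alignment, kind="protein")}
        tree, _ = bootstrap_nj(aligned, replicates=config.bootstrap_replicates,
                               seed=config.seed)
        (out_dir / "nj_tree.nwk").write_text(to_newick(tree) + "\n")
    return df


def run_expression(config: RunConfig) -> pd.DataFrame:
    """Relative expression per gene/tissue with Tukey letters and an
    enrichment category per gene."""
    if config.ct_table is None:
        raise ValueError("run_expression needs --ct-table")
    out_dir = Path(config.out_dir)
    ct = read_ct_table(config.ct_table)
    genes = [g for g in ct["gene"].unique() if g != config.reference_gene]
    rows = []
    for gene in genes:
        try:
            res = relative_expression(ct, gene, config.reference_gene,
                                      config.calibrator_tissue)
        except ValueError as exc:
            log.warning("gene %s skipped: %s", gene, exc)
            continue
        tissue_anova(res, alpha=config.alpha)
        cat = enrichment_call(res, fold_specific=config.fold_specific,
                              alpha=config.alpha)
        for _, srow in res.summary.iterrows():
            rows.append({
                "gene": gene, "tissue": srow["tissue"],
                "mean_rel": srow["mean_rel"],
                "se": srow["se"] if not math.isnan(srow["se"]) else 0.0,
                "letter": res.letters.get(srow["tissue"], ""),
                "anova_p": res.anova_p, "category": str(cat),
            })
    df = pd.DataFrame(
        rows, columns=["gene", "tissue", "mean_rel", "se", "letter", "anova_p", "category"]
    )
    _write_manifest(config, out_dir, "expression")
    df.to_csv(out_dir / "expression.tsv", sep="\t", index=False, float_format="%.6g")
    log.info("expression: %d genes (alpha=%g, fold_specific=%g)",
             len(genes), config.alpha, config.fold_specific)
    return df
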