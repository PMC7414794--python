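"""FASTA and TSV input/output.

FASTA goes through Biopython; the tabular interfaces (gene annotation
table, ortholog-pair list, long-format Ct table) are plain TSV read with
pandas. The annotation table mirrors the layout of published OBP/CSP
characterization tables: ``gene accession orf_bp sp_start sp_end mw_kda
pi class`` with ``-`` for absent fields and ``5'missing`` / ``3'missing``
flags in the ``orf_bp`` column for partial clones.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GeneRecord, ProteinRecord, AA_ALPHABET, DNA_ALPHABET

PathLike = Union[str, Path]

ANNOTATION_COLUMNS = [
    "gene", "accession", "orf_bp", "sp_start", "sp_end", "mw_kda", "pi", "class",
]


class FastaParseError(ValueError):
    pass


def _looks_like_protein(seq: str) -> bool:
    return bool(set(seq) - DNA_ALPHABET) and not (set(seq) - AA_ALPHABET - {"*"})


def read_fasta(path: PathLike, kind: str = "auto") -> list:
    """Read FASTA into GeneRecord or ProteinRecord objects.

    ``kind`` is "dna", "protein", or "auto" (per-file majority vote on the
    alphabet). Ids are the first whitespace-delimited header token and
    sequences are uppercased. Empty sequences raise, naming the record.
    """
    if kind not in ("auto", "dna", "protein"):
        raise ValueError(f"unknown kind {kind!r}")
    raw = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        raw.append((rec.id, seq))
    if kind == "auto":
        kind = "protein" if any(_looks_like_protein(s) for _, s in raw) else "dna"
    if kind == "dna":
        return [GeneRecord(id=i, nt_seq=s) for i, s in raw]
    return [ProteinRecord(id=i, aa_seq=s) for i, s in raw]


def write_fasta(records: Iterable, path: PathLike) -> None:
    seqs = []
    for r in records:
        seq = r.nt_seq if isinstance(r, GeneRecord) else r.aa_seq
        seqs.append(SeqRecord(Seq(seq), id=r.id, description=""))
    SeqIO.write(seqs, str(path), "fasta")


def _parse_sp_range(text: str) -> tuple[int, int] | None:
    """Parse a '1-19' / '1–19' style signal-peptide range (1-based incl.)."""
    text = str(text).strip().replace("–", "-")
    if text in ("", "-", "NF", "nan"):
        return None
    if "-" in text:
        a, b = text.split("-", 1)
        return int(a), int(b)
    return 1, int(text)


def read_annotation_table(path: PathLike) -> pd.DataFrame:
    """Read the gene annotation TSV.

    Adds derived boolean columns ``complete`` (intact ORF), ``missing5``
    and ``missing3`` from the flags in the ``orf_bp`` column, and a
    numeric ``orf_bp_nt`` column (NaN for partial records).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {missing}")
    orf = df["orf_bp"].str.strip().str.replace("’", "'", regex=False)
    df["missing5"] = orf.str.contains("5'", regex=False)
    df["missing3"] = orf.str.contains("3'", regex=False)
    df["orf_bp_nt"] = pd.to_numeric(orf, errors="coerce")
    df["complete"] = df["orf_bp_nt"].notna()
    return df


def write_annotation_table(df: pd.DataFrame, path: PathLike) -> None:
    df.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def load_study_gene_table() -> pd.DataFrame:
    """The published annotation table for the 44 OBPs + 6 CSPs of the
    hoverfly *Episyrphus balteatus* (GenBank MT247210–MT247259)."""
    ref = importlib.resources.files("chemokit.data") / "study_gene_table.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_annotation_table(p)


def load_published_kaks_table() -> pd.DataFrame:
    """Published per-pair Ka/Ks estimates for *E. balteatus* versus
    *E. corollae* OBP and CSP ortholog pairs."""
    ref = importlib.resources.files("chemokit.data") / "published_kaks_pairs.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def read_ct_table(path: PathLike) -> pd.DataFrame:
    """Long-format qPCR Ct table: gene, tissue, bio_rep, tech_rep, ct."""
    df = pd.read_csv(path, sep="\t")
    need = ["gene", "tissue", "bio_rep", "tech_rep", "ct"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {missing}")
    return df


def read_pair_list(path: PathLike) -> pd.DataFrame:
    """Ortholog pair list TSV with columns id_a, id_b."""
    df = pd.read_csv(path, sep="\t")
    for c in ("id_a", "id_b"):
        if c not in df.columns:
            raise ValueError(f"{path}: pair list missing column {c!r}")
    return df
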