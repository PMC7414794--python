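"""Nei-Gojobori (1986) Ka/Ks estimation on codon-aligned ortholog pairs.

Synonymous (S) and nonsynonymous (N) site counts: at each codon
position, each of the three possible single-base changes contributes
1/3 of a site; changes creating stop codons are excluded from the
denominator, so a codon carries between 2 and 3 sites in total.
Observed differences (Sd, Nd) decompose each differing codon pair by
averaging over all orderings of the single-base steps, dropping paths
that pass through stop codons. Proportions are corrected for multiple
hits with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p); p >= 3/4
is saturated and the corresponding rate is undefined (NaN).

Ka/Ks (omega) < 1 indicates purifying selection. Ks = 0 with Ka > 0 is
reported as +inf and excluded from medians; Ka = Ks = 0 is undefined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .align import CodonAlignment, GAP_CODON

BASES = "ACGT"

_STANDARD_CODE = {}


def _codon_table() -> dict[str, str]:
    if not _STANDARD_CODE:
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        table = unambiguous_dna_by_id[1]
        _STANDARD_CODE.update(table.forward_table)
        for stop in table.stop_codons:
            _STANDARD_CODE[stop] = "*"
    return _STANDARD_CODE


def is_sense(codon: str) -> bool:
    aa = _codon_table().get(codon)
    return aa is not None and aa != "*"


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon."""
    codon = codon.upper()
    code = _codon_table()
    if code.get(codon, "*") == "*":
        raise ValueError(f"stop or ambiguous codon {codon!r}")
    aa = code[codon]
    s = sites = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            alt_aa = code[alt]
            if alt_aa == "*":
                continue  # stop outcomes excluded from the denominator
            sites += 1.0 / 3.0
            if alt_aa == aa:
                s += 1.0 / 3.0
    return s, sites - s


def sequence_sites(codons: list[str]) -> tuple[float, float]:
    s = n = 0.0
    for c in codons:
        cs, cn = ng86_sites(c)
        s += cs
        n += cn
    return s, n


def codon_path_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """(Sd, Nd) for one codon pair, averaged over all orderings of the
    single-base steps; paths through stop codons are dropped. None when
    every path is blocked."""
    c1, c2 = c1.upper(), c2.upper()
    code = _codon_table()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd_tot = nd_tot = 0.0
    n_valid = 0
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code[nxt] == "*":
                ok = False
                break
            if code[nxt] == code[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if ok:
            sd_tot += sd
            nd_tot += nd
            n_valid += 1
    if n_valid == 0:
        return None
    return sd_tot / n_valid, nd_tot / n_valid


def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    alignment: CodonAlignment


@dataclass
class KaKsResult:
    pair: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    ratio: float  # NaN undefined, +inf when Ks = 0 < Ka
    n_codons: int  # comparable (ungapped, unambiguous) codon columns


def _comparable(ca: str, cb: str) -> bool:
    if GAP_CODON in (ca, cb) or "-" in ca or "-" in cb:
        return False
    if "N" in ca or "N" in cb:
        return False
    return is_sense(ca) and is_sense(cb)


def kaks(pair: OrthologPair) -> KaKsResult:
    """NG86 estimate for one codon-aligned ortholog pair."""
    sa = na = sb = nb = sd = nd = 0.0
    n_codons = 0
    for ca, cb in pair.alignment.codon_pairs():
        if not _comparable(ca, cb):
            continue
        d = codon_path_differences(ca, cb)
        if d is None:
            warnings.warn(
                f"{pair.id_a}/{pair.id_b}: codon pair {ca}/{cb} has no "
                "stop-free mutational path; column skipped", stacklevel=2,
            )
            continue
        s1, n1 = ng86_sites(ca)
        s2, n2 = ng86_sites(cb)
        sa += s1
        na += n1
        sb += s2
        nb += n2
        sd += d[0]
        nd += d[1]
        n_codons += 1
    if n_codons == 0:
        raise ValueError(f"{pair.id_a}/{pair.id_b}: no comparable codons")
    s_sites = (sa + sb) / 2.0
    n_sites = (na + nb) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if math.isnan(ks) or math.isnan(ka):
        ratio = math.nan
    elif ks == 0.0:
        ratio = math.nan if ka == 0.0 else math.inf
    else:
        ratio = ka / ks
    return KaKsResult(f"{pair.id_a}-{pair.id_b}", s_sites, n_sites, sd, nd,
                      ps, pn, ks, ka, ratio, n_codons)


@dataclass
class KaKsSummary:
    n: int
    median_ka: float
    median_ks: float
    median_ratio: float
    max_ratio: float
    frac_purifying: float  # fraction of defined ratios < 1


def _defined(values) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[np.isfinite(arr)]


def summarize_kaks(results) -> KaKsSummary:
    """Family-level medians and the purifying-selection report.

    Accepts a list of KaKsResult or a DataFrame with columns
    ``ka``, ``ks``, ``ka_ks``. Undefined (NaN) and infinite ratios are
    excluded from the ratio median; the median of an even count is the
    mean of the two central values.
    """
    if isinstance(results, pd.DataFrame):
        ka, ks, ratio = results["ka"], results["ks"], results["ka_ks"]
        n = len(results)
    else:
        ka = [r.ka for r in results]
        ks = [r.ks for r in results]
        ratio = [r.ratio for r in results]
        n = len(ka)
    if n == 0:
        raise ValueError("no Ka/Ks results to summarize")
    ka_d, ks_d, ratio_d = _defined(ka), _defined(ks), _defined(ratio)
    if ratio_d.size == 0:
        raise ValueError("no defined Ka/Ks ratios")
    return KaKsSummary(
        n=n,
        median_ka=float(np.median(ka_d)),
        median_ks=float(np.median(ks_d)),
        median_ratio=float(np.median(ratio_d)),
        max_ratio=float(ratio_d.max()),
        frac_purifying=float((ratio_d < 1.0).mean()),
    )


def kaks_table(results: list[KaKsResult]) -> pd.DataFrame:
    """Per-pair TSV-ready table with a trailing median row."""
    rows = [
        {"pair": r.pair, "ka": r.ka, "ks": r.ks, "ka_ks": r.ratio}
        for r in results
    ]
    summary = summarize_kaks(results)
    rows.append({"pair": "median", "ka": summary.median_ka,
                 "ks": summary.median_ks, "ka_ks": summary.median_ratio})
    return pd.DataFrame(rows, columns=["pair", "ka", "ks", "ka_ks"])
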