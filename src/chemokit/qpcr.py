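"""qPCR analysis: primer efficiency, 2^-delta-delta-Ct relative
quantification, ANOVA with Tukey HSD across tissues, and
enrichment-category calling.

Quantification follows the standard comparative-Ct scheme: technical
replicates are averaged first; dCt = Ct_target - Ct_reference per
(tissue, biological replicate); relative expression is 2^-ddCt, where
ddCt is referenced to the calibrator tissue's mean relative level in
the linear domain, so the calibrator's mean relative expression is
exactly 1 by construction (with noise-free replicates this coincides
with subtracting the calibrator's mean dCt). With a balanced design (equal technical replicates per
biological replicate), averaging technical replicates and running a
one-way ANOVA on biological replicates is exactly the nested ANOVA's
between-tissue test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DEFAULT_EFFICIENCY_BAND = (90.0, 110.0)


@dataclass
class StandardCurve:
    gene: str
    slope: float
    intercept: float
    r2: float
    efficiency_percent: float
    in_band: bool


def efficiency(points, gene: str = "",
               band: tuple[float, float] = DEFAULT_EFFICIENCY_BAND) -> StandardCurve:
    """Primer efficiency from a dilution-series standard curve.

    ``points`` is a sequence of (log10 input, mean Ct). Efficiency
    E% = (10^(-1/slope) - 1) x 100; a slope of -log2(10)... i.e.
    -3.3219 gives exactly 100%. Curves outside ``band`` are flagged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 dilution points")
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in log10 input")
    res = stats.linregress(x, y)
    eff = (10.0 ** (-1.0 / res.slope) - 1.0) * 100.0
    return StandardCurve(gene, float(res.slope), float(res.intercept),
                         float(res.rvalue**2), float(eff),
                         band[0] <= eff <= band[1])


@dataclass
class EnrichmentCall:
    kind: str            # "tissue_specific" | "tissue_enriched" | "broad"
    tissue: str | None = None

    def __str__(self) -> str:
        return self.kind if self.tissue is None else f"{self.kind}({self.tissue})"


@dataclass
class ExpressionResult:
    gene: str
    calibrator: str
    per_rep: pd.DataFrame          # tissue, bio_rep, dct, ddct, rel
    summary: pd.DataFrame          # tissue, mean_rel, se
    anova_p: float = math.nan
    anova_f: float = math.nan
    letters: dict[str, str] = field(default_factory=dict)
    significant: dict[tuple[str, str], bool] = field(default_factory=dict)
    category: EnrichmentCall | None = None


def relative_expression(ct: pd.DataFrame, gene: str, reference_gene: str,
                        calibrator_tissue: str) -> ExpressionResult:
    """2^-ddCt relative expression of ``gene`` across tissues."""
    need = {"gene", "tissue", "bio_rep", "tech_rep", "ct"}
    if not need <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(need)}")
    tech_means = (
        ct.groupby(["gene", "tissue", "bio_rep"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    target = tech_means[tech_means["gene"] == gene]
    ref = tech_means[tech_means["gene"] == reference_gene].set_index(
        ["tissue", "bio_rep"]
    )["ct"]
    if target.empty:
        raise ValueError(f"no Ct rows for gene {gene!r}")
    rows = []
    for _, r in target.iterrows():
        key = (r["tissue"], r["bio_rep"])
        if key not in ref.index:
            raise ValueError(
                f"{gene}: missing reference {reference_gene!r} measurement "
                f"for tissue {key[0]!r} bio_rep {key[1]}"
            )
        rows.append({"tissue": r["tissue"], "bio_rep": r["bio_rep"],
                     "dct": r["ct"] - ref.loc[key]})
    per_rep = pd.DataFrame(rows)
    cal = per_rep[per_rep["tissue"] == calibrator_tissue]
    if cal.empty:
        raise ValueError(f"calibrator tissue {calibrator_tissue!r} absent for {gene}")
    # calibrate in the linear domain so the calibrator mean is exactly 1
    cal_level = float(np.mean(2.0 ** (-cal["dct"])))
    per_rep["ddct"] = per_rep["dct"] + math.log2(cal_level)
    per_rep["rel"] = 2.0 ** (-per_rep["ddct"])
    summary = (
        per_rep.groupby("tissue", sort=False)["rel"]
        .agg(mean_rel="mean", se=lambda v: v.std(ddof=1) / math.sqrt(len(v)))
        .reset_index()
    )
    return ExpressionResult(gene, calibrator_tissue, per_rep, summary)


def _compact_letter_display(order: list[str],
                            significant: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Greedy letter assignment from the highest mean: a group joins an
    existing letter iff it is not significantly different from every
    current member; otherwise it opens a new letter."""
    letter_groups: list[list[str]] = []
    for t in order:
        placed = False
        for grp in letter_groups:
            if all(not significant[tuple(sorted((t, u)))] for u in grp):
                grp.append(t)
                placed = True
        if not placed:
            letter_groups.append([t])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {t: "" for t in order}
    for i, grp in enumerate(letter_groups):
        for t in grp:
            letters[t] += alphabet[i]
    return letters


def tissue_anova(result: ExpressionResult, alpha: float = 0.05) -> ExpressionResult:
    """One-way ANOVA + Tukey HSD on per-biological-replicate relative
    expression; fills ``anova_p``, pairwise significance, and the
    compact letter display."""
    groups = [g["rel"].to_numpy() for _, g in result.per_rep.groupby("tissue", sort=False)]
    tissues = list(result.per_rep.groupby("tissue", sort=False).groups)
    if len(tissues) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 tissues with >= 2 biological replicates")
    values = np.concatenate(groups)
    if np.allclose(values, values[0]):
        result.anova_p = 1.0
        result.anova_f = 0.0
        result.significant = {
            tuple(sorted((a, b))): False
            for i, a in enumerate(tissues) for b in tissues[i + 1 :]
        }
    else:
        f_res = stats.f_oneway(*groups)
        result.anova_p = float(f_res.pvalue)
        result.anova_f = float(f_res.statistic)
        tk = pairwise_tukeyhsd(
            values,
            np.concatenate([[t] * len(g) for t, g in zip(tissues, groups)]),
            alpha=alpha,
        )
        from itertools import combinations

        sig = {}
        for (a, b), reject in zip(combinations(tk.groupsunique, 2), tk.reject):
            sig[tuple(sorted((str(a), str(b))))] = bool(reject)
        result.significant = sig
    order = (
        result.summary.sort_values("mean_rel", ascending=False)["tissue"].tolist()
    )
    result.letters = _compact_letter_display(order, result.significant)
    return result


def enrichment_call(result: ExpressionResult, fold_specific: float = 50.0,
                    alpha: float = 0.05) -> EnrichmentCall:
    """Categorize a gene's tissue profile.

    tissue_specific(t): t has the top mean, is Tukey-separated from
    every other tissue, and its mean fold versus every other tissue is
    >= ``fold_specific``. tissue_enriched(t): separated but below the
    fold bar. Otherwise broad.
    """
    if not result.significant and math.isnan(result.anova_p):
        result = tissue_anova(result, alpha=alpha)
    s = result.summary.sort_values("mean_rel", ascending=False)
    top, top_mean = s.iloc[0]["tissue"], s.iloc[0]["mean_rel"]
    others = s.iloc[1:]
    separated = all(
        result.significant[tuple(sorted((top, t)))] for t in others["tissue"]
    )
    if not separated:
        call = EnrichmentCall("broad")
    else:
        min_fold = (top_mean / others["mean_rel"]).min() if len(others) else math.inf
        if min_fold >= fold_specific:
            call = EnrichmentCall("tissue_specific", top)
        else:
            call = EnrichmentCall("tissue_enriched", top)
    result.category = call
    return call
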