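"""Primer efficiency, 2^-ddCt quantification, nested ANOVA reduction,
Tukey letters and enrichment categories."""

import numpy as np
import pandas as pd
import pytest

import chemokit as ck
from chemokit.qpcr import ExpressionResult, _compact_letter_display

from oracles import nested_anova_f_oracle


def _ct_rows(entries):
    rows = []
    for gene, tissue, bio, tech, ct in entries:
        rows.append(dict(gene=gene, tissue=tissue, bio_rep=bio, tech_rep=tech, ct=ct))
    return pd.DataFrame(rows)


def test_efficiency_slope_of_perfect_doubling():
    pts = [(x, 30 - 3.3219 * x) for x in range(5)]
    curve = ck.efficiency(pts)
    assert curve.efficiency_percent == pytest.approx(100.0, abs=0.01)
    assert curve.r2 == pytest.approx(1.0)
    assert curve.in_band


def test_efficiency_recovers_generating_slope():
    pts = [(x, 28.4 - 3.5 * x) for x in range(4)]
    assert ck.efficiency(pts).slope == pytest.approx(-3.5, abs=1e-9)


def test_efficiency_band_flag():
    pts = [(x, 30 - 4.2 * x) for x in range(4)]  # ~73% efficiency
    assert not ck.efficiency(pts).in_band


def test_efficiency_input_validation():
    with pytest.raises(ValueError):
        ck.efficiency([(0, 30), (1, 27)])
    with pytest.raises(ValueError):
        ck.efficiency([(1, 30), (1, 27), (1, 24)])


def test_relative_expression_closed_form():
    df = _ct_rows(
        [("x", "A", b, 1, 20.0) for b in (1, 2)]
        + [("x", "cal", b, 1, 24.0) for b in (1, 2)]
        + [("ref", "A", b, 1, 18.0) for b in (1, 2)]
        + [("ref", "cal", b, 1, 18.0) for b in (1, 2)]
    )
    res = ck.relative_expression(df, "x", "ref", "cal")
    by_tissue = res.summary.set_index("tissue")["mean_rel"]
    assert by_tissue["A"] == pytest.approx(16.0)
    assert by_tissue["cal"] == pytest.approx(1.0)


def test_calibrator_mean_is_one(rng):
    spec = ck.SimSpec(seed=21, ct_genes={"g": {"antennae": 8.0, "head": 2.0,
                                               "thorax": 1.0, "abdomen": 1.0,
                                               "leg": 1.0}})
    ct, _ = ck.gen_ct_table(spec)
    res = ck.relative_expression(ct, "g", "rps3", "leg")
    cal = res.summary.set_index("tissue")["mean_rel"]["leg"]
    assert cal == pytest.approx(1.0)


def test_constant_ct_shift_cancels():
    base = _ct_rows(
        [("x", "A", b, 1, 20.0 + b) for b in (1, 2)]
        + [("x", "cal", b, 1, 24.0) for b in (1, 2)]
        + [("ref", "A", b, 1, 18.0 + b) for b in (1, 2)]
        + [("ref", "cal", b, 1, 18.0) for b in (1, 2)]
    )
    shifted = base.copy()
    # shifting target and reference of one cell jointly leaves rel unchanged
    mask_t = (shifted.tissue == "A") & (shifted.bio_rep == 1)
    shifted.loc[mask_t, "ct"] += 3.7
    r1 = ck.relative_expression(base, "x", "ref", "cal").summary
    r2 = ck.relative_expression(shifted, "x", "ref", "cal").summary
    pd.testing.assert_frame_equal(r1, r2)


def test_missing_reference_rows_rejected():
    df = _ct_rows([("x", "A", 1, 1, 20.0), ("x", "cal", 1, 1, 24.0),
                   ("ref", "cal", 1, 1, 18.0)])
    with pytest.raises(ValueError, match="missing reference"):
        ck.relative_expression(df, "x", "ref", "cal")


def test_identical_values_give_p_one_and_shared_letter():
    per_rep = pd.DataFrame(
        [{"tissue": t, "bio_rep": b, "dct": 0.0, "ddct": 0.0, "rel": 1.0}
         for t in ("A", "B", "C") for b in (1, 2, 3)]
    )
    summary = per_rep.groupby("tissue")["rel"].agg(
        mean_rel="mean", se="sem").reset_index()
    res = ExpressionResult("g", "A", per_rep, summary)
    ck.tissue_anova(res)
    assert res.anova_p == 1.0
    assert len(set(res.letters.values())) == 1


def test_nested_anova_equals_two_step_oracle(rng):
    """With a balanced design, tech-replicate averaging then one-way
    ANOVA reproduces the nested-model F exactly."""
    a, b, t = 4, 3, 3
    for _ in range(10):
        data = rng.normal(0, 1, size=(a, b, t)) + rng.normal(
            0, 2, size=(a, 1, 1)
        )
        per_rep = pd.DataFrame(
            [{"tissue": f"T{i}", "bio_rep": j + 1, "rel": data[i, j].mean()}
             for i in range(a) for j in range(b)]
        )
        summary = per_rep.groupby("tissue")["rel"].agg(
            mean_rel="mean", se="sem").reset_index()
        res = ExpressionResult("g", "T0", per_rep, summary)
        ck.tissue_anova(res)
        assert res.anova_f == pytest.approx(nested_anova_f_oracle(data), rel=1e-9)


def test_planted_antennae_effect_separates():
    """100x antennae effect, CV 10%, B=3: antennae letter distinct from
    every other tissue in >= 95% of 200 simulations."""
    rng = np.random.default_rng(909)
    tissues = ["antennae", "head", "thorax", "abdomen", "leg"]
    wins = 0
    for _ in range(200):
        rows = []
        for tissue in tissues:
            mean = 100.0 if tissue == "antennae" else 1.0
            for b in range(1, 4):
                rows.append({"tissue": tissue, "bio_rep": b,
                             "rel": rng.normal(mean, 0.1 * mean)})
        per_rep = pd.DataFrame(rows)
        summary = per_rep.groupby("tissue", sort=False)["rel"].agg(
            mean_rel="mean", se="sem").reset_index()
        res = ExpressionResult("g", "leg", per_rep, summary)
        ck.tissue_anova(res)
        ant = res.letters["antennae"]
        if all(set(ant).isdisjoint(res.letters[t]) for t in tissues[1:]):
            wins += 1
    assert wins / 200 >= 0.95


def test_enrichment_categories():
    rng = np.random.default_rng(31)
    spec = ck.SimSpec(
        seed=31,
        ct_genes={
            "spec100": {"antennae": 100.0, "head": 1, "thorax": 1, "abdomen": 1, "leg": 1},
            "enr5": {"antennae": 5.0, "head": 1, "thorax": 1, "abdomen": 1, "leg": 1},
            "flat": {t: 1.0 for t in ("antennae", "head", "thorax", "abdomen", "leg")},
        },
    )
    ct, truth = ck.gen_ct_table(spec)
    calls = {}
    for g in ("spec100", "enr5", "flat"):
        res = ck.relative_expression(ct, g, "rps3", "leg")
        ck.tissue_anova(res)
        calls[g] = str(ck.enrichment_call(res))
    assert calls["spec100"] == "tissue_specific(antennae)"
    assert calls["enr5"] == "tissue_enriched(antennae)"
    assert calls["flat"] == "broad"
    assert calls == truth


def test_category_invariant_under_calibrator_choice():
    spec = ck.SimSpec(seed=57, ct_genes={"g": {"antennae": 100.0, "head": 1,
                                               "thorax": 1, "abdomen": 1, "leg": 1}})
    ct, _ = ck.gen_ct_table(spec)
    calls = set()
    for cal in ("leg", "head", "thorax"):
        res = ck.relative_expression(ct, "g", "rps3", cal)
        ck.tissue_anova(res)
        calls.add(str(ck.enrichment_call(res)))
    assert calls == {"tissue_specific(antennae)"}


def test_letter_display_is_deterministic_function_of_significance():
    sig = {("A", "B"): True, ("A", "C"): True, ("B", "C"): False}
    letters = _compact_letter_display(["A", "B", "C"], sig)
    assert letters["A"] != letters["B"]
    assert letters["B"] == letters["C"]
    assert letters == _compact_letter_display(["A", "B", "C"], dict(sig))
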