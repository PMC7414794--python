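"""Cysteine signatures and subclass assignment."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chemokit as ck
from chemokit.classify import (
    CLASS_MOTIFS, LABEL_CLASSIC, LABEL_CSP, LABEL_MINUS_C, LABEL_PLUS_C,
    LABEL_UNCLASSIFIED, assign_class, check_csp, cys_signature,
)

from oracles import strict_label_oracle


def _mature_from_spacings(gaps, lead=5, tail=20, proline_after_c6=False):
    parts = ["A" * lead]
    for g in gaps:
        parts.append("C")
        parts.append("A" * g)
    parts.append("C")
    s = "".join(parts) + "A" * tail
    if proline_after_c6:
        positions = [i for i, a in enumerate(s) if a == "C"]
        p = positions[-2] + 1
        s = s[:p] + "P" + s[p + 1 :]
    return s


def test_cys_signature_examples():
    sig = cys_signature("ACAC")
    assert sig.positions == (2, 4) and sig.spacings == (1,)
    assert cys_signature("AAAA").count == 0


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet="ACDGKLC", min_size=1, max_size=80))
def test_cys_signature_matches_linear_scan(s):
    sig = cys_signature(s)
    positions = [i + 1 for i, a in enumerate(s) if a == "C"]
    assert list(sig.positions) == positions
    assert list(sig.spacings) == [
        b - a - 1 for a, b in zip(positions, positions[1:])
    ]
    # spacing arithmetic is self-consistent
    for i, g in enumerate(sig.spacings):
        assert sig.positions[i + 1] - sig.positions[i] - 1 == g


@pytest.mark.parametrize("mode", ["count_based", "strict"])
def test_classic_spacings_assign_classic(mode):
    mature = _mature_from_spacings([25, 3, 40, 9, 8])
    sig = cys_signature(mature)
    assert assign_class(sig, mature, mode=mode).label == LABEL_CLASSIC


def test_minus_c_strict_assignment():
    mature = _mature_from_spacings([32, 40, 18])
    sig = cys_signature(mature)
    assert assign_class(sig, mature, mode="strict").label == LABEL_MINUS_C


def test_zero_cysteines_unclassified():
    mature = "A" * 50
    assert assign_class(cys_signature(mature), mature).label == LABEL_UNCLASSIFIED


def test_check_csp():
    csp = _mature_from_spacings([6, 18, 2])
    ok, _ = check_csp(cys_signature(csp), csp)
    assert ok
    minus = _mature_from_spacings([32, 40, 18])
    assert not check_csp(cys_signature(minus), minus)[0]
    six = _mature_from_spacings([6, 18, 2, 8, 8])
    assert not check_csp(cys_signature(six), six)[0]


def test_four_cys_family_hint_disambiguation():
    minus = _mature_from_spacings([32, 40, 18])
    sig = cys_signature(minus)
    assert assign_class(sig, minus, family_hint="OBP").label == LABEL_MINUS_C
    csp = _mature_from_spacings([6, 18, 2])
    sig2 = cys_signature(csp)
    assert assign_class(sig2, csp).label == LABEL_CSP
    assert assign_class(sig2, csp, family_hint="OBP").label == LABEL_MINUS_C


def test_plus_c_requires_proline_dyad():
    gaps = [25, 3, 43, 24, 9, 8, 10]
    with_p = _mature_from_spacings(gaps, proline_after_c6=True)
    without_p = _mature_from_spacings(gaps, proline_after_c6=False)
    assert assign_class(cys_signature(with_p), with_p).label == LABEL_PLUS_C
    assert assign_class(cys_signature(without_p), without_p).label == LABEL_UNCLASSIFIED


def test_strict_matches_declarative_oracle_randomized():
    """10,000 random spacing vectors: strict labels equal an
    independently written declarative pattern oracle."""
    rng = np.random.default_rng(424242)
    templates = {
        4: [(32, 32), (36, 46), (18, 18), (6, 6)],
        6: CLASS_MOTIFS[LABEL_CLASSIC].gap_constraints,
        8: CLASS_MOTIFS[LABEL_PLUS_C].gap_constraints,
    }
    for _ in range(10_000):
        count = int(rng.choice([4, 6, 8]))
        n_gaps = count - 1
        gaps = []
        for i in range(n_gaps):
            if rng.random() < 0.7:  # near a real constraint
                lo, hi = templates[count][i % len(templates[count])]
                g = int(rng.integers(max(0, lo - 4), hi + 5))
            else:
                g = int(rng.integers(0, 60))
            gaps.append(g)
        mature = _mature_from_spacings(
            gaps,
            lead=int(rng.integers(0, 8)),
            tail=int(rng.integers(0, 40)),
            proline_after_c6=bool(rng.random() < 0.5) and count >= 3,
        )
        sig = cys_signature(mature)
        got = assign_class(sig, mature, mode="strict").label
        assert got == strict_label_oracle(mature), (gaps, mature)


def test_strict_matches_oracle_on_boundary_grid():
    """Exhaustive grid over every +-1 boundary value of every range."""
    for name, motif in CLASS_MOTIFS.items():
        choices = []
        for (lo, hi), single in zip(motif.gap_constraints, motif.singleton):
            tol = 2 if single else 0
            vals = {max(0, lo - tol - 1), max(0, lo - tol), hi + tol, hi + tol + 1}
            choices.append(sorted(vals))
        for gaps in product(*choices):
            mature = _mature_from_spacings(
                gaps, tail=18, proline_after_c6=(name == LABEL_PLUS_C)
            )
            sig = cys_signature(mature)
            got = assign_class(sig, mature, mode="strict").label
            assert got == strict_label_oracle(mature), (name, gaps)


def test_strict_refines_count_based(family_200):
    """A strict-mode label implies the same count-based label."""
    _, proteins, truth = family_200
    by_id = {p.id: p for p in proteins}
    for row in truth.itertuples():
        mature = row.mature
        sig = cys_signature(mature)
        strict = assign_class(sig, mature, mode="strict", family_hint="OBP").label
        if strict != LABEL_UNCLASSIFIED:
            count = assign_class(sig, mature, mode="count_based",
                                 family_hint="OBP").label
            assert count == strict


def test_label_invariant_under_cterminal_extension():
    mature = _mature_from_spacings([25, 3, 40, 9, 8], tail=5)
    sig = cys_signature(mature)
    base = assign_class(sig, mature, mode="strict").label
    longer = mature + "GGSSA"
    assert assign_class(cys_signature(longer), longer, mode="strict").label == base


def test_classify_family_recovers_planted_classes(family_200):
    _, proteins, truth = family_200
    anns = {
        r.protein_id: ck.SignalAnnotation(r.protein_id, r.sp_end)
        for r in truth.itertuples()
    }
    table, counts = ck.classify_family(proteins, anns, mode="count_based",
                                       family_hints={p.id: "OBP" for p in proteins})
    merged = table.merge(truth, left_on="protein_id", right_on="protein_id")
    assert (merged["label"] == merged["class"]).all()
    assert sum(counts.values()) == len(proteins)


def test_classify_family_empty():
    table, counts = ck.classify_family([])
    assert table.empty and counts == {}


def test_classify_family_partials_flagged_and_excluded(family_200):
    _, proteins, truth = family_200
    anns = {
        r.protein_id: ck.SignalAnnotation(r.protein_id, r.sp_end)
        for r in truth.itertuples()
    }
    partial = {proteins[0].id, proteins[1].id}
    table, counts = ck.classify_family(proteins, anns, partial_ids=partial)
    assert table["partial"].sum() == 2
    assert sum(counts.values()) == len(proteins) - 2
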