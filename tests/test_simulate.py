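"""Generators: determinism, planted-truth closure, edge cases."""

import numpy as np
import pytest

import chemokit as ck
from chemokit.classify import cys_signature, assign_class
from chemokit.simulate import substream, truth_category


def test_same_seed_same_bytes(tmp_path):
    for i, out in enumerate(["a.fasta", "b.fasta"]):
        genes, _, _ = ck.gen_family(ck.SimSpec(seed=5, n=20))
        ck.write_fasta(genes, tmp_path / out)
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_substreams_are_operation_scoped():
    # drawing from one generator does not shift another's stream
    a = substream(1, "gen_family").integers(0, 1000, size=5)
    _ = substream(1, "gen_ct_table").integers(0, 1000, size=50)
    b = substream(1, "gen_family").integers(0, 1000, size=5)
    assert (a == b).all()
    assert not (a == substream(1, "plant_motifs").integers(0, 1000, size=5)).all()


def test_empty_family():
    genes, proteins, truth = ck.gen_family(ck.SimSpec(seed=1, n=0))
    assert genes == [] and proteins == [] and truth.empty


def test_pure_classic_family_recovered_strict():
    spec = ck.SimSpec(seed=9, n=50, class_mix={"Classic": 1.0})
    _, proteins, truth = spec, None, None
    _, proteins, truth = ck.gen_family(spec)
    for row in truth.itertuples():
        sig = cys_signature(row.mature)
        assert assign_class(sig, row.mature, mode="strict").label == "Classic"


def test_generated_protein_lengths_in_study_range(family_200):
    _, proteins, truth = family_200
    for p in proteins:
        assert 124 <= len(p.aa_seq) <= 260
    assert truth["sp_end"].between(15, 27).all()


def test_back_translation_is_synonymous(family_200):
    genes, proteins, _ = family_200
    for g, p in zip(genes[:20], proteins[:20]):
        assert ck.translate(g.nt_seq) == p.aa_seq


def test_omega_zero_means_no_amino_acid_changes():
    """With omega = 0 every accepted change is synonymous, so ancestor
    and descendant encode identical proteins. The NG86 path-averaged Ka
    can still be marginally positive (multi-hit synonymous codons admit
    nonsynonymous mutational orderings), so the estimator is checked
    against ~0, not exact zero."""
    pairs, _ = ck.gen_ortholog_pairs(ck.SimSpec(seed=3, n_pairs=10, n_codons=100,
                                                omega=0.0))
    for p in pairs:
        assert ck.translate(p.alignment.seq_a) == ck.translate(p.alignment.seq_b)
        r = ck.kaks(p)
        assert r.ka <= 0.01
        assert r.ratio < 0.1


def test_branch_len_zero_means_identical_pairs():
    pairs, _ = ck.gen_ortholog_pairs(ck.SimSpec(seed=3, n_pairs=5, n_codons=50,
                                                branch_len=0.0))
    for p in pairs:
        assert p.alignment.seq_a == p.alignment.seq_b


def test_neutral_simulation_estimates_near_one():
    spec = ck.SimSpec(seed=13, n_pairs=50, n_codons=300, omega=1.0)
    pairs, _ = ck.gen_ortholog_pairs(spec)
    s = ck.summarize_kaks([ck.kaks(p) for p in pairs])
    assert 0.8 <= s.median_ratio <= 1.25


def test_ct_table_zero_noise_exact_fold():
    spec = ck.SimSpec(seed=2, ct_noise_sd=0.0,
                      ct_genes={"g": {"antennae": 16.0, "head": 1, "thorax": 1,
                                      "abdomen": 1, "leg": 1}})
    ct, _ = ck.gen_ct_table(spec)
    res = ck.relative_expression(ct, "g", "rps3", "leg")
    assert res.summary.set_index("tissue")["mean_rel"]["antennae"] == pytest.approx(16.0)


def test_ct_table_deterministic():
    t1, _ = ck.gen_ct_table(ck.SimSpec(seed=4))
    t2, _ = ck.gen_ct_table(ck.SimSpec(seed=4))
    assert t1.equals(t2)


def test_planted_expression_categories_recovered():
    """>=95% of 200 planted genes recover their true category at Ct
    noise sd 0.2."""
    rng = np.random.default_rng(888)
    tissues = ("antennae", "head", "thorax", "abdomen", "leg")
    genes = {}
    for i in range(200):
        kind = i % 3
        target = tissues[int(rng.integers(0, len(tissues)))]
        if kind == 0:
            folds = {t: (100.0 if t == target else 1.0) for t in tissues}
        elif kind == 1:
            folds = {t: (8.0 if t == target else 1.0) for t in tissues}
        else:
            folds = {t: 1.0 for t in tissues}
        genes[f"g{i}"] = folds
    spec = ck.SimSpec(seed=77, ct_genes=genes, ct_noise_sd=0.2)
    ct, truth = ck.gen_ct_table(spec)
    correct = 0
    for g, expected in truth.items():
        res = ck.relative_expression(ct, g, "rps3", "leg")
        ck.tissue_anova(res)
        if str(ck.enrichment_call(res)) == expected:
            correct += 1
    assert correct / len(truth) >= 0.95


def test_truth_category_rules():
    t = ("a", "b", "c")
    assert truth_category({"a": 100, "b": 1, "c": 1}) == "tissue_specific(a)"
    assert truth_category({"a": 5, "b": 1, "c": 1}) == "tissue_enriched(a)"
    assert truth_category({"a": 1, "b": 1, "c": 1}) == "broad"


def test_plant_motifs_validation():
    spec = ck.SimSpec(seed=1, n=5)
    with pytest.raises(ValueError, match="undefined motif"):
        ck.plant_motifs(spec, {1: "WKDHEY"}, [("1-2", 1.0)])
    with pytest.raises(ValueError, match="width"):
        ck.plant_motifs(spec, {1: "WKD"}, [("1", 1.0)])
    with pytest.raises(ValueError, match="zero-length"):
        ck.plant_motifs(spec, {1: "WKDHEY"}, [("1", 1.0)], seq_len=(0, 0))


def test_plant_motifs_single_architecture_truth():
    spec = ck.SimSpec(seed=6, n=20)
    recs, truth = ck.plant_motifs(spec, {1: "WKDHEY", 2: "MHYWND"}, [("1-2", 1.0)])
    assert (truth["pattern"] == "1-2").all()
    pf = ck.pattern_frequency(truth["pattern"].tolist())
    assert len(pf) == 1 and pf["percent"].iloc[0] == 100.0


def test_class_mix_must_sum_to_one():
    with pytest.raises(ValueError):
        ck.SimSpec(seed=1, class_mix={"Classic": 0.5})
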