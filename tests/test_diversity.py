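"""Diversity summaries, TN93 distances, PhiST and neighbour joining."""

import io
import itertools

import numpy as np
import pytest

from mitocr.diversity import (DistanceModel, nj_tree, p_distance,
                              pairwise_phist, phist_matrix, summary_stats,
                              tn93_distance)
from mitocr.variants import parse_motif

mk = parse_motif

# 300-nt pair with 8 transitions and 4 transversions; the expected TN93
# values below were computed with an independent implementation (ape's
# dist.dna) and frozen here.
S3 = ("GGCTTATCTTATGCAGGCAAGCGGCAAGATTTATCTCCGAAACGAGGTGAAAATCTTCCATGTATCCTTC"
      "CCCACTCAACACATTACCCCTCCGGTAATATCCAGGTTACATTAAACAATAAAATAGGCTGATGTATCTT"
      "CCATTTCGCCTATATTCCCTGAACACAACCTAAAACTATTGTACTTGTCCCTCCCCACTTGATACAGACC"
      "ATACATAAAGACAGATCCCCACCCGTCTAACACCAACCAGACCACTCAAATCAGACTCGGCTACGAAAAA"
      "ACCGACACACTTAAACTACC")
S4 = ("GGCTTATCTTATGCAGGCAAGCGGCAAGATTTATCTCCGAAAGGAGGTGAAAACTTTCCACGTATCCTTC"
      "CCCACTCAACACATAACCCCTCCGGTAATATTCAGGTTACATTAAACAATAAAATAGGCTGATGTATCTT"
      "CCATTTCGCTTATATTCCCTGAACACAACCCACAACTATTGCACTTGTCCCTCCCCACTTGATACATACC"
      "ATACATAAAGACAGGTCCCCACCCGTCTAACACCAACCAGACCACTCAAATCAGACTCGGCTACGAAAAA"
      "ACCGACACACTTAAACTACC")


def test_summary_identical_sequences():
    stats = summary_stats([mk("073", f"s{i}") for i in range(4)], "g")
    assert (stats.s, stats.hd, stats.k, stats.pi) == (0, 0.0, 0.0, 0.0)


def test_summary_all_distinct_maximal_hd():
    motifs = [mk(t, t) for t in ("073", "146", "263", "489")]
    assert summary_stats(motifs, "g").hd == pytest.approx(1.0)


def test_summary_two_plus_two_toy():
    motifs = [mk("073-146-263", "a"), mk("073-146-263", "b"),
              mk("", "c"), mk("", "d")]
    stats = summary_stats(motifs, "toy", region_length=100)
    assert stats.hd == pytest.approx(2 / 3)
    assert stats.k == pytest.approx(2.0)       # 4 differing pairs * 3 / 6
    assert stats.pi == pytest.approx(0.02)
    assert stats.s == 3


def test_summary_requires_two_samples():
    with pytest.raises(ValueError):
        summary_stats([mk("073", "a")], "g")


def test_hd_invariant_under_relabelling():
    a = summary_stats([mk("073", "1"), mk("073", "2"), mk("146", "3")], "g")
    b = summary_stats([mk("489", "1"), mk("489", "2"), mk("263", "3")], "g")
    assert a.hd == pytest.approx(b.hd)


def test_tn93_identical_is_zero():
    assert tn93_distance(S3, S3) == 0.0


def test_tn93_matches_independent_oracle():
    s1 = "ACGT" * 25
    s2 = s1[:4] + "G" + s1[5:]          # one A->G transition in 100 sites
    assert tn93_distance(s1, s2, DistanceModel(gamma_alpha=None)) == \
        pytest.approx(0.0102055831, abs=1e-9)
    assert tn93_distance(s1, s2, DistanceModel(gamma_alpha=0.26)) == \
        pytest.approx(0.0110507534, abs=1e-9)
    assert tn93_distance(S3, S4, DistanceModel(gamma_alpha=None)) == \
        pytest.approx(0.0416238441, abs=1e-9)
    assert tn93_distance(S3, S4, DistanceModel(gamma_alpha=0.26)) == \
        pytest.approx(0.0489486621, abs=1e-9)


def test_tn93_dominates_p_distance():
    rng = np.random.default_rng(6)
    for _ in range(10):
        s1 = "".join(rng.choice(list("ACGT"), size=200))
        s2 = list(s1)
        for i in rng.choice(200, size=10, replace=False):
            s2[i] = rng.choice([b for b in "ACGT" if b != s1[i]])
        s2 = "".join(s2)
        plain = tn93_distance(s1, s2, DistanceModel(gamma_alpha=None))
        gamma = tn93_distance(s1, s2, DistanceModel(gamma_alpha=0.26))
        assert plain >= p_distance(s1, s2) - 1e-12
        assert gamma >= plain - 1e-12


def test_tn93_pairwise_deletion_of_ambiguity():
    s1 = "ACGTACGTAC"
    s2 = "ACGTNCGTAC"
    assert tn93_distance(s1, s2) == 0.0


def test_tn93_degenerate_falls_back_to_p_distance():
    s1 = "AG" * 50
    s2 = "GA" * 50                      # saturated transitions
    with pytest.warns(UserWarning, match="p-distance"):
        d = tn93_distance(s1, s2)
    assert d == pytest.approx(1.0)


def test_phist_identical_populations_zero():
    pa = [mk("073", f"a{i}", "A") for i in range(3)] + \
         [mk("146", f"a{i}", "A") for i in range(3)]
    pb = [mk("073", f"b{i}", "B") for i in range(3)] + \
         [mk("146", f"b{i}", "B") for i in range(3)]
    assert abs(pairwise_phist({"A": pa, "B": pb})[0].phi_st) < 1e-12


def test_phist_fixed_difference_is_one():
    pa = [mk("073", f"a{i}", "A") for i in range(4)]
    pb = [mk("146-263", f"b{i}", "B") for i in range(4)]
    assert pairwise_phist({"A": pa, "B": pb})[0].phi_st == pytest.approx(1.0)


def test_phist_matches_brute_force_amova():
    pops = {"A": [mk("073", "a1"), mk("073-146", "a2"), mk("", "a3")],
            "B": [mk("263", "b1"), mk("263-489", "b2"), mk("263", "b3")]}
    obs = pairwise_phist(pops)[0].phi_st
    members = pops["A"] + pops["B"]
    D = np.array([[len(a.variants ^ b.variants) for b in members]
                  for a in members], dtype=float)
    n = 6
    ss_total = D.sum() / (2 * n)
    ss_within = D[:3, :3].sum() / 6 + D[3:, 3:].sum() / 6
    sigma_w = (ss_within) / (n - 2)
    n_c = (n - (9 + 9) / n) / 1
    sigma_a = ((ss_total - ss_within) / 1 - sigma_w) / n_c
    assert obs == pytest.approx(sigma_a / (sigma_a + sigma_w))


def test_phist_permutation_detects_structure():
    rng = np.random.default_rng(12)
    pa = [mk("073-146", f"a{i}", "A") for i in range(8)]
    pb = [mk("263-489-523d", f"b{i}", "B") for i in range(8)]
    r = pairwise_phist({"A": pa, "B": pb}, permutations=199, seed=1)[0]
    assert r.p_value < 0.05


def test_phist_small_population_excluded():
    pops = {"A": [mk("073", "a1", "A")],
            "B": [mk("146", "b1", "B"), mk("146", "b2", "B")],
            "C": [mk("263", "c1", "C"), mk("", "c2", "C")]}
    with pytest.warns(UserWarning, match="excluded"):
        results = pairwise_phist(pops)
    assert {(r.pop1, r.pop2) for r in results} == {("B", "C")}


def test_phist_haplotype_mode_bounded():
    pa = [mk("073", f"a{i}", "A") for i in range(4)]
    pb = [mk("146-263-489", f"b{i}", "B") for i in range(4)]
    r = pairwise_phist({"A": pa, "B": pb}, mode="haplotype")[0]
    assert r.phi_st == pytest.approx(1.0)


def test_nj_three_taxa_closed_form():
    # d(AB)=3, d(AC)=5, d(BC)=6 -> a=1, b=2, c=4
    D = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
    newick = nj_tree(D, ["A", "B", "C"])
    from skbio import TreeNode
    tree = TreeNode.read(io.StringIO(newick))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 4.0})


def test_nj_additive_matrix_recovered_exactly():
    D = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
                 dtype=float)
    from skbio import TreeNode
    tree = TreeNode.read(io.StringIO(nj_tree(D, list("ABCD"))))
    got = tree.tip_tip_distances(list("ABCD"))
    assert np.allclose(got.filter(list("ABCD")).data, D)


def test_nj_topology_invariant_under_taxon_permutation():
    D = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
                 dtype=float)
    from skbio import TreeNode
    t1 = TreeNode.read(io.StringIO(nj_tree(D, list("ABCD"))))
    perm = [2, 0, 3, 1]
    Dp = D[np.ix_(perm, perm)]
    t2 = TreeNode.read(io.StringIO(nj_tree(Dp, [list("ABCD")[i] for i in perm])))
    assert t1.compare_rfd(t2) == 0.0


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        nj_tree(np.array([[0, 1], [2, 0]], dtype=float), ["A", "B"])


def test_phist_matrix_shape():
    pa = [mk("073", f"a{i}", "A") for i in range(3)]
    pb = [mk("146", f"b{i}", "B") for i in range(3)]
    pc = [mk("263", f"c{i}", "C") for i in range(3)]
    mat = phist_matrix(pairwise_phist({"A": pa, "B": pb, "C": pc}))
    assert list(mat.index) == ["A", "B", "C"]
    assert np.allclose(mat.values, mat.values.T)
    assert np.allclose(np.diag(mat.values), 0.0)
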