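"""Median-joining network construction, post-processing and the exhaustive
Steiner oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mitocr.network import (HaplotypeTable, build_mj, condense, ensure_node,
                            export_network, import_graphml, mp_postprocess,
                            steiner_minimal_cost)
from mitocr.variants import Motif, parse_motif
from tests.conftest import random_haplotype_set

mk = parse_motif


def test_condense_merges_identical_motifs():
    motifs = [mk("073", f"a{i}", "X") for i in range(4)] + \
             [mk("146", f"b{i}", "Y") for i in range(2)]
    table = condense(motifs)
    assert len(table.haplotypes) == 2
    assert sorted(sum(c.values()) for c in table.counts) == [2, 4]
    assert table.n_samples == 6


def test_condense_all_distinct_and_order_invariant():
    motifs = [mk("073", "a"), mk("146", "b"), mk("263", "c")]
    t1 = condense(motifs)
    t2 = condense(list(reversed(motifs)))
    assert len(t1.haplotypes) == 3
    assert t1.haplotypes == t2.haplotypes


def test_two_haplotypes_one_edge():
    net = build_mj(condense([mk("", "a"), mk("073", "b")]))
    assert net.graph.number_of_nodes() == 2
    assert net.graph.number_of_edges() == 1
    (u, v), = net.graph.edges
    assert {str(x) for x in net.edge_label(u, v)} == {"073"}


def test_median_vector_reduces_cost():
    # {} / {a,b} / {a,c} needs the median {a}: total cost 3 mutations
    net = build_mj(condense([mk("", "a"), mk("073-146", "b"), mk("073-263", "c")]))
    medians = [net.haplotype(n) for n in net.median_nodes]
    assert frozenset(mk("073").variants) in medians
    assert net.spanning_cost() == 3 * net.table.default_weight


def test_parallel_pairs_make_a_reticulation():
    motifs = [mk("", "a"), mk("073", "b"), mk("146", "c"), mk("073-146", "d")]
    net = build_mj(condense(motifs), epsilon=0)
    assert len(nx.cycle_basis(net.graph)) >= 1


def test_negative_epsilon_rejected():
    with pytest.raises(ValueError):
        build_mj(condense([mk("", "a"), mk("073", "b")]), epsilon=-1)


def test_observed_haplotypes_survive_postprocessing():
    rng = np.random.default_rng(2)
    motifs = random_haplotype_set(rng, 5, 6)
    net = mp_postprocess(build_mj(condense(motifs)))
    observed = {net.haplotype(n) for n in net.observed_nodes}
    assert observed == {m.variants for m in motifs}


def test_tree_shaped_network_unchanged_by_mp():
    motifs = [mk("", "a"), mk("073", "b"), mk("073-146", "c")]
    net = build_mj(condense(motifs))
    pruned = mp_postprocess(net)
    assert set(pruned.graph.nodes) == set(net.graph.nodes)
    assert set(pruned.graph.edges) == set(net.graph.edges)


def test_mp_preserves_minimum_cost():
    rng = np.random.default_rng(7)
    for _ in range(10):
        motifs = random_haplotype_set(rng, 5, 6)
        net = build_mj(condense(motifs))
        assert mp_postprocess(net).spanning_cost() == pytest.approx(
            net.spanning_cost())


def test_oracle_equivalence_small_instances():
    rng = np.random.default_rng(123)
    for _ in range(30):
        motifs = random_haplotype_set(rng, int(rng.integers(3, 7)),
                                      int(rng.integers(3, 9)))
        table = condense(motifs)
        net = mp_postprocess(build_mj(table, epsilon=0))
        assert net.spanning_cost() == pytest.approx(steiner_minimal_cost(table))


def test_cost_invariant_under_input_permutation():
    rng = np.random.default_rng(17)
    motifs = random_haplotype_set(rng, 5, 6)
    c1 = build_mj(condense(motifs)).spanning_cost()
    c2 = build_mj(condense(list(reversed(motifs)))).spanning_cost()
    assert c1 == pytest.approx(c2)


def test_weighted_distance_metric_axioms():
    rng = np.random.default_rng(31)
    motifs = random_haplotype_set(rng, 6, 7)
    weights = {v.position: int(rng.integers(1, 11))
               for m in motifs for v in m.variants}
    table = condense(motifs, site_weights=weights)

    def d(a, b):
        return sum(table.weight(x) for x in a.variants ^ b.variants)

    for a, b, c in itertools.combinations(motifs, 3):
        assert d(a, b) == d(b, a)
        assert d(a, c) <= d(a, b) + d(b, c)
        assert d(a, a) == 0


def test_excluded_sites_can_carry_zero_weight():
    table = condense([mk("", "a"), mk("152", "b"), mk("073-152", "c")],
                     site_weights={152: 0})
    net = build_mj(table)
    assert net.spanning_cost() == table.default_weight  # only 073 costs


def test_ensure_node_adds_missing_root():
    net = build_mj(condense([mk("073", "a"), mk("073-146", "b")]))
    rooted = ensure_node(net, mk("").variants)
    haps = [rooted.haplotype(n) for n in rooted.graph]
    assert frozenset() in haps
    assert nx.is_connected(rooted.graph)


def test_export_import_round_trip(tmp_path):
    motifs = [mk("", "a", "X"), mk("073-146", "b", "X"), mk("073-263", "c", "Y")]
    net = mp_postprocess(build_mj(condense(motifs)))
    path = tmp_path / "net.graphml"
    export_network(net, path)
    back = import_graphml(path)
    assert len(back.graph) == len(net.graph)
    orig = {(str(Motif(d["hap"])), d["kind"], tuple(sorted(d["counts"].items())))
            for _, d in net.graph.nodes(data=True)}
    loaded = {(str(Motif(d["hap"])), d["kind"], tuple(sorted(d["counts"].items())))
              for _, d in back.graph.nodes(data=True)}
    assert orig == loaded
    assert back.graph.number_of_edges() == net.graph.number_of_edges()


def test_export_dot_and_unknown_format(tmp_path):
    net = build_mj(condense([mk("", "a"), mk("073", "b")]))
    dot = tmp_path / "net.dot"
    export_network(net, dot, "dot")
    text = dot.read_text()
    assert text.startswith("graph mj") and '"0" -- "1"' in text
    with pytest.raises(ValueError):
        export_network(net, tmp_path / "x.foo", "foo")


def test_edge_labels_telescope_along_paths():
    rng = np.random.default_rng(4)
    motifs = random_haplotype_set(rng, 5, 6)
    net = mp_postprocess(build_mj(condense(motifs)))
    nodes = list(net.graph)
    for a, b in itertools.combinations(net.observed_nodes, 2):
        path = nx.shortest_path(net.graph, a, b)
        acc = frozenset()
        for u, v in zip(path, path[1:]):
            acc ^= net.edge_label(u, v)
        assert acc == net.haplotype(a) ^ net.haplotype(b)


def test_haplotype_table_rejects_nonpositive_counts():
    with pytest.raises(ValueError):
        HaplotypeTable([frozenset()], [{"X": 0}])
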