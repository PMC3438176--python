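"""Median-joining haplotype networks with site weights.

Haplotypes are encoded as presence/absence vectors over the set of variants
segregating in the sample, so the search space is a weighted hypercube: the
distance between two haplotypes is the summed weight of the variants in
their symmetric difference.  ``build_mj`` follows the median-joining
scheme: build the epsilon-relaxed minimum spanning network, repeatedly add
the majority-consensus (quasi-median) vector of connected triplets whenever
it lowers the cost of spanning the current node set, then discard median
vectors that no longer earn their place.  ``mp_postprocess`` prunes edges
and medians that lie on no minimum-cost tree spanning the observed
haplotypes (exact Steiner-based pruning for small networks).

``steiner_minimal_cost`` is an exhaustive Dreyfus-Wagner oracle over the
full hypercube, kept deliberately independent of the heuristic so that one
can validate the other.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .variants import Motif, Variant, format_variant, parse_motif

DEFAULT_SITE_WEIGHT = 10
LOW_WEIGHT = 5  # conventional down-weight for flagged homoplastic sites


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population counts and site weights."""

    haplotypes: list                  # list[frozenset[Variant]]
    counts: list                      # list[dict population -> int]
    site_weights: dict = field(default_factory=dict)
    default_weight: int = DEFAULT_SITE_WEIGHT

    def __post_init__(self):
        if any(sum(c.values()) <= 0 for c in self.counts):
            raise ValueError("haplotype counts must be positive")

    @property
    def n_samples(self):
        return sum(sum(c.values()) for c in self.counts)

    def weight(self, variant: Variant) -> int:
        return int(self.site_weights.get(variant.position, self.default_weight))

    def total_counts(self):
        return [sum(c.values()) for c in self.counts]


def condense(motifs, site_weights=None, default_weight=DEFAULT_SITE_WEIGHT) -> HaplotypeTable:
    """Merge identical motifs, keeping per-population counts.

    Output order is canonical (sorted by motif string), so permuting the
    input leaves the table unchanged.
    """
    groups: dict = {}
    for m in motifs:
        groups.setdefault(m.variants, {})
        pop = m.population or "all"
        groups[m.variants][pop] = groups[m.variants].get(pop, 0) + 1
    keys = sorted(groups, key=lambda h: str(Motif(h)))
    return HaplotypeTable([k for k in keys], [groups[k] for k in keys],
                          dict(site_weights or {}), default_weight)


# ---------------------------------------------------------------------------
# bit-vector machinery

class _Space:
    """The weighted hypercube spanned by the variants of a haplotype set."""

    def __init__(self, haplotypes, table: HaplotypeTable):
        self.variants = sorted({v for h in haplotypes for v in h},
                               key=Variant.sort_key)
        self.index = {v: i for i, v in enumerate(self.variants)}
        self.w = np.array([table.weight(v) for v in self.variants], dtype=float)

    def encode(self, hap) -> tuple:
        vec = np.zeros(len(self.variants), dtype=bool)
        for v in hap:
            vec[self.index[v]] = True
        return tuple(vec.tolist())

    def decode(self, vec) -> frozenset:
        return frozenset(v for v, bit in zip(self.variants, vec) if bit)

    def dist(self, a, b) -> float:
        return float(self.w[np.array(a) != np.array(b)].sum())

    def dist_matrix(self, vecs) -> np.ndarray:
        X = np.array(vecs, dtype=bool)
        return ((X[:, None, :] != X[None, :, :]) * self.w).sum(axis=2)


def _mst_cost(D: np.ndarray) -> float:
    """Prim MST cost on a dense symmetric distance matrix."""
    n = len(D)
    if n <= 1:
        return 0.0
    in_tree = np.zeros(n, dtype=bool)
    best = D[0].copy()
    in_tree[0] = True
    best[0] = np.inf
    total = 0.0
    for _ in range(n - 1):
        j = int(np.argmin(best))
        total += best[j]
        in_tree[j] = True
        best = np.minimum(best, D[j])
        best[in_tree] = np.inf
    return float(total)


def _minimax_levels(D: np.ndarray) -> np.ndarray:
    """minimax(u,v): the largest edge on the MST path, i.e. the Kruskal
    level at which u and v first become connected."""
    n = len(D)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mm = np.zeros((n, n))
    comp_members = {i: [i] for i in range(n)}
    pairs = sorted(((D[i, j], i, j) for i in range(n) for j in range(i + 1, n)))
    for d, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        for a in comp_members[ri]:
            for b in comp_members[rj]:
                mm[a, b] = mm[b, a] = d
        parent[rj] = ri
        comp_members[ri].extend(comp_members.pop(rj))
    return mm


def _msn_edges(D: np.ndarray, epsilon: float):
    """Edges of the epsilon-relaxed minimum spanning network."""
    mm = _minimax_levels(D)
    n = len(D)
    return [(i, j) for i in range(n) for j in range(i + 1, n)
            if D[i, j] <= mm[i, j] + epsilon + 1e-9]


# ---------------------------------------------------------------------------
# the network object

class MedianNetwork:
    """Graph of observed haplotypes plus inferred median vectors."""

    def __init__(self, graph: nx.Graph, epsilon: float, table: HaplotypeTable):
        self.graph = graph
        self.epsilon = epsilon
        self.table = table

    @property
    def observed_nodes(self):
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def median_nodes(self):
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def haplotype(self, node) -> frozenset:
        return self.graph.nodes[node]["hap"]

    def edge_label(self, u, v) -> frozenset:
        return self.haplotype(u) ^ self.haplotype(v)

    def edge_weight(self, u, v) -> float:
        return sum(self.table.weight(x) for x in self.edge_label(u, v))

    def mst_cost(self) -> float:
        """Cost of a minimum spanning tree over *all* current nodes."""
        space = _Space([self.haplotype(n) for n in self.graph], self.table)
        vecs = [space.encode(self.haplotype(n)) for n in self.graph]
        return _mst_cost(space.dist_matrix(vecs))

    def spanning_cost(self) -> float:
        """Minimum cost of connecting the observed haplotypes within the
        network (medians optional) — exact for <=14 observed haplotypes."""
        terms = self.observed_nodes
        if len(terms) > 14:
            return self.mst_cost()
        return _graph_steiner_cost(self.graph, terms,
                                   lambda u, v: self.edge_weight(u, v))


def build_mj(table: HaplotypeTable, epsilon: float = 0) -> MedianNetwork:
    """Median-joining network of a haplotype table.

    Ties between equally-improving candidate medians are broken toward the
    lexicographically smallest variant set, so the construction is
    deterministic under input permutation.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    observed = list(table.haplotypes)
    if len(observed) < 2:
        raise ValueError("need at least two distinct haplotypes")
    space = _Space(observed, table)
    nodes = [space.encode(h) for h in observed]
    observed_set = set(nodes)

    if len(space.variants) <= 10 and len(observed_set) <= 8:
        # small instance: the full quasi-median closure provably contains
        # the branch points of every minimum-cost tree of the observed
        # haplotypes, so medians can be selected exactly
        nodes = _median_closure(nodes)
        nodes = _exact_median_selection(nodes, observed_set, space)
        return _to_network(nodes, observed_set, space, table, epsilon)

    max_medians = max(4 * len(nodes), 64)
    while True:
        D = space.dist_matrix(nodes)
        edges = _msn_edges(D, epsilon)
        adj = {i: set() for i in range(len(nodes))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        # quasi-medians of triplets connected in the network, with their
        # connection costs lambda = d(u,x) + d(v,x) + d(w,x)
        node_set = set(nodes)
        cands: dict = {}
        for u in range(len(nodes)):
            for v, t in itertools.combinations(sorted(adj[u]), 2):
                a, b, c = (np.array(nodes[u]), np.array(nodes[v]),
                           np.array(nodes[t]))
                med = tuple((a.astype(int) + b + c >= 2).tolist())
                if med in node_set:
                    continue
                lam = sum(space.dist(med, nodes[x]) for x in (u, v, t))
                if med not in cands or lam < cands[med]:
                    cands[med] = lam
        if not cands:
            break
        lam_min = min(cands.values())
        to_add = sorted((m for m, lam in cands.items()
                         if lam <= lam_min + epsilon + 1e-9),
                        key=lambda m: _lex_key(space, m))
        room = max_medians - (len(nodes) - len(observed_set))
        if room <= 0:
            break
        nodes.extend(to_add[:room])

    # drop median vectors whose removal leaves the spanning cost unchanged
    changed = True
    while changed:
        changed = False
        cost = _mst_cost(space.dist_matrix(nodes))
        medians = sorted((m for m in nodes if m not in observed_set),
                         key=lambda m: _lex_key(space, m))
        for m in medians:
            rest = [x for x in nodes if x != m]
            if _mst_cost(space.dist_matrix(rest)) <= cost + 1e-9:
                nodes = rest
                changed = True
                break

    return _to_network(nodes, observed_set, space, table, epsilon)


def _median_closure(nodes, cap: int = 1024):
    """Close a set of binary vectors under coordinate-wise majority of
    triples (the quasi-median closure)."""
    current = list(dict.fromkeys(nodes))
    frontier = list(current)
    while frontier and len(current) < cap:
        new = []
        seen = set(current)
        for a, b, c in itertools.combinations(current, 3):
            med = tuple((x + y + z) >= 2 for x, y, z in zip(a, b, c))
            if med not in seen:
                seen.add(med)
                new.append(med)
        frontier = new
        current.extend(new)
    return current[:cap]


def _exact_median_selection(nodes, observed_set, space):
    """Keep exactly the median vectors that lie on some minimum-cost tree
    spanning the observed haplotypes (Steiner node forcing)."""
    D = space.dist_matrix(nodes)
    terms = [i for i, v in enumerate(nodes) if v in observed_set]
    c_star = _graph_steiner_cost(None, terms, None, closure=D,
                                 node_order=range(len(nodes)))
    kept = []
    for i, vec in enumerate(nodes):
        if vec in observed_set:
            kept.append(vec)
            continue
        c_forced = _graph_steiner_cost(None, terms + [i], None, closure=D,
                                       node_order=range(len(nodes)))
        if c_forced <= c_star + 1e-9:
            kept.append(vec)
    return kept


def _lex_key(space, vec):
    return tuple(format_variant(v) for v in sorted(space.decode(vec),
                                                   key=Variant.sort_key))


def _to_network(nodes, observed_set, space, table, epsilon):
    D = space.dist_matrix(nodes)
    edges = _msn_edges(D, epsilon)
    g = nx.Graph()
    hap_index = {h: i for i, h in enumerate(table.haplotypes)}
    for i, vec in enumerate(nodes):
        hap = space.decode(vec)
        if vec in observed_set:
            idx = hap_index[hap]
            g.add_node(i, hap=hap, kind="observed",
                       counts=dict(table.counts[idx]))
        else:
            g.add_node(i, hap=hap, kind="median", counts={})
    for i, j in edges:
        label = space.decode(nodes[i]) ^ space.decode(nodes[j])
        g.add_edge(i, j, weight=float(D[i, j]),
                   label="/".join(sorted(format_variant(v) for v in label)))
    return MedianNetwork(g, epsilon, table)


def ensure_node(network: MedianNetwork, hap) -> MedianNetwork:
    """Return a network guaranteed to contain ``hap`` (e.g. a clade's nodal
    haplotype used as a dating root); if absent it is added as an inferred
    node and the spanning network is recomputed at the same epsilon."""
    hap = frozenset(hap)
    haps = [network.haplotype(n) for n in network.graph]
    if hap in haps:
        return network
    table = network.table
    space = _Space(haps + [hap], table)
    nodes = [space.encode(h) for h in haps] + [space.encode(hap)]
    observed = {space.encode(network.haplotype(n))
                for n in network.observed_nodes}
    return _to_network(nodes, observed, space, table, network.epsilon)


# ---------------------------------------------------------------------------
# maximum-parsimony post-processing

def _graph_steiner_cost(graph: nx.Graph, terminals, weight_fn,
                        closure: np.ndarray | None = None,
                        node_order=None) -> float:
    """Exact Steiner tree cost of ``terminals`` within ``graph``
    (Dreyfus-Wagner on the graph's metric closure).

    ``closure`` may supply a precomputed all-pairs shortest-path matrix
    (indexed by ``node_order``) when the caller knows it in closed form.
    """
    nodes = list(graph.nodes) if node_order is None else list(node_order)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    if closure is not None:
        W = closure
    else:
        W = np.full((n, n), np.inf)
        np.fill_diagonal(W, 0.0)
        for u, v in graph.edges:
            w = weight_fn(u, v)
            i, j = idx[u], idx[v]
            W[i, j] = W[j, i] = min(W[i, j], w)
        # Floyd-Warshall metric closure
        for k in range(n):
            W = np.minimum(W, W[:, k:k + 1] + W[k:k + 1, :])
    terms = [idx[t] for t in terminals]
    if len(terms) <= 1:
        return 0.0
    t0, rest = terms[0], terms[1:]
    k = len(rest)
    S = {}
    for i, t in enumerate(rest):
        S[1 << i] = W[t].copy()
    for size in range(2, k + 1):
        for Dmask in (m for m in range(1, 1 << k) if bin(m).count("1") == size):
            M = np.full(n, np.inf)
            sub = (Dmask - 1) & Dmask
            while sub:
                if sub < (Dmask ^ sub):   # each split once
                    M = np.minimum(M, S[sub] + S[Dmask ^ sub])
                sub = (sub - 1) & Dmask
            S[Dmask] = np.min(M[None, :] + W, axis=1) if np.isfinite(M).any() else M
    full = (1 << k) - 1
    return float(S[full][t0])


def mp_postprocess(network: MedianNetwork) -> MedianNetwork:
    """Delete every edge and median vector lying on no minimum-cost tree
    spanning the observed haplotypes within the network.

    Exact (Steiner enumeration by edge forcing) for networks with at most
    14 observed haplotypes; larger networks fall back to union-of-minimum-
    spanning-trees pruning, which never removes an observed node.
    """
    g = network.graph.copy()
    for u, v in g.edges:
        g.edges[u, v]["w"] = network.edge_weight(u, v)
    wf = lambda graph: (lambda u, v: graph.edges[u, v]["w"])
    terms = network.observed_nodes

    def contract(graph, u, v):
        h = nx.Graph()
        h.add_nodes_from(n for n in graph if n != v)
        for a, b, d in graph.edges(data=True):
            a2 = u if a == v else a
            b2 = u if b == v else b
            if a2 == b2:
                continue
            if h.has_edge(a2, b2):
                h.edges[a2, b2]["w"] = min(h.edges[a2, b2]["w"], d["w"])
            else:
                h.add_edge(a2, b2, w=d["w"])
        return h

    if 2 <= len(terms) <= 14:
        c_star = _graph_steiner_cost(g, terms, wf(g))
        drop = []
        for u, v in g.edges:
            gc = contract(g, u, v)
            t2 = list(dict.fromkeys([u if t == v else t for t in terms] + [u]))
            if g.edges[u, v]["w"] + _graph_steiner_cost(gc, t2, wf(gc)) \
                    > c_star + 1e-9:
                drop.append((u, v))
        g.remove_edges_from(drop)
    else:
        for u, v in list(g.edges):
            w = g.edges[u, v]["w"]
            light = [(a, b) for a, b, d in g.edges(data=True)
                     if d["w"] < w - 1e-9]
            sub = nx.Graph(light)
            if u in sub and v in sub and nx.has_path(sub, u, v):
                g.remove_edge(u, v)
    # medians disconnected from the observed component, or isolated, go
    term_set = set(terms)
    changed = True
    while changed:
        changed = False
        for m in [n for n, d in g.nodes(data=True) if d["kind"] == "median"]:
            if g.degree(m) <= 1:
                g.remove_node(m)
                changed = True
    for comp in list(nx.connected_components(g)):
        if not comp & term_set:
            g.remove_nodes_from(comp)
    return MedianNetwork(g, network.epsilon, network.table)


# ---------------------------------------------------------------------------
# exhaustive oracle

def steiner_minimal_cost(table: HaplotypeTable) -> float:
    """Exhaustive Steiner minimal tree cost over the full hypercube of
    variant combinations (Dreyfus-Wagner; feasible for <=12 segregating
    variants).  Independent of the median-joining heuristic."""
    space = _Space(table.haplotypes, table)
    B = len(space.variants)
    if B > 12:
        raise ValueError("oracle limited to 12 segregating variants")
    V = 1 << B
    # hypercube metric closure in closed form: weighted Hamming distance
    bits = ((np.arange(V)[:, None] >> np.arange(B)[None, :]) & 1).astype(bool)
    W = ((bits[:, None, :] != bits[None, :, :]) * space.w).sum(axis=2)
    terms = [sum(1 << b for b in range(B) if space.encode(h)[b])
             for h in table.haplotypes]
    return _graph_steiner_cost(None, list(dict.fromkeys(terms)), None,
                               closure=W, node_order=range(V))


# ---------------------------------------------------------------------------
# export / import

def export_network(network: MedianNetwork, path, fmt: str = "graphml"):
    """Write the network with round-trippable attributes (graphml or dot)."""
    g = nx.Graph()
    g.graph["epsilon"] = network.epsilon
    for n, d in network.graph.nodes(data=True):
        g.add_node(str(n), kind=d["kind"], motif=str(Motif(d["hap"])),
                   counts=json.dumps(d["counts"], sort_keys=True))
    for u, v, d in network.graph.edges(data=True):
        g.add_edge(str(u), str(v), label=d["label"], weight=float(d["weight"]))
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("graph mj {\n")
            for n, d in g.nodes(data=True):
                fh.write(f'  "{n}" [kind="{d["kind"]}", motif="{d["motif"]}", '
                         f'counts="{d["counts"].replace(chr(34), chr(39))}"];\n')
            for u, v, d in g.edges(data=True):
                fh.write(f'  "{u}" -- "{v}" [label="{d["label"]}", '
                         f'weight="{d["weight"]}"];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_graphml(path, table: HaplotypeTable | None = None) -> MedianNetwork:
    raw = nx.read_graphml(path)
    g = nx.Graph()
    for n, d in raw.nodes(data=True):
        g.add_node(n, hap=parse_motif(d["motif"]).variants, kind=d["kind"],
                   counts=json.loads(d["counts"]))
    for u, v, d in raw.edges(data=True):
        g.add_edge(u, v, label=d.get("label", ""), weight=float(d.get("weight", 0)))
    if table is None:
        haps = [d["hap"] for n, d in g.nodes(data=True) if d["kind"] == "observed"]
        counts = [d["counts"] or {"all": 1}
                  for n, d in g.nodes(data=True) if d["kind"] == "observed"]
        table = HaplotypeTable(haps, counts)
    return MedianNetwork(g, float(raw.graph.get("epsilon", 0)), table)
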