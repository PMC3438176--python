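"""Founder-age (TMRCA) estimation from the rho statistic, and a classic
skyline demographic reconstruction.

rho is the mean number of mutations separating each sampled individual
from the clade's founding (nodal) haplotype; under a molecular clock it is
linear in time, so a named calibration converts it to years.  The standard
error follows Saillard et al.'s estimator computed on a spanning tree of
the network: sigma^2 = sum over edges of (n_e/n)^2 * m_e, with n_e the
individuals whose root path uses the edge and m_e the mutations on it.

``classic_skyline`` converts the coalescent intervals of an ultrametric
genealogy into stepwise female effective sizes, Nef_k = I_k * k(k-1)/2 (in
generations), the deterministic counterpart of Bayesian skyline plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .network import MedianNetwork
from .reference import DEFAULT_REGION

GENERATION_YEARS = 25.0


@dataclass(frozen=True)
class ClockCalibration:
    """A named mutation-rate calibration.

    ``rate-based`` clocks carry mutations/site/Myr and need a region length;
    ``per-mutation`` clocks carry years per mutation.
    """

    name: str
    mode: str                      # "rate-based" | "per-mutation"
    rate: float
    region_length: int | None = None

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.mode not in ("rate-based", "per-mutation"):
            raise ValueError(f"unknown clock mode {self.mode!r}")


#: The per-mutation control-region constant (9,058 yr/mutation) is the
#: linear coefficient of the published control-region rho calculator.
SOARES_YEARS_PER_MUTATION = 9058.0

def default_clocks(region_length: int = DEFAULT_REGION.total_length):
    """Registry of the five calibrations used for founder-age tables."""
    return {
        "howell": ClockCalibration("howell", "rate-based", 0.45, region_length),
        "kemp": ClockCalibration("kemp", "rate-based", 0.34, region_length),
        "endicott": ClockCalibration("endicott", "rate-based", 0.302, region_length),
        "santos": ClockCalibration("santos", "rate-based", 0.24, region_length),
        "soares_cr": ClockCalibration("soares_cr", "per-mutation",
                                      SOARES_YEARS_PER_MUTATION),
    }


@dataclass(frozen=True)
class RhoEstimate:
    clade: str
    rho: float
    sigma: float
    n: int

    def __post_init__(self):
        if self.rho < 0 or self.sigma < 0 or self.n < 1:
            raise ValueError("invalid rho estimate")


@dataclass(frozen=True)
class AgeEstimate:
    clade: str
    calibration: str
    age_years: int
    ci: tuple | None = None


def _round_year(x: float) -> int:
    return int(math.floor(x + 0.5))   # half-up, matching printed tables


def rho_sigma(network: MedianNetwork, root, clade: str = "",
              per_individual: bool = True) -> RhoEstimate:
    """rho and its standard error for a network rooted at a nodal haplotype.

    ``root`` is a node id of the network, or a haplotype (set of variants)
    matching one node.  Reticulations are resolved on a minimum-cost
    spanning tree of the network, ties broken toward paths through
    higher-frequency nodes.  Distances count each variant as one mutation.
    With ``per_individual`` (the default) every sampled individual
    contributes; otherwise each distinct haplotype counts once.
    """
    g = network.graph
    if root not in g:
        matches = [n for n in g if network.haplotype(n) == frozenset(root)]
        if not matches:
            raise ValueError("root haplotype not present in the network")
        root = matches[0]
    if not nx.is_connected(g):
        raise ValueError("network is disconnected")

    def node_count(n):
        return sum(g.nodes[n]["counts"].values()) if g.nodes[n]["kind"] == "observed" else 0

    # mutation-count spanning tree; prefer heavier (higher-frequency) ends
    t = nx.Graph()
    t.add_nodes_from(g)
    edges = sorted(g.edges,
                   key=lambda e: (len(network.edge_label(*e)),
                                  -(node_count(e[0]) + node_count(e[1])),
                                  tuple(sorted(map(str, e)))))
    uf = {n: n for n in g}

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            uf[ru] = rv
            t.add_edge(u, v, m=len(network.edge_label(u, v)))

    counts = {n: (node_count(n) if per_individual else
                  (1 if g.nodes[n]["kind"] == "observed" else 0)) for n in g}
    n_total = sum(counts.values())
    if n_total < 1:
        raise ValueError("no sampled individuals in the network")

    # one DFS from the root gives distances and subtree counts
    dist = {root: 0}
    order = [root]
    parent = {root: None}
    for node in order:
        for nb in t.neighbors(node):
            if nb not in dist:
                dist[nb] = dist[node] + t.edges[node, nb]["m"]
                parent[nb] = node
                order.append(nb)
    rho = sum(counts[n] * dist[n] for n in g) / n_total
    below = dict(counts)
    var = 0.0
    for node in reversed(order[1:]):
        below[parent[node]] += below[node]
        m_e = t.edges[node, parent[node]]["m"]
        var += (below[node] / n_total) ** 2 * m_e
    return RhoEstimate(clade, rho, math.sqrt(var), n_total)


def rho_to_age(estimate: RhoEstimate, calibration: ClockCalibration) -> AgeEstimate:
    """Convert rho to years BP under a calibration (rounded to the year)."""
    def convert(r):
        if calibration.mode == "per-mutation":
            return r * calibration.rate
        if not calibration.region_length:
            raise ValueError("rate-based clock needs a region length")
        return r / (calibration.rate * 1e-6 * calibration.region_length)

    lo = max(estimate.rho - 1.96 * estimate.sigma, 0.0)
    hi = estimate.rho + 1.96 * estimate.sigma
    return AgeEstimate(estimate.clade, calibration.name,
                       _round_year(convert(estimate.rho)),
                       (_round_year(convert(lo)), _round_year(convert(hi))))


def rescale_age(age_years: float, from_rate: float, to_rate: float) -> int:
    """Rescale an age between mutation rates (ages are inversely
    proportional to the rate)."""
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("rates must be positive")
    return _round_year(age_years * from_rate / to_rate)


@dataclass(frozen=True)
class SkylineStep:
    start_years_bp: float        # older bound
    end_years_bp: float          # younger bound
    nef: float
    k: int                       # lineages extant during the interval


def classic_skyline(genealogy, generation_time: float = GENERATION_YEARS):
    """Classic skyline estimate from an ultrametric genealogy.

    ``genealogy`` provides tip and internal node times in years BP (see
    :class:`mitocr.simulate.Genealogy`; a Newick string with branch lengths
    in years is also accepted).  Steps are returned oldest first.
    """
    times = _coalescent_times(genealogy)
    n = len(times) + 1
    events = sorted(times)               # years BP, youngest first
    steps = []
    prev = 0.0
    k = n
    for t in events:
        interval_years = t - prev
        if interval_years < -1e-6:
            raise ValueError("negative coalescent interval")
        gens = interval_years / generation_time
        steps.append(SkylineStep(t, prev, gens * k * (k - 1) / 2.0, k))
        prev = t
        k -= 1
    steps.reverse()
    return steps


def skyline_harmonic_mean(steps) -> float:
    """Time-weighted harmonic mean of the skyline (a natural single-number
    summary of effective size over the genealogy's depth)."""
    total = sum(s.start_years_bp - s.end_years_bp for s in steps)
    denom = sum((s.start_years_bp - s.end_years_bp) / s.nef
                for s in steps if s.nef > 0)
    if denom <= 0:
        raise ValueError("degenerate skyline")
    return total / denom


def skyline_epoch_ratio(steps) -> float:
    """Recent/ancient effective-size ratio: time-weighted harmonic mean of
    the younger half of coalescent events over that of the older half."""
    half = len(steps) // 2
    old, recent = steps[:half], steps[half:]
    if not old or not recent:
        raise ValueError("need at least two skyline steps")
    return skyline_harmonic_mean(recent) / skyline_harmonic_mean(old)


def _coalescent_times(genealogy):
    if hasattr(genealogy, "coalescent_times_years"):
        times = list(genealogy.coalescent_times_years())
    else:
        times = _times_from_newick(str(genealogy))
    if not times:
        raise ValueError("genealogy has no coalescences")
    return times


def _times_from_newick(newick: str):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.calc_node_ages(ultrametricity_precision=1e-3)
    return [nd.age for nd in tree.ageorder_node_iter() if not nd.is_leaf()]
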