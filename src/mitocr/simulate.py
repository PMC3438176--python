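"""Coalescent simulation of control-region datasets with known truth.

The generator produces female-line (haploid) genealogies under constant,
exponential-growth or piecewise demographies, sprinkles finite-sites
mutations with optional gamma rate heterogeneity across sites, and emits
motifs/sequences whose founder haplotype carries a chosen clade's
diagnostic variants.  Every run is seeded; the accompanying
:class:`SimTruth` records the quantities (TMRCA, genealogy, demography,
per-branch mutation counts) that downstream estimators try to recover.

Scenario presets mirror the demographic narratives of the southern South
American clades: a constant-size clade (b2l-like), steady growth from the
early Holocene (d1g-like) and an order-of-magnitude expansion starting
5,000 years BP (c1b13-like), plus a two-deme split for differentiation
tests.  Clade founder ages near 14-15 kyr correspond to small within-clade
effective sizes (TMRCA ~ 2*Nef generations), which is what the presets
encode.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .clades import default_registry
from .reference import DEFAULT_REGION, TRANSITION, RegionSpec, region_reference
from .variants import (TRANSITION_KIND, TRANSVERSION_KIND, Motif, Variant,
                       format_motif, parse_motif)
from .align import apply_motif

GENERATION_YEARS = 25.0


@dataclass(frozen=True)
class _Epoch:
    start_g: float              # backward time, generations
    end_g: float                # may be inf
    n_start: float              # Nef at start_g
    growth: float = 0.0         # backward growth rate per generation

    def size_at(self, tau: float) -> float:
        return self.n_start * math.exp(self.growth * (tau - self.start_g))


@dataclass(frozen=True)
class DemographyModel:
    """Female effective size through (backward) time."""

    kind: str
    epochs: tuple
    generation_time: float = GENERATION_YEARS

    @classmethod
    def constant(cls, nef: float, generation_time: float = GENERATION_YEARS):
        if nef <= 0:
            raise ValueError("Nef must be positive")
        return cls("constant", (_Epoch(0.0, math.inf, nef),), generation_time)

    @classmethod
    def exponential_growth(cls, n_present: float, n_ancestral: float,
                           onset_years_bp: float,
                           generation_time: float = GENERATION_YEARS):
        """Exponential size change between the onset and the present,
        constant ``n_ancestral`` before."""
        if min(n_present, n_ancestral, onset_years_bp) <= 0:
            raise ValueError("sizes and onset must be positive")
        t_g = onset_years_bp / generation_time
        rho = math.log(n_ancestral / n_present) / t_g
        return cls("exponential-growth",
                   (_Epoch(0.0, t_g, n_present, rho),
                    _Epoch(t_g, math.inf, n_ancestral)),
                   generation_time)

    @classmethod
    def piecewise(cls, steps, generation_time: float = GENERATION_YEARS):
        """``steps`` = [(start_years_bp, nef), ...] with start 0 first."""
        epochs = []
        steps = sorted(steps)
        if not steps or steps[0][0] != 0:
            raise ValueError("piecewise demography must start at 0 BP")
        for i, (start, nef) in enumerate(steps):
            if nef <= 0:
                raise ValueError("sizes must be positive")
            end = steps[i + 1][0] if i + 1 < len(steps) else math.inf
            epochs.append(_Epoch(start / generation_time, end / generation_time, nef))
        return cls("piecewise", tuple(epochs), generation_time)

    def size_at_years(self, years_bp: float) -> float:
        tau = years_bp / self.generation_time
        for ep in self.epochs:
            if ep.start_g <= tau < ep.end_g:
                return ep.size_at(tau)
        return self.epochs[-1].size_at(tau)

    def sample_coalescence(self, tau0: float, k: int, rng, cap: float = math.inf):
        """Next pair-coalescence time after ``tau0`` (generations) with k
        lineages (rate k(k-1)/(2*Nef(t))), truncated at ``cap``."""
        c = k * (k - 1) / 2.0
        if c <= 0:
            return math.inf
        for ep in self.epochs:
            if ep.end_g <= tau0:
                continue
            s = max(tau0, ep.start_g)
            n_s = ep.size_at(s)
            if ep.growth == 0.0:
                w = rng.exponential(n_s / c)
            else:
                u = rng.exponential(1.0)
                inner = 1.0 - u * ep.growth * n_s / c
                w = math.inf if inner <= 0 else -math.log(inner) / ep.growth
            t = s + w
            if t < min(ep.end_g, cap):
                return t
            if ep.end_g >= cap:
                return math.inf
        return math.inf


@dataclass
class Genealogy:
    """Ultrametric genealogy; node times in years BP (tips at 0)."""

    parent: list                 # parent index or -1
    time_years: list             # node age in years BP
    tip_ids: list                # names of the first len(tip_ids) nodes
    populations: list = field(default_factory=list)

    @property
    def n_tips(self):
        return len(self.tip_ids)

    @property
    def root(self):
        return self.parent.index(-1)

    @property
    def tmrca_years(self):
        return max(self.time_years)

    def coalescent_times_years(self):
        return sorted(self.time_years[self.n_tips:])

    def branches(self):
        """(child, parent, length_years) over all non-root nodes."""
        for child, par in enumerate(self.parent):
            if par >= 0:
                yield child, par, self.time_years[par] - self.time_years[child]

    def newick(self) -> str:
        children: dict = {}
        for child, par in enumerate(self.parent):
            children.setdefault(par, []).append(child)

        def fmt(node):
            if node < self.n_tips:
                label = self.tip_ids[node]
            else:
                label = ""
            kids = children.get(node, [])
            if not kids:
                return f"{label}"
            inner = ",".join(
                f"{fmt(k)}:{self.time_years[node] - self.time_years[k]:.6f}"
                for k in kids)
            return f"({inner}){label}"

        return fmt(self.root) + ";"


@dataclass
class SimConfig:
    n: int = 30
    mutation_rate: float = 0.302          # mutations/site/Myr
    region: RegionSpec = DEFAULT_REGION
    gamma_alpha: float | None = 0.26
    founder_motif: Motif = Motif()
    demography: DemographyModel = None
    seed: int = 0
    generation_time: float = GENERATION_YEARS
    transition_bias: float = 0.95
    mask_diagnostic: bool = True
    population: str = "pop1"

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.demography is None:
            self.demography = DemographyModel.constant(
                1000.0, self.generation_time)


@dataclass
class SimTruth:
    tmrca_years: float
    newick: str
    branch_mutations: dict
    demography: str
    founder_motif: str
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "tmrca_years": self.tmrca_years,
            "newick": self.newick,
            "branch_mutations": {str(k): v for k, v in self.branch_mutations.items()},
            "demography": self.demography,
            "founder_motif": self.founder_motif,
            "seed": self.seed}, indent=1)


def simulate_genealogy(config: SimConfig, rng=None) -> Genealogy:
    """Standard (Kingman) coalescent of ``config.n`` tips under the
    configured demography; deterministic for a fixed seed."""
    rng = rng or np.random.default_rng(config.seed)
    demo = config.demography
    g = config.generation_time
    n = config.n
    parent = [-1] * n
    times = [0.0] * n
    active = list(range(n))
    tau = 0.0
    while len(active) > 1:
        tau = demo.sample_coalescence(tau, len(active), rng)
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent.append(-1)
        times.append(tau * g)
        new = len(parent) - 1
        parent[a] = parent[b] = new
        active = [x for x in active if x not in (a, b)] + [new]
    tips = [f"s{i + 1}" for i in range(n)]
    return Genealogy(parent, times, tips, [config.population] * n)


def sprinkle_mutations(genealogy: Genealogy, config: SimConfig, rng=None):
    """Drop Poisson mutations on branches and return (motifs, SimTruth).

    Sites mutate by toggling: a hit at an already-derived site reverts it;
    otherwise the site gains a transition with probability
    ``transition_bias``, else a transversion.  Diagnostic (founder) sites
    are masked from the mutable set by default so that classification truth
    stays unambiguous.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    positions = [p for p in config.region.positions()]
    masked = {v.position for v in config.founder_motif.variants} \
        if config.mask_diagnostic else set()
    sites = np.array([p for p in positions if p not in masked])
    if config.gamma_alpha:
        site_rates = rng.gamma(config.gamma_alpha, 1.0 / config.gamma_alpha,
                               size=len(sites))
    else:
        site_rates = np.ones(len(sites))
    per_year = config.mutation_rate * 1e-6
    site_prob = site_rates / site_rates.sum()
    total_rate = per_year * site_rates.sum()     # per branch-year

    ref = region_reference(config.region)
    children: dict = {}
    for child, par, _ in genealogy.branches():
        children.setdefault(par, []).append(child)

    founder = {v.position: v for v in config.founder_motif.variants}
    states = {genealogy.root: dict(founder)}
    branch_counts = {}
    order = [genealogy.root]
    for node in order:
        order.extend(children.get(node, []))
    for node in order:
        if node == genealogy.root:
            continue
        par = genealogy.parent[node]
        state = dict(states[par])
        length = genealogy.time_years[par] - genealogy.time_years[node]
        k = rng.poisson(total_rate * length)
        branch_counts[node] = int(k)
        for s_idx in rng.choice(len(sites), size=k, p=site_prob):
            pos = int(sites[s_idx])
            if pos in state:
                del state[pos]                  # back mutation
            else:
                base = ref[config.region.to_index(pos)]
                if rng.random() < config.transition_bias:
                    state[pos] = Variant(pos, TRANSITION_KIND, TRANSITION[base])
                else:
                    others = [b for b in "ACGT"
                              if b != base and b != TRANSITION[base]]
                    state[pos] = Variant(pos, TRANSVERSION_KIND,
                                         others[int(rng.integers(2))])
        states[node] = state
    motifs = [Motif(frozenset(states[i].values()), genealogy.tip_ids[i],
                    genealogy.populations[i] if genealogy.populations else
                    config.population)
              for i in range(genealogy.n_tips)]
    truth = SimTruth(genealogy.tmrca_years, genealogy.newick(), branch_counts,
                     config.demography.kind, format_motif(config.founder_motif),
                     config.seed)
    return motifs, truth


# ---------------------------------------------------------------------------
# presets

def _founder(clade: str) -> Motif:
    reg = default_registry()
    variants = frozenset()
    cur = clade
    while cur is not None:
        variants |= reg[cur].defining
        cur = reg[cur].parent
    return Motif(variants)


def scenario_config(name: str, seed: int, n: int = 40) -> SimConfig:
    """Named simulation presets (see module docstring)."""
    if name == "b2l-like":
        return SimConfig(n=n, seed=seed, founder_motif=_founder("B2l"),
                         demography=DemographyModel.constant(300.0),
                         population="b2l")
    if name == "d1g-like":
        return SimConfig(n=n, seed=seed, founder_motif=_founder("D1g"),
                         demography=DemographyModel.exponential_growth(
                             1500.0, 300.0, 9000.0),
                         population="d1g")
    if name == "c1b13-like":
        return SimConfig(n=n, seed=seed, founder_motif=_founder("C1b13"),
                         demography=DemographyModel.exponential_growth(
                             2000.0, 200.0, 5000.0),
                         population="c1b13")
    if name == "constant-validation":
        # deep constant-size scenario for estimator validation: a slow
        # uniform-rate clock keeps the region far from saturation
        return SimConfig(n=30, seed=seed, mutation_rate=0.01, gamma_alpha=None,
                         demography=DemographyModel.constant(5000.0),
                         population="validation")
    raise ValueError(f"unknown scenario {name!r}")


def simulate_two_deme(n_per_deme: int, split_generations: float, nef: float,
                      seed: int, generation_time: float = GENERATION_YEARS
                      ) -> Genealogy:
    """Two demes of size ``nef`` with no migration, merging into one
    ancestral deme of the same size ``split_generations`` ago."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_deme
    parent = [-1] * n
    times = [0.0] * n
    demo = DemographyModel.constant(nef, generation_time)
    deme_lineages = [list(range(n_per_deme)), list(range(n_per_deme, n))]

    def coalesce(active, tau, cap):
        while len(active) > 1:
            t = demo.sample_coalescence(tau, len(active), rng, cap=cap)
            if not math.isfinite(t) or t >= cap:
                return active, cap
            i, j = sorted(rng.choice(len(active), size=2, replace=False))
            a, b = active[i], active[j]
            parent.append(-1)
            times.append(t * generation_time)
            new = len(parent) - 1
            parent[a] = parent[b] = new
            active = [x for x in active if x not in (a, b)] + [new]
            tau = t
        return active, tau

    remaining = []
    for lineages in deme_lineages:
        left, _ = coalesce(lineages, 0.0, split_generations)
        remaining.extend(left)
    coalesce(remaining, split_generations, math.inf)
    tips = [f"a{i + 1}" for i in range(n_per_deme)] + \
           [f"b{i + 1}" for i in range(n_per_deme)]
    pops = ["demeA"] * n_per_deme + ["demeB"] * n_per_deme
    return Genealogy(parent, times, tips, pops)


@dataclass
class Scenario:
    name: str
    motifs: list
    sequences: list              # (sample_id, sequence)
    truth: SimTruth
    genealogy: Genealogy


def make_scenario(name: str, seed: int, n: int = 40, out_dir=None) -> Scenario:
    """Generate a named scenario; optionally write FASTA + population TSV +
    truth JSON + Newick under ``out_dir``."""
    if name == "two-deme":
        gen = simulate_two_deme(max(n // 2, 2), 10000.0, 1000.0, seed)
        # a slow clock keeps deep two-deme genealogies off saturation
        cfg = SimConfig(n=gen.n_tips, seed=seed, mutation_rate=0.05,
                        demography=DemographyModel.constant(1000.0))
        motifs, truth = sprinkle_mutations(gen, cfg)
    else:
        cfg = scenario_config(name, seed, n)
        gen = simulate_genealogy(cfg)
        motifs, truth = sprinkle_mutations(gen, cfg)
    ref = region_reference(cfg.region)
    seqs = [(m.sample_id, apply_motif(ref, m, cfg.region)) for m in motifs]
    if out_dir is not None:
        import pathlib

        from .io import write_fasta, write_motif_table, write_population_table
        import pandas as pd

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / f"{name}.fasta", seqs)
        write_population_table(
            out / f"{name}.populations.tsv",
            pd.DataFrame({"sample_id": [m.sample_id for m in motifs],
                          "population": [m.population for m in motifs]}))
        write_motif_table(out / f"{name}.motifs.tsv", motifs)
        (out / f"{name}.truth.json").write_text(truth.to_json())
        (out / f"{name}.nwk").write_text(gen.newick() + "\n")
    return Scenario(name, motifs, seqs, truth, gen)
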