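"""Seeded validation experiments used by the acceptance checks.

Each function runs a self-contained simulation experiment against the
package's own estimators and returns summary numbers; all randomness is
derived from the caller's seed.
"""

from __future__ import annotations

import numpy as np

from .dating import (ClockCalibration, RhoEstimate, classic_skyline,
                     rho_sigma, rho_to_age, skyline_epoch_ratio,
                     skyline_harmonic_mean)
from .diversity import pairwise_phist
from .network import build_mj, condense, ensure_node, mp_postprocess, \
    steiner_minimal_cost
from .reference import TRANSITION, reference_base
from .simulate import (make_scenario, scenario_config, simulate_genealogy,
                       sprinkle_mutations)
from .variants import TRANSITION_KIND, Motif, Variant


def random_binary_instance(rng, max_haplotypes=6, max_sites=8):
    """A random small haplotype table over shared transition sites."""
    n_sites = int(rng.integers(3, max_sites + 1))
    positions = rng.choice(range(100, 500), size=n_sites, replace=False)
    variants = [Variant(int(p), TRANSITION_KIND,
                        TRANSITION[reference_base(int(p))])
                for p in positions]
    n_haps = int(rng.integers(3, max_haplotypes + 1))
    haps = set()
    guard = 0
    while len(haps) < n_haps and guard < 500:
        mask = rng.integers(0, 2, size=n_sites).astype(bool)
        haps.add(frozenset(v for v, b in zip(variants, mask) if b))
        guard += 1
    return condense([Motif(h, f"s{i}") for i, h in enumerate(
        sorted(haps, key=lambda h: str(Motif(h))))])


def mj_oracle_agreement(seed: int, instances: int = 100) -> float:
    """Fraction (in %) of random small instances where the median-joining
    network's spanning cost equals the exhaustive Steiner minimum."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(instances):
        table = random_binary_instance(rng)
        net = mp_postprocess(build_mj(table, epsilon=0))
        if abs(net.spanning_cost() - steiner_minimal_cost(table)) < 1e-6:
            agree += 1
    return 100.0 * agree / instances


def rho_skyline_recovery(seed: int, replicates: int = 200):
    """Constant-size recovery experiment (Nef 5000, n 30).

    Returns (mean rho-based age, mean true TMRCA, skyline harmonic-mean
    estimate of Nef, true Nef).
    """
    ages, truths, skyline = [], [], []
    for rep in range(replicates):
        cfg = scenario_config("constant-validation", seed=seed * 10000 + rep)
        gen = simulate_genealogy(cfg)
        motifs, truth = sprinkle_mutations(gen, cfg)
        founder = cfg.founder_motif.variants
        table = condense(motifs)
        if len(table.haplotypes) >= 2:
            net = ensure_node(build_mj(table), founder)
            est = rho_sigma(net, founder)
        else:
            d = [len(m.variants ^ founder) for m in motifs]
            est = RhoEstimate("sim", float(np.mean(d)), 0.0, len(d))
        cal = ClockCalibration("sim", "rate-based", cfg.mutation_rate,
                               cfg.region.total_length)
        ages.append(rho_to_age(est, cal).age_years)
        truths.append(truth.tmrca_years)
        skyline.append(skyline_harmonic_mean(classic_skyline(gen)))
    nef_true = cfg.demography.epochs[0].n_start
    return (float(np.mean(ages)), float(np.mean(truths)),
            float(np.mean(skyline)), float(nef_true))


def growth_discrimination(seed: int, pairs: int = 100) -> float:
    """% of paired runs in which the expanding scenario shows the larger
    recent/ancient skyline ratio than the constant one."""
    wins = 0
    for rep in range(pairs):
        s = seed * 10000 + rep
        grow = simulate_genealogy(scenario_config("c1b13-like", seed=s))
        const = simulate_genealogy(scenario_config("b2l-like", seed=s))
        wins += (skyline_epoch_ratio(classic_skyline(grow))
                 > skyline_epoch_ratio(classic_skyline(const)))
    return 100.0 * wins / pairs


def two_deme_detection(seed: int, runs: int = 50,
                       permutations: int = 199) -> float:
    """% of two-deme simulations with permutation-significant PhiST."""
    hits = 0
    for rep in range(runs):
        sc = make_scenario("two-deme", seed=seed * 10000 + rep, n=20)
        groups: dict = {}
        for m in sc.motifs:
            groups.setdefault(m.population, []).append(m)
        r = pairwise_phist(groups, permutations=permutations, seed=rep)[0]
        hits += r.p_value < 0.05
    return 100.0 * hits / runs
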