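"""End-to-end study workflow: sequences -> motifs -> classification ->
per-haplogroup networks -> founder-age table -> diversity / PhiST / NJ.

Every product is written deterministically (fixed seed, canonical sort
orders), with a run manifest recording the configuration hash so a run can
be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from .align import align_and_call
from .clades import (ROOT, Assignment, ancestors, classify, collapse_to,
                     count_by_clade, default_registry)
from .dating import (RhoEstimate, default_clocks, rho_sigma, rho_to_age,
                     rescale_age)
from .diversity import (DistanceModel, pairwise_phist, phist_matrix, nj_tree,
                        summary_stats)
from .io import read_fasta, read_motif_table, read_population_table, write_motif_table
from .network import build_mj, condense, ensure_node, export_network, mp_postprocess
from .reference import DEFAULT_REGION, RegionSpec
from .variants import (GLOBAL_EXCLUSIONS, NETWORK_EXCLUSIONS, Motif,
                       exclude_sites, parse_motif)

log = logging.getLogger("mitocr")

FOCAL_CLADES = ("D1g", "B2l", "C1b13", "D4h3a5")


@dataclass
class RunConfig:
    fasta: str | None = None
    motif_table: str | None = None
    population_table: str | None = None
    region: RegionSpec = DEFAULT_REGION
    global_exclusions: tuple = GLOBAL_EXCLUSIONS
    network_exclusions: tuple = NETWORK_EXCLUSIONS
    clocks: tuple = ("howell", "kemp", "endicott", "santos", "soares_cr")
    grouping: str = "by-population"          # or "by-clade"
    focal_clades: tuple = FOCAL_CLADES
    epsilon: float = 0.0
    tolerance: int = 1
    out_dir: str = "mitocr_out"
    seed: int = 0

    def digest(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load_motifs(config: RunConfig):
    if config.motif_table:
        motifs = read_motif_table(config.motif_table)
    elif config.fasta:
        pops = {}
        if config.population_table:
            df = read_population_table(config.population_table)
            pops = dict(zip(df["sample_id"], df["population"]))
        motifs = [align_and_call(seq, region=config.region, sample_id=name,
                                 population=pops.get(name, "all"))
                  for name, seq in read_fasta(config.fasta)]
    else:
        raise ValueError("config needs a fasta or a motif table")
    return motifs


def _basal(registry, clade: str) -> str:
    chain = [c for c in ancestors(registry, clade) if c != ROOT]
    return chain[-1] if chain else clade


def nodal_haplotype(registry, clade: str, exclusions=()):
    """Accumulated defining control-region variants along the clade path."""
    variants = frozenset()
    cur = clade
    while cur is not None:
        variants |= registry[cur].defining
        cur = registry[cur].parent
    return frozenset(exclude_sites([Motif(variants)], exclusions)[0].variants) \
        if exclusions else variants


def clade_rho(motifs, clade: str, registry=None, epsilon: float = 0.0,
              exclusions=GLOBAL_EXCLUSIONS + NETWORK_EXCLUSIONS) -> RhoEstimate:
    """Build the clade's median-joining network and compute rho at its
    nodal haplotype."""
    registry = registry or default_registry()
    clean = exclude_sites(motifs, exclusions)
    nodal = nodal_haplotype(registry, clade, exclusions)
    table = condense(clean)
    if len(table.haplotypes) < 2:
        # degenerate clade sample: rho straight from the nodal distance
        d = [len(m.variants ^ nodal) for m in clean]
        rho = sum(d) / len(d)
        return RhoEstimate(clade, rho, (rho / len(d)) ** 0.5 if rho else 0.0,
                           len(d))
    net = ensure_node(mp_postprocess(build_mj(table, epsilon)), nodal)
    return rho_sigma(net, nodal, clade=clade)


def make_table1(rhos: dict, clocks=None, base_ages: dict | None = None,
                base_clock: str = "endicott") -> pd.DataFrame:
    """Founder-age table: one row per clade, one column per calibration.

    Per-mutation clocks are converted directly from rho; rate-based columns
    are filled by inverse-rate rescaling of ``base_ages`` (ages in years
    under ``base_clock``) when provided.
    """
    clocks = clocks or default_clocks()
    rows = {}
    for clade, est in rhos.items():
        if not isinstance(est, RhoEstimate):
            est = RhoEstimate(clade, float(est), 0.0, 1)
        row = {}
        for name, cal in clocks.items():
            if cal.mode == "per-mutation":
                row[name] = rho_to_age(est, cal).age_years
            elif base_ages is not None and clade in base_ages:
                base = clocks[base_clock]
                row[name] = rescale_age(base_ages[clade], base.rate, cal.rate)
        rows[clade] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "clade"
    return df


def run_full(config: RunConfig) -> dict:
    """Execute the full workflow; returns {product name: path}."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = default_registry()
    products = {}

    def stage(name):
        log.info("stage %s", name)

    stage("variants")
    motifs = _load_motifs(config)
    motifs = exclude_sites(motifs, config.global_exclusions)
    write_motif_table(out / "motifs.tsv", motifs)
    products["motifs"] = out / "motifs.tsv"
    log.info("loaded %d samples", len(motifs))

    stage("classify")
    assignments = [classify(m, registry, tolerance=config.tolerance)
                   for m in motifs]
    unclassified = [a for a in assignments if a.clade == "unclassified"]
    for a in unclassified:
        log.warning("sample %s not assignable to a registry clade", a.sample_id)
    pd.DataFrame([asdict(a) for a in assignments]).to_csv(
        out / "assignments.tsv", sep="\t", index=False)
    products["assignments"] = out / "assignments.tsv"

    stage("frequencies")
    count_by_clade(assignments).to_csv(out / "haplogroup_frequencies.tsv", sep="\t")
    products["frequencies"] = out / "haplogroup_frequencies.tsv"

    stage("networks")
    by_sample = {m.sample_id: m for m in motifs}
    net_motifs = exclude_sites(motifs, tuple(config.global_exclusions)
                               + tuple(config.network_exclusions))
    net_by_sample = {m.sample_id: m for m in net_motifs}
    groups: dict = {}
    for a in assignments:
        if a.clade == "unclassified":
            continue
        groups.setdefault(_basal(registry, a.clade), []).append(a.sample_id)
    for basal, sample_ids in sorted(groups.items()):
        table = condense([net_by_sample[s] for s in sample_ids])
        if len(table.haplotypes) < 2:
            log.info("network %s skipped (single haplotype)", basal)
            continue
        net = mp_postprocess(build_mj(table, config.epsilon))
        path = out / f"network_{basal}.graphml"
        export_network(net, path)
        products[f"network_{basal}"] = path

    stage("dating")
    clocks = {k: v for k, v in default_clocks(config.region.total_length).items()
              if k in config.clocks}
    rhos = {}
    for clade in config.focal_clades:
        members = [a.sample_id for a in assignments
                   if clade in ancestors(registry, a.clade)
                   ] if clade in registry else []
        if len(members) >= 3:
            rhos[clade] = clade_rho(
                [by_sample[s] for s in members], clade, registry,
                config.epsilon,
                tuple(config.global_exclusions) + tuple(config.network_exclusions))
    if rhos:
        table1 = make_table1(rhos, clocks)
        table1.to_csv(out / "founder_ages.tsv", sep="\t")
        products["founder_ages"] = out / "founder_ages.tsv"
        pd.DataFrame([asdict(r) for r in rhos.values()]).to_csv(
            out / "rho.tsv", sep="\t", index=False)
        products["rho"] = out / "rho.tsv"

    stage("diversity")
    if config.grouping == "by-clade":
        key = {a.sample_id: a.clade for a in assignments}
    else:
        key = {m.sample_id: m.population for m in motifs}
    div_groups: dict = {}
    for m in motifs:
        div_groups.setdefault(key[m.sample_id], []).append(m)
    summaries = [summary_stats(ms, g, config.region.total_length)
                 for g, ms in sorted(div_groups.items()) if len(ms) >= 2]
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out / "diversity.tsv", sep="\t", index=False)
    products["diversity"] = out / "diversity.tsv"

    stage("phist")
    usable = {g: ms for g, ms in div_groups.items() if len(ms) >= 2}
    if len(usable) >= 2:
        results = pairwise_phist(usable, permutations=0, seed=config.seed)
        mat = phist_matrix(results)
        mat.to_csv(out / "phist.tsv", sep="\t")
        products["phist"] = out / "phist.tsv"
        if len(mat) >= 3:
            (out / "phist_nj.nwk").write_text(
                nj_tree(mat.values, list(mat.index)) + "\n")
            products["nj"] = out / "phist_nj.nwk"

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_samples": len(motifs),
        "n_unclassified": len(unclassified),
        "products": {k: str(v) for k, v in products.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    products["manifest"] = out / "manifest.json"
    return products
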