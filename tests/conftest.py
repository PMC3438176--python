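import numpy as np
import pytest

from mitocr.reference import (DEFAULT_REGION, TRANSITION, reference_base,
                              region_reference)
from mitocr.variants import TRANSITION_KIND, TRANSVERSION_KIND, Motif, Variant


@pytest.fixture(scope="session")
def region():
    return DEFAULT_REGION


@pytest.fixture(scope="session")
def region_ref(region):
    return region_reference(region)


def random_substitution_motif(rng, region, k=5, sample_id=""):
    """A random indel-free motif of k substitutions inside the region."""
    positions = rng.choice([p for p in region.positions()], size=k, replace=False)
    variants = []
    for pos in sorted(int(p) for p in positions):
        base = reference_base(pos)
        if rng.random() < 0.8:
            variants.append(Variant(pos, TRANSITION_KIND, TRANSITION[base]))
        else:
            others = [b for b in "ACGT" if b not in (base, TRANSITION[base])]
            variants.append(Variant(pos, TRANSVERSION_KIND,
                                    others[int(rng.integers(2))]))
    return Motif(frozenset(variants), sample_id)


def synthetic_cohort(seed=0):
    """A 300-sample cohort assembled from the registry's nodal motifs.

    Synthetic stand-in for the study's sequence table (an external
    download): composition mirrors the reported haplogroup counts — 87 D1
    lineages of which 70 carry the 16187 transition — with private
    variation drawn away from every diagnostic or excluded site.
    """
    from mitocr.clades import default_registry
    from mitocr.pipeline import nodal_haplotype

    rng = np.random.default_rng(seed)
    registry = default_registry()
    reserved = {v.position for c in registry.values() for v in c.defining}
    reserved |= {152, 16519, 309, 315, 303}
    pool = [p for p in DEFAULT_REGION.positions() if p not in reserved]
    rng.shuffle(pool)
    pool = iter(pool)
    populations = ["Aymara", "Atacameno", "Pehuenche", "MapucheCL",
                   "Huilliche", "Tehuelche", "Kawesqar", "Yamana", "MapucheAR"]

    composition = [("D1g", 70), ("D1", 17), ("B2l", 57), ("B2-16188", 20),
                   ("B2-455+T", 16), ("B2", 10), ("C1b13", 43), ("C1b", 21),
                   ("C1", 3), ("D4h3a5", 20), ("A2", 23)]
    motifs = []
    i = 0
    for clade, count in composition:
        base = nodal_haplotype(registry, clade)
        for _ in range(count):
            k = int(rng.poisson(1.5))
            privates = set()
            for _ in range(k):
                pos = next(pool)
                base_ref = reference_base(pos)
                privates.add(Variant(pos, TRANSITION_KIND,
                                     TRANSITION[base_ref]))
            motifs.append(Motif(base | frozenset(privates), f"ind{i:03d}",
                                populations[i % len(populations)]))
            i += 1
    assert len(motifs) == 300
    return motifs


def random_haplotype_set(rng, n_haps, n_sites, lo=100, hi=400):
    """Distinct binary haplotypes over shared random transition sites."""
    positions = rng.choice(range(lo, hi), size=n_sites, replace=False)
    variants = [Variant(int(p), TRANSITION_KIND, TRANSITION[reference_base(int(p))])
                for p in positions]
    haps = set()
    guard = 0
    while len(haps) < n_haps and guard < 1000:
        mask = rng.integers(0, 2, size=n_sites).astype(bool)
        haps.add(frozenset(v for v, b in zip(variants, mask) if b))
        guard += 1
    return [Motif(h, f"s{i}") for i, h in enumerate(sorted(
        haps, key=lambda h: str(Motif(h))))]
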