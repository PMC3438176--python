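"""Sequence diversity statistics, TN93 distances, pairwise PhiST and
neighbour-joining dendrograms.

PhiST is the AMOVA analogue of FST computed from molecular distances
(the behaviour of the standard population-genetics software for sequence
data): the pairwise distance matrix supplies the squared deviations of the
among/within sums of squares, and PhiST = sigma^2_a / (sigma^2_a +
sigma^2_w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .variants import Motif

DEFAULT_GAMMA_ALPHA = 0.26


@dataclass(frozen=True)
class DistanceModel:
    model: str = "TN93"
    gamma_alpha: float | None = DEFAULT_GAMMA_ALPHA

    def __post_init__(self):
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma shape must be positive")


@dataclass(frozen=True)
class DiversitySummary:
    group: str
    n: int
    s: int                      # segregating sites
    hd: float
    hd_se: float
    pi: float
    pi_se: float
    k: float                    # mean pairwise differences


def _pairwise_diff(a: Motif, b: Motif) -> int:
    return len(a.variants ^ b.variants)


def summary_stats(motifs, group: str = "", region_length: int = 1018) -> DiversitySummary:
    """S, Hd (+/-SE, Nei 1987), K and pi (=K/L) for one group of motifs."""
    n = len(motifs)
    if n < 2:
        raise ValueError("need at least two samples")
    sites = set()
    for m in motifs:
        sites |= {v.site_key for v in m.variants}
    # a site is segregating only if not shared by every sample
    seg = 0
    for key in sites:
        carriers = sum(1 for m in motifs if key in {v.site_key for v in m.variants})
        if 0 < carriers < n:
            seg += 1

    counts: dict = {}
    for m in motifs:
        counts[m.variants] = counts.get(m.variants, 0) + 1
    freqs = np.array(list(counts.values())) / n
    sum_p2 = float((freqs ** 2).sum())
    hd = n * (1.0 - sum_p2) / (n - 1)
    # Nei (1987) eq. 8.12 sampling variance of haplotype diversity
    sum_p3 = float((freqs ** 3).sum())
    hd_var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum_p3 - sum_p2 ** 2) + sum_p2 - sum_p2 ** 2)
    k = float(np.mean([_pairwise_diff(a, b) for a, b in combinations(motifs, 2)]))
    pi = k / region_length
    # Tajima (1983) sampling variance of pi (no-recombination neutral model)
    pi_var = ((n + 1) / (3.0 * (n - 1)) * pi / region_length
              + 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1)) * pi ** 2)
    return DiversitySummary(group, n, seg, hd, math.sqrt(max(hd_var, 0.0)),
                            pi, math.sqrt(max(pi_var, 0.0)), k)


# ---------------------------------------------------------------------------
# TN93 (+ gamma) distances

_VALID = frozenset("ACGT")


def tn93_distance(seq1: str, seq2: str, model: DistanceModel = DistanceModel()) -> float:
    """Tamura-Nei (1993) distance, optionally gamma-corrected.

    Gap and ambiguity columns are dropped pairwise.  Degenerate base
    frequencies (a required class empty while changes are observed) fall
    back to the uncorrected p-distance with a warning.
    """
    import warnings

    pairs = [(a, b) for a, b in zip(seq1.upper(), seq2.upper())
             if a in _VALID and b in _VALID]
    if not pairs:
        raise ValueError("no comparable sites")
    L = len(pairs)
    if seq1 == seq2:
        return 0.0
    freq = {b: 0 for b in "ACGT"}
    p1 = p2 = q = 0
    for a, b in pairs:
        freq[a] += 1
        freq[b] += 1
        if a != b:
            ab = {a, b}
            if ab == {"A", "G"}:
                p1 += 1
            elif ab == {"C", "T"}:
                p2 += 1
            else:
                q += 1
    g = {b: freq[b] / (2 * L) for b in "ACGT"}
    gr, gy = g["A"] + g["G"], g["C"] + g["T"]
    P1, P2, Q = p1 / L, p2 / L, q / L
    if P1 + P2 + Q == 0:
        return 0.0
    k1 = 2 * g["A"] * g["G"] / gr if gr > 0 else 0.0
    k2 = 2 * g["C"] * g["T"] / gy if gy > 0 else 0.0
    k3 = 2 * (gr * gy - g["A"] * g["G"] * gy / gr - g["C"] * g["T"] * gr / gy) \
        if gr > 0 and gy > 0 else 0.0
    x1 = 1 - P1 / k1 - Q / (2 * gr) if k1 > 0 else 1.0
    x2 = 1 - P2 / k2 - Q / (2 * gy) if k2 > 0 else 1.0
    x3 = 1 - Q / (2 * gr * gy) if gr * gy > 0 else 1.0
    degenerate = ((k1 == 0 and P1 > 0) or (k2 == 0 and P2 > 0)
                  or (k3 == 0 and Q > 0) or min(x1, x2, x3) <= 0)
    if degenerate:
        warnings.warn("degenerate base frequencies: falling back to p-distance")
        return (p1 + p2 + q) / L

    if model.gamma_alpha is None:
        f = lambda x: -math.log(x)
    else:
        a = model.gamma_alpha
        f = lambda x: a * (x ** (-1.0 / a) - 1.0)
    return k1 * f(x1) + k2 * f(x2) + k3 * f(x3)


def p_distance(seq1: str, seq2: str) -> float:
    pairs = [(a, b) for a, b in zip(seq1.upper(), seq2.upper())
             if a in _VALID and b in _VALID]
    if not pairs:
        raise ValueError("no comparable sites")
    return sum(a != b for a, b in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# PhiST

@dataclass(frozen=True)
class FstResult:
    pop1: str
    pop2: str
    phi_st: float
    p_value: float | None = None


def _phist_from_matrix(D2: np.ndarray, sizes) -> float:
    """PhiST from a matrix of (squared) pairwise distances between all
    individuals, populations in contiguous blocks of the given sizes."""
    n = int(sum(sizes))
    p = len(sizes)
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    start = 0
    for s in sizes:
        block = D2[start:start + s, start:start + s]
        ss_within += block.sum() / (2.0 * s)
        start += s
    ss_among = ss_total - ss_within
    df_within = n - p
    sigma_w = ss_within / df_within if df_within > 0 else 0.0
    n_c = (n - sum(s * s for s in sizes) / n) / (p - 1)
    if abs(ss_among) <= 1e-12:      # exactly exchangeable groups
        sigma_a = 0.0
    else:
        sigma_a = (ss_among / (p - 1) - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return sigma_a / denom


def pairwise_phist(populations: dict, model: DistanceModel | None = None,
                   mode: str = "distance", permutations: int = 0,
                   seed: int = 0):
    """Pairwise PhiST between populations of motifs or sequences.

    ``populations`` maps name -> list of Motif (mode "distance" uses the
    count of pairwise differences) or name -> list of sequences (TN93 with
    ``model``).  ``mode="haplotype"`` scores any two distinct haplotypes as
    one difference (frequency-only FST).  Populations with fewer than two
    members are excluded with a warning.  A seeded permutation test is run
    when ``permutations`` > 0.
    """
    import warnings

    kept = {}
    for name, members in populations.items():
        if len(members) < 2:
            warnings.warn(f"population {name!r} has n<2: excluded")
        else:
            kept[name] = list(members)
    names = list(kept)
    if len(names) < 2:
        raise ValueError("need at least two populations with n>=2")

    def dist(a, b):
        if isinstance(a, Motif):
            if mode == "haplotype":
                return 0.0 if a.variants == b.variants else 1.0
            return float(_pairwise_diff(a, b))
        return tn93_distance(a, b, model or DistanceModel())

    rng = np.random.default_rng(seed)
    results = []
    for n1, n2 in combinations(names, 2):
        members = kept[n1] + kept[n2]
        sizes = [len(kept[n1]), len(kept[n2])]
        m = len(members)
        D2 = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                D2[i, j] = D2[j, i] = dist(members[i], members[j])
        obs = _phist_from_matrix(D2, sizes)
        pval = None
        if permutations > 0:
            hits = 1
            idx = np.arange(m)
            for _ in range(permutations):
                rng.shuffle(idx)
                perm = D2[np.ix_(idx, idx)]
                if _phist_from_matrix(perm, sizes) >= obs - 1e-12:
                    hits += 1
            pval = hits / (permutations + 1)
        results.append(FstResult(n1, n2, obs, pval))
    return results


def phist_matrix(results) -> "np.ndarray":
    import pandas as pd

    names = sorted({r.pop1 for r in results} | {r.pop2 for r in results})
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for r in results:
        mat.loc[r.pop1, r.pop2] = mat.loc[r.pop2, r.pop1] = r.phi_st
    return mat


# ---------------------------------------------------------------------------
# neighbour joining

def nj_tree(distance_matrix, labels) -> str:
    """Saitou-Nei neighbour joining -> Newick string.

    Negative branch lengths are clamped to zero with the excess moved to
    the adjacent branch; ties are broken by taxon input order.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.asarray(distance_matrix, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    tree = nj(DistanceMatrix(D, ids=list(labels)))
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            excess = -node.length
            node.length = 0.0
            for sib in node.siblings():
                if sib.length is not None:
                    sib.length += excess
    return str(tree).strip()
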