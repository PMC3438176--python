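# Methods

This note documents the models, estimators and design choices behind
`mitocr`, and what its validation experiments do and do not establish.

## Coordinates, notation and the packaged reference

All variants are 1-based rCRS-relative. The control region spans the
replication origin, so regions are explicit segment lists
(default (16032–16544), (51–555), 1018 bp total) and indices never wrap
circularly. Parsing accepts the standard dialect — bare position =
transition, `posALT` transversion, `pos+BASES` insertion, `posd`
deletion, `@` reversion, leading zeros — and formatting canonically
sorts by position, so motif strings round-trip.

The packaged reference is a **synthetic stand-in**, generated in code
(`mitocr.reference`). It fixes the true rCRS base at every position the
registry or notation relies on (these are implied by published
`REFposALT` tokens such as C16187T and A470G), the real 303–315 and
16184–16193 C-tract contexts, the bases immediately 3′ of the printed
indel sites (so canonical indel placement matches the printed notation),
and the published 8116F/8116R primer sequences spaced for a 275-bp
product containing position 8116 with an A allele whose transition
creates the SmaI site CCCGGG. Everything else is deterministic filler
with mtDNA-like composition, scrubbed of accidental primer or SmaI
matches. Consequences: coordinate arithmetic, alignment, notation,
classification, networks, dating and simulation behave exactly as on the
real reference; only base-level conclusions at undocumented positions
would be meaningless, and no analysis here depends on them.

## Variant calling

Samples are aligned to the region reference globally (match +1,
mismatch −1, gap open −5, gap extend −2). The scores are a package
choice — motif extraction, not alignment art, is the contract — and the
gap penalties are set high enough that substitution-only samples never
acquire spurious gaps, which is what makes the apply/call round trip
exact for indel-free motifs. Indels are normalised to the 3′-most
equivalent placement on the forward strand (the forensic-database
convention): deletions slide through homopolymer runs, insertions slide
through whole-unit repeats and homopolymers. IUPAC ambiguity codes are
treated as missing data (no call), not mismatches. Alignments with
identity below 70% are rejected as non-control-region input.

Sites 309+C/309+CC are excluded from all analyses, and 152/16519
additionally from network construction, as hypervariable/homoplastic;
exclusion lists are arguments everywhere.

## Classification

The registry is a tree of clade definitions; each node carries its own
control-region diagnostics and, flagged separately, coding-region
diagnostics (8116 for D1g1; 10202/10724/13020 for D1g2). Classification
walks the tree and returns the deepest admissible clade, where
admissible means (i) at least one of the clade's own diagnostics is
present — descent requires evidence — and (ii) at most `tolerance`
(default 1) of the diagnostics accumulated along the whole path are
absent, absorbing private back mutations such as @16301. Coding-only
clades are reachable only in `with-coding` mode, mirroring the fact that
D1g1/D1g2 were resolved by RFLP/sequencing rather than D-loop motifs.
Ties on (depth, score) are reported as ambiguous and broken
alphabetically rather than guessed. The A2/C1c/C1d/C1d1e entries are
provisional approximations from the general haplogroup literature (their
nodal motifs are not printed in the source networks) and no numeric
result here depends on them.

## Median-joining networks

Haplotypes are binary vectors over the segregating variants; distance is
the summed site weight of the symmetric difference (default weight 10,
down-weight 5 suggested for flagged homoplastic sites, 0 = excluded; the
numbers mirror the conventions of the standard network program, which
states the policy but not the values). The ε-relaxed minimum spanning
network connects u,v whenever d(u,v) ≤ minimax(u,v) + ε (ε default 0).

Median vectors are quasi-medians (coordinate-wise majority) of triplets.
Two regimes:

* **Exact (≤10 segregating variants and ≤8 distinct haplotypes).** The
  full quasi-median closure of the observed haplotypes is generated; for
  binary characters it provably contains the branch points of every
  minimum-cost tree spanning the observed haplotypes. Medians are kept
  exactly when forcing them as a terminal leaves the Steiner cost
  unchanged (Dreyfus–Wagner dynamic programming on the metric closure).
* **Heuristic (larger instances).** The classic iteration: candidate
  medians come from triplets connected in the current network, all
  candidates within ε of the minimal connection cost are added, and the
  loop repeats to a fixed point (bounded by a median cap); medians whose
  removal leaves the spanning cost unchanged are then discarded. Like
  the original algorithm this is a heuristic and can in principle miss a
  cheaper tree, which is exactly why the exact regime exists for the
  instances small enough to verify.

Maximum-parsimony post-processing deletes every edge and median lying on
no minimum-cost tree of the observed haplotypes within the network —
exactly, by edge contraction plus Steiner recomputation, for ≤14
observed haplotypes; larger networks fall back to union-of-minimum-
spanning-tree pruning (exact enumeration is exponential in terminals).
Observed haplotypes are never deleted. `steiner_minimal_cost` is an
independent exhaustive oracle (Dreyfus–Wagner over the entire weighted
hypercube, ≤12 variants) used to validate all of this.

## Rho dating

ρ is the count-weighted mean mutational distance from the clade's nodal
haplotype to each sampled individual, measured on a minimum-mutation
spanning tree of the network (reticulations are resolved toward paths
through higher-frequency nodes; the source workflow computed ρ "from the
networks" without stating a rule, so the tie-break is documented rather
than inherited). Each variant counts one mutation regardless of weight
or type. σ² = Σₑ (nₑ/n)² mₑ (Saillard), giving σ = 1/√n on a perfect
star. Individuals, not distinct haplotypes, carry the weights by
default (`per_individual=False` switches).

Clock registry: rate-based 0.45, 0.34, 0.302, 0.24 mutations/site/Myr
and the per-mutation control-region constant 9,058 yr/mutation (the
linear coefficient of the published control-region rho calculator,
recovered from its printed conversions). Ages are rounded half-up to
the year, matching printed tables; rate-based rescaling is exact inverse
proportionality. The time-dependent correction of the per-mutation
clock is out of scope; the constant is accurate in the 0–30 kyr range
used here.

## Classic skyline

For an ultrametric genealogy with coalescent intervals Iₖ (k lineages),
Nef,k = Iₖ(generations)·k(k−1)/2. Steps are reported oldest→youngest in
years BP with a 25-year generation. Two summaries: the time-weighted
harmonic mean (algebraically the TMRCA moment estimator
TMRCA/(2(1−1/n)), hence unbiased for constant Nef) and the
recent/ancient epoch ratio (harmonic means over the younger and older
halves of the coalescent events), used to discriminate growth from
constancy. This deterministic estimator replaces Bayesian skyline
machinery; it has no MCMC uncertainty but also no smoothing, so single
intervals are exponentially noisy — hence the aggregated summaries.

## Diversity and differentiation

Hd uses n(1−Σpᵢ²)/(n−1) with Nei's (1987) sampling variance; π = K/L
with Tajima's (1983) variance; S counts sites segregating within the
group. TN93 distances use empirical base frequencies, the two transition
classes and transversions, with the gamma form (α = 0.26 by default)
replacing −ln x by α(x^(−1/α)−1); degenerate frequency configurations
fall back to p-distance with a warning. Gap/ambiguous columns are
dropped pairwise, not listwise.

ΦST follows the AMOVA variance decomposition with the pairwise distance
matrix supplying squared deviations: σ²ₐ from among-population, σ²_w
from within-population sums of squares, ΦST = σ²ₐ/(σ²ₐ+σ²_w). When the
among-group sum of squares is exactly zero (exchangeable groups) the
among component is taken as zero, so identical populations score exactly
0; otherwise small negative estimates are reported as computed.
A frequency-only mode (any two distinct haplotypes at distance 1) is
provided since the original software choice is ambiguous. Permutation
tests shuffle individuals between the pair, seeded, with the
(hits+1)/(perms+1) estimator. Neighbour joining delegates to
scikit-bio's Saitou–Nei implementation; negative branches are clamped to
zero with the excess moved to the sibling branch.

## Simulator

Haploid coalescent with pair rate k(k−1)/(2·Nef(t)) per generation;
non-constant Nef is handled by closed-form intensity inversion per
epoch (constant and exponential pieces), so no discretisation error.
Genealogies are stored in years BP; generations enter only through the
25-year conversion at the boundary. Mutations are Poisson on branches
with gamma site rates (shape 0.26 by default), finite-sites toggling
(a second hit reverts), and a 0.95:0.05 transition:transversion bias.
Founder diagnostic sites are masked from mutation by default so that
classification truth is unambiguous (configurable off). Everything is
driven by an explicit seed; identical seeds give identical datasets.

Scenario presets encode the study narratives: `b2l-like` constant
Nef = 300 (a young clade's TMRCA ≈ 2·Nef generations ≈ 15 kyr),
`d1g-like` five-fold exponential growth from 9 kyr BP, `c1b13-like`
order-of-magnitude expansion from 5 kyr BP, all at 0.302
mutations/site/Myr, and `two-deme` (split 10,000 generations ago, no
migration, slower clock to stay off saturation) for ΦST power checks.
The `constant-validation` scenario (Nef 5,000, n 30, uniform site rates)
uses a 0.01 mutations/site/Myr clock: at the ~240-kyr TMRCA that Nef
implies, control-region rates would saturate a 1-kb region and no
estimator could be unbiased; the slow clock keeps expected root-to-tip
counts near 2.5 so the experiment tests the estimator, not saturation.

What the simulator does not emulate: heteroplasmy, sequencing error,
ancient-DNA damage, selection, migration after a split, and the
time-dependent rate correction. Passing recovery tests therefore show
estimator correctness under the model's assumptions, not robustness to
real-data artefacts.

## Numerical conventions

Ages round half-up to the year. MST/Steiner comparisons use a 1e-9
absolute tolerance on integer-weighted costs. Candidate-median ties
break toward the lexicographically smallest variant set; spanning-tree
ties toward higher-frequency endpoints, then node order — all orderings
canonical so outputs are byte-identical across runs. Empty motifs
classify as `unclassified` with score 0; populations with n < 2 are
excluded from diversity/ΦST with a warning rather than an error.

## Validation experiments (scripts/acceptance.py)

The acceptance script recomputes, from scratch at run time: the
founder-age table under all five calibrations (per-mutation conversions
from the network ρ values; rate columns by rescaling the 0.302-rate
ages); the 8116/SmaI amplicon length on the packaged reference; the
MJ-vs-Steiner agreement over 100 random ≤6-haplotype instances; the
constant-size recovery errors (mean ρ-based age vs mean true TMRCA over
200 replicates; skyline harmonic mean vs Nef); growth-vs-constant
discrimination over 100 paired runs; and two-deme ΦST detection over 50
runs. Problem sizes were chosen so the whole script runs in seconds on
one core while keeping Monte-Carlo error a few times smaller than the
tolerances being checked.
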