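"""Haplogroup definitions and motif-based classification.

The registry encodes the southern South American mtDNA clades as a tree of
named nodes, each carrying the control-region variants that define it
relative to its parent (plus, flagged separately, coding-region diagnostics
such as the 8116 transition that splits D1g1 from D1g2).  Classification
walks the tree and returns the deepest clade whose accumulated defining
variants are present in the motif, tolerating a configurable number of
missing defining sites to absorb private back mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .variants import Motif, Variant, parse_motif, parse_variant

_CODING_KEY = lambda v: (v.position, v.kind, v.insert_index, v.derived)


@dataclass(frozen=True)
class CladeDefinition:
    name: str
    parent: str | None
    defining: frozenset            # control-region Variants
    coding: frozenset = frozenset()  # coding-region Variants (separate assay)
    provisional: bool = False

    def __post_init__(self):
        if self.parent is not None and not (self.defining or self.coding):
            raise ValueError(f"non-root clade {self.name} has no defining variants")


@dataclass(frozen=True)
class Assignment:
    sample_id: str
    clade: str
    score: int = 0
    missing: int = 0
    private: int = 0
    ambiguous: bool = False
    population: str = ""


ROOT = "rCRS"

# nodal motifs as printed in the source networks; coding diagnostics are
# rCRS transitions given by bare positions
_REGISTRY_ROWS = [
    # name, parent, control-region defining, coding defining, provisional
    ("D1", ROOT, "16223-16325-16362-073-263-315+C-489", "", False),
    ("D1g", "D1", "16187", "", False),
    ("D1g1", "D1g", "", "8116", False),
    ("D1g2", "D1g", "", "10202-10724-13020", False),
    ("D4h3a", ROOT, "16241-16342", "", False),
    ("D4h3a5", "D4h3a", "16051", "", False),
    ("B2", ROOT, "16183C-16189-16217-073-263-315+C-499", "", False),
    ("B2l", "B2", "470", "", False),
    ("B2-16188", "B2", "16188", "", False),
    ("B2-455+T", "B2", "146-215-455+T", "", False),
    ("C1", ROOT, "16223-16298-16325-16327-073-249d-263-290d-291d-315+C-489-522d-523d",
     "", False),
    ("C1b", "C1", "493", "", False),
    ("C1b13", "C1b", "258", "", False),
    # nodal motifs below are not printed in the source data; provisional
    # approximations from the general haplogroup literature
    ("A2", ROOT, "073-235-263-315+C-16111-16223-16290-16319-16362", "", True),
    ("C1c", "C1", "", "9545", True),
    ("C1d", "C1", "16051", "", True),
    ("C1d1e", "C1d", "194", "", True),
]


def default_registry() -> dict[str, CladeDefinition]:
    """The packaged classification tree (clade name -> definition)."""
    reg = {ROOT: CladeDefinition(ROOT, None, frozenset())}
    for name, parent, cr, coding, prov in _REGISTRY_ROWS:
        reg[name] = CladeDefinition(
            name, parent,
            frozenset(parse_motif(cr).variants),
            frozenset(parse_variant(t) for t in coding.split("-") if t),
            prov)
    _check_acyclic(reg)
    return reg


def _check_acyclic(reg):
    for name in reg:
        seen, cur = set(), name
        while cur is not None:
            if cur in seen:
                raise ValueError(f"parent cycle at {cur}")
            seen.add(cur)
            cur = reg[cur].parent


def load_registry(path) -> dict[str, CladeDefinition]:
    """Read a registry from its plain-text serialisation (see save_registry)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    reg = {ROOT: CladeDefinition(ROOT, None, frozenset())}
    for r in df.itertuples(index=False):
        reg[r.clade] = CladeDefinition(
            r.clade, r.parent or ROOT,
            frozenset(parse_motif(r.motif).variants),
            frozenset(parse_motif(getattr(r, "coding", "")).variants),
            str(getattr(r, "provisional", "")).lower() in ("1", "true", "yes"))
    _check_acyclic(reg)
    return reg


def save_registry(path, registry):
    rows = [{"clade": c.name, "parent": c.parent, "motif": str(Motif(c.defining)),
             "coding": str(Motif(c.coding)), "provisional": c.provisional}
            for c in registry.values() if c.parent is not None]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _children(registry):
    kids = {name: [] for name in registry}
    for c in registry.values():
        if c.parent is not None:
            kids[c.parent].append(c.name)
    for v in kids.values():
        v.sort()
    return kids

def _matches(defining: Variant, motif_keys) -> bool:
    return (defining.position, defining.kind, defining.insert_index,
            defining.derived) in motif_keys


def classify(motif: Motif, registry=None, mode: str = "control-region-only",
             tolerance: int = 1) -> Assignment:
    """Assign a motif to the deepest admissible clade of the registry.

    A clade is admissible when at most ``tolerance`` of the defining
    variants accumulated along its root path are absent from the motif.
    In ``with-coding`` mode coding diagnostics count like control-region
    ones; otherwise they are ignored.  Ties on (depth, score) are reported
    with ``ambiguous=True`` and broken alphabetically.
    """
    if registry is None:
        registry = default_registry()
    use_coding = mode == "with-coding"
    motif_keys = {(v.position, v.kind, v.insert_index, v.derived)
                  for v in motif.variants if not v.reverted}
    kids = _children(registry)
    best = []  # (depth, score, name, path_defining)

    def walk(name, depth, path_defining):
        cdef = registry[name]
        if cdef.parent is not None and not use_coding and not cdef.defining:
            return          # coding-only clade: not assignable from motifs alone
        local = cdef.defining | (cdef.coding if use_coding else frozenset())
        if cdef.parent is not None and local and \
                not any(_matches(d, motif_keys) for d in local):
            return          # no evidence for this clade's own diagnostics
        path_defining = path_defining | cdef.defining
        if use_coding:
            path_defining = path_defining | cdef.coding
        missing = sum(0 if _matches(d, motif_keys) else 1 for d in path_defining)
        if missing > tolerance:
            return
        score = len(path_defining) - missing
        best.append((depth, score, name, path_defining, missing))
        for child in kids[name]:
            walk(child, depth + 1, path_defining)

    walk(ROOT, 0, frozenset())
    depth, score, name, path_defining, missing = max(
        best, key=lambda t: (t[0], t[1], [-ord(ch) for ch in t[2]]))
    ambiguous = sum(1 for t in best if t[0] == depth and t[1] == score) > 1
    if name == ROOT:
        return Assignment(motif.sample_id, "unclassified", 0, 0,
                          len(motif_keys), False, motif.population)
    explained = {(d.position, d.kind, d.insert_index, d.derived)
                 for d in path_defining}
    private = sum(1 for k in motif_keys if k not in explained)
    return Assignment(motif.sample_id, name, score, missing, private,
                      ambiguous, motif.population)


def ancestors(registry, name):
    chain = []
    cur = name
    while cur is not None:
        chain.append(cur)
        cur = registry[cur].parent
    return chain


def collapse_to(assignments, target: str, registry=None):
    """Relabel assignments to ``target`` when their clade descends from it."""
    if registry is None:
        registry = default_registry()
    out = []
    for a in assignments:
        if a.clade in registry and target in ancestors(registry, a.clade):
            out.append(Assignment(a.sample_id, target, a.score, a.missing,
                                  a.private, a.ambiguous, a.population))
        else:
            out.append(a)
    return out


def count_by_clade(assignments) -> pd.DataFrame:
    """Absolute counts and within-population percentages per clade.

    Percentages are rounded to the nearest integer for report tables.
    """
    df = pd.DataFrame({"population": [a.population for a in assignments],
                       "clade": [a.clade for a in assignments]})
    counts = pd.crosstab(df["population"], df["clade"])
    pct = (counts.div(counts.sum(axis=1), axis=0) * 100).round(0).astype(int)
    out = pd.concat({"count": counts, "percent": pct}, axis=1)
    return out
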