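"""Variant and motif handling in forensic mtDNA notation.

A *motif* is the list of differences of a control-region sequence from the
rCRS, written in the compact dialect used across the haplogroup literature:
``"073"`` (bare position = transition), ``"C16187T"``, ``"16183C"``
(transversion), ``"315+C"`` (insertion), ``"249d"`` (deletion) and the
``"@"`` prefix for a reversion of an earlier mutation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .reference import MT_LENGTH, TRANSITION, is_transition, reference_base

TRANSITION_KIND = "transition"
TRANSVERSION_KIND = "transversion"
INSERTION = "insertion"
DELETION = "deletion"

_KIND_ORDER = {TRANSITION_KIND: 0, TRANSVERSION_KIND: 1, DELETION: 2, INSERTION: 3}


class VariantParseError(ValueError):
    pass


@dataclass(frozen=True, order=False)
class Variant:
    """A single rCRS-relative difference."""

    position: int
    kind: str
    derived: str = ""
    insert_index: int = 1
    reverted: bool = False

    def __post_init__(self):
        if not 1 <= self.position <= MT_LENGTH:
            raise VariantParseError(
                f"position {self.position} outside 1..{MT_LENGTH}")
        if self.kind not in _KIND_ORDER:
            raise VariantParseError(f"unknown variant kind {self.kind!r}")
        if self.kind == DELETION and self.derived:
            raise VariantParseError("deletion carries no derived base")
        if self.kind in (TRANSITION_KIND, TRANSVERSION_KIND, INSERTION) and not self.derived:
            raise VariantParseError(f"{self.kind} requires a derived base")

    @property
    def site_key(self):
        return (self.position, self.kind, self.insert_index)

    def sort_key(self):
        return (self.position, _KIND_ORDER[self.kind], self.insert_index, self.derived)

    def __str__(self) -> str:
        return format_variant(self)


_TOKEN_RE = re.compile(
    r"^(?P<ref>[ACGT])?(?P<pos>\d+)"
    r"(?:(?P<ins>\+[ACGT]+)|(?P<del>[dD](?:el)?)|(?P<alt>[ACGT]))?$",
    re.IGNORECASE,
)


def parse_variant(token: str) -> Variant:
    """Parse one notation token into a canonical :class:`Variant`.

    Bare numeric tokens ("073") denote the transition at that position, with
    the derived base inferred from the reference.  A trailing base that is
    not the transition partner denotes a transversion ("16183C").
    """
    raw = token.strip()
    reverted = raw.startswith("@")
    body = raw[1:] if reverted else raw
    m = _TOKEN_RE.match(body)
    if not m or not body:
        raise VariantParseError(f"malformed variant token {token!r}")
    pos = int(m.group("pos"))
    if not 1 <= pos <= MT_LENGTH:
        raise VariantParseError(f"position {pos} outside 1..{MT_LENGTH} in {token!r}")
    if m.group("ins"):
        return Variant(pos, INSERTION, m.group("ins")[1:].upper(), reverted=reverted)
    if m.group("del"):
        return Variant(pos, DELETION, reverted=reverted)
    ref_base = reference_base(pos)
    stated_ref = m.group("ref")
    if stated_ref and stated_ref.upper() != ref_base:
        raise VariantParseError(
            f"{token!r}: stated reference base {stated_ref.upper()} "
            f"differs from rCRS {ref_base} at {pos}")
    alt = m.group("alt")
    if alt is None:
        return Variant(pos, TRANSITION_KIND, TRANSITION[ref_base], reverted=reverted)
    alt = alt.upper()
    if alt == ref_base:
        raise VariantParseError(f"{token!r}: derived base equals the reference")
    kind = TRANSITION_KIND if is_transition(ref_base, alt) else TRANSVERSION_KIND
    return Variant(pos, kind, alt, reverted=reverted)


def format_variant(v: Variant) -> str:
    pos = f"{v.position:03d}"
    at = "@" if v.reverted else ""
    if v.kind == INSERTION:
        return f"{at}{pos}+{v.derived}"
    if v.kind == DELETION:
        return f"{at}{pos}d"
    if v.kind == TRANSITION_KIND:
        return f"{at}{pos}"
    return f"{at}{pos}{v.derived}"


@dataclass(frozen=True)
class Motif:
    """A set of variants carried by one sample (or defining one haplotype)."""

    variants: frozenset = frozenset()
    sample_id: str = ""
    population: str = ""

    def __post_init__(self):
        vs = frozenset(self.variants)
        keys = [v.site_key for v in vs]
        if len(set(keys)) != len(keys):
            raise ValueError("motif holds two variants at one site")
        object.__setattr__(self, "variants", vs)

    def sorted_variants(self):
        return sorted(self.variants, key=Variant.sort_key)

    def __len__(self):
        return len(self.variants)

    def __iter__(self):
        return iter(self.sorted_variants())

    def __str__(self) -> str:
        return format_motif(self)


def parse_motif(text: str, sample_id: str = "", population: str = "") -> Motif:
    """Parse a hyphen- or whitespace-joined motif string ("" = rCRS)."""
    tokens = [t for t in re.split(r"[-\s,]+", text.strip()) if t]
    return Motif(frozenset(parse_variant(t) for t in tokens), sample_id, population)


def format_motif(motif: Motif) -> str:
    return "-".join(format_variant(v) for v in motif.sorted_variants())


def _excluded(v: Variant, rule) -> bool:
    if isinstance(rule, Variant):
        return v.site_key == rule.site_key and v.derived == rule.derived
    return v.position == int(rule)


#: removed from every analysis (unstable C-tract insertion calls)
GLOBAL_EXCLUSIONS = ("309+C", "309+CC")
#: additionally removed for network building (highly homoplastic sites)
NETWORK_EXCLUSIONS = (152, 16519)


def exclude_sites(motifs, excluded=GLOBAL_EXCLUSIONS):
    """Return motifs with variants at excluded sites removed.

    ``excluded`` mixes bare positions (drop every variant there) and tokens
    like ``"309+C"`` (drop that exact variant).  Inputs are not modified.
    """
    rules = [parse_variant(e) if isinstance(e, str) else int(e) for e in excluded]
    out = []
    for m in motifs:
        keep = frozenset(v for v in m.variants
                         if not any(_excluded(v, r) for r in rules))
        out.append(replace(m, variants=keep))
    return out
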