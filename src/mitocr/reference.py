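"""Reference sequence and coordinate handling for the mtDNA control region.

Variants throughout this package are expressed relative to the human
mitochondrial reference (rCRS numbering, 1-based, 16,569 bp).  The package
does not bundle the real genome: :func:`reference_sequence` returns a
**synthetic stand-in** built in code.  The stand-in honours the true rCRS
base at every diagnostic position used by the clade registry and the variant
notation (transitions such as A73G, C16187T, A470G, C258T imply the
reference base at those sites), the real homopolymer contexts around the
303–315 and 16184–16193 C-tracts, and the geometry of the 8116 SmaI RFLP
assay (primer binding sites spaced for a 275-bp product, position 8116
inside it with an A allele whose transition to G creates a CCCGGG site).
Every other position is deterministic filler with a human-mtDNA-like base
composition.  Coordinates, notation and all algorithms behave exactly as
they would on the real reference; only analyses that depend on bases at
positions outside the table below are not meaningful on the stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

MT_LENGTH = 16569

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def is_transition(ref: str, alt: str) -> bool:
    return TRANSITION.get(ref.upper()) == alt.upper()


#: True rCRS bases at the diagnostic positions referenced by the clade
#: registry, the notation examples and the homoplasy exclusion lists.  These
#: are fixed by the REFposALT tokens the source data use (e.g. C16187T,
#: A470G) and by standard control-region conventions.
KNOWN_BASES = {
    55: "T", 56: "A", 73: "A", 146: "T", 152: "T", 153: "A", 194: "C",
    215: "A", 235: "A", 249: "A", 250: "C", 258: "C", 263: "A",
    290: "A", 291: "A", 292: "T", 316: "G",
    455: "T", 456: "C", 470: "A", 489: "T", 493: "A", 499: "G",
    522: "C", 523: "A", 524: "G", 525: "T", 16194: "A",
    16051: "A", 16111: "C", 16187: "C", 16188: "C", 16209: "T", 16217: "T",
    16223: "C", 16241: "A", 16290: "C", 16298: "T", 16301: "C", 16319: "G",
    16325: "T", 16327: "C", 16342: "T", 16362: "T", 16519: "T",
}

#: Real homopolymer contexts (1-based inclusive spans -> sequence).
KNOWN_CONTEXTS = {
    (303, 315): "CCCCCCCTCCCCC",   # HVS-II C-tract, 310T interrupts
    (16183, 16193): "ACCCCCTCCCC",  # HVS-I C-tract, 16189T interrupts
}

# SmaI RFLP assay for the 8116 coding transition (synthetic geometry: the
# printed primers and the printed 275-bp product length position the forward
# primer 5' end at 7990 so that 8116 lies inside the amplicon).
PRIMER_8116F = "TGAAGCCCCCATTCGTATAA"
PRIMER_8116R = "GTGGGCTCTAGAGGGGGTAG"
SMAI_SITE = "CCCGGG"
_8116F_START = 7990          # 1-based 5' position of the forward primer
_AMPLICON_8116_LEN = 275
# context CCC[A]GG at 8113-8118: the derived G at 8116 creates the SmaI site
_8116_CONTEXT = ((8113, 8118), "CCCAGG")


@lru_cache(maxsize=1)
def reference_sequence() -> str:
    """Return the 16,569-bp synthetic stand-in reference (see module docs)."""
    rng = np.random.default_rng(16569)
    bases = np.array(list("ACGT"))
    # human mtDNA-like composition
    seq = list(rng.choice(bases, size=MT_LENGTH, p=[0.31, 0.31, 0.13, 0.25]))
    for (start, end), ctx in list(KNOWN_CONTEXTS.items()) + [_8116_CONTEXT]:
        seq[start - 1:end] = list(ctx)
    for pos, base in KNOWN_BASES.items():
        seq[pos - 1] = base
    f0 = _8116F_START - 1
    seq[f0:f0 + len(PRIMER_8116F)] = list(PRIMER_8116F)
    rtail = revcomp(PRIMER_8116R)
    r0 = f0 + _AMPLICON_8116_LEN - len(rtail)
    seq[r0:r0 + len(rtail)] = list(rtail)
    s = "".join(seq)
    # keep primer sites unique and the reference amplicon SmaI-free:
    # deterministically break any accidental extra primer match or CCCGGG word
    for word, keep_at in ((PRIMER_8116F, f0), (rtail, r0), (SMAI_SITE, None)):
        start = 0
        while True:
            i = s.find(word, start)
            if i < 0:
                break
            if i != keep_at:
                mid = i + len(word) // 2
                s = s[:mid] + TRANSITION[s[mid]] + s[mid + 1:]
            start = i + 1
    return s


def reference_base(position: int) -> str:
    """rCRS base at a 1-based position of the stand-in reference."""
    if not 1 <= position <= MT_LENGTH:
        raise ValueError(f"position {position} outside 1..{MT_LENGTH}")
    return reference_sequence()[position - 1]


@dataclass(frozen=True)
class RegionSpec:
    """One or more 1-based inclusive rCRS segments read as a single sequence.

    The control region spans the origin, so it is represented as an explicit
    segment list (HVS-I then HVS-II by default), never by circular
    arithmetic.
    """

    segments: tuple = ((16032, 16544), (51, 555))

    def __post_init__(self):
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in segs:
            if not (1 <= a <= b <= MT_LENGTH):
                raise ValueError(f"bad segment ({a},{b})")
        spans = sorted(segs)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("segments overlap")

    @property
    def total_length(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)

    def contains(self, position: int) -> bool:
        return any(a <= position <= b for a, b in self.segments)

    def positions(self):
        """rCRS coordinates in reading order."""
        for a, b in self.segments:
            yield from range(a, b + 1)

    def to_index(self, position: int) -> int:
        """0-based index within the concatenated region sequence."""
        offset = 0
        for a, b in self.segments:
            if a <= position <= b:
                return offset + (position - a)
            offset += b - a + 1
        raise ValueError(f"position {position} not in region {self.segments}")

    def to_position(self, index: int) -> int:
        offset = 0
        for a, b in self.segments:
            n = b - a + 1
            if index < offset + n:
                return a + (index - offset)
            offset += n
        raise ValueError(f"index {index} outside region of length {offset}")

    def slice_of(self, full_sequence: str) -> str:
        return "".join(full_sequence[a - 1:b] for a, b in self.segments)


DEFAULT_REGION = RegionSpec()


def region_reference(region: RegionSpec = DEFAULT_REGION) -> str:
    """Stand-in reference restricted to a region (concatenated segments)."""
    return region.slice_of(reference_sequence())
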