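"""In-silico PCR and restriction digestion (RFLP typing).

Implements the 8116/SmaI presence assay: amplify a short product around the
coding position with the published primer pair, digest with SmaI (CCCGGG,
blunt cut between positions 3 and 4 of the site) and compare fragment
patterns between alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reference import PRIMER_8116F, PRIMER_8116R, SMAI_SITE, revcomp


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        if min(len(self.forward), len(self.reverse)) < 15:
            raise ValueError("primers must be at least 15 nt")


PAIR_8116 = PrimerPair("8116", PRIMER_8116F, PRIMER_8116R)


class AmpliconError(ValueError):
    pass


def _find_all(template: str, word: str):
    hits, start = [], 0
    while True:
        i = template.find(word, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def predict_amplicon(template: str, primers: PrimerPair):
    """Return (product sequence, length) for a unique primer binding pair.

    The forward primer must match the sense strand exactly once and the
    reverse complement of the reverse primer exactly once downstream; the
    product runs 5' end to 5' end, both primers included.
    """
    template = template.upper()
    f = _find_all(template, primers.forward.upper())
    r = _find_all(template, revcomp(primers.reverse))
    if len(f) != 1 or len(r) != 1:
        raise AmpliconError(
            f"primer pair {primers.name}: {len(f)} forward and {len(r)} "
            "reverse binding sites (need exactly 1 each)")
    start = f[0]
    end = r[0] + len(primers.reverse)
    if end <= start + len(primers.forward):
        raise AmpliconError(f"primer pair {primers.name}: reverse site not downstream")
    product = template[start:end]
    return product, len(product)


def digest(product: str, recognition: str = SMAI_SITE, cut_offset: int = 3):
    """Fragment lengths after complete digestion (sorted 5'->3').

    ``cut_offset`` is the 0-based offset of the cut within the recognition
    word (SmaI cuts CCC/GGG).  No site yields the intact product.
    """
    product = product.upper()
    cuts = sorted(i + cut_offset for i in _find_all(product, recognition.upper()))
    bounds = [0] + [c for c in cuts if 0 < c < len(product)] + [len(product)]
    return [b - a for a, b in zip(bounds, bounds[1:])]
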