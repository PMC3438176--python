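"""Pairwise alignment of control-region sequences and variant calling.

The caller aligns a sample against the reference slice of a
:class:`~mitocr.reference.RegionSpec` (global alignment, match +1,
mismatch -1, gap open -5, gap extend -2), extracts column-wise differences
and maps them back to rCRS coordinates.  Indels are normalised to the
3'-most equivalent placement on the forward strand, the convention used by
forensic mtDNA databases, so that e.g. an extra C in the 303-315 tract is
always reported as an insertion after the last C of the run.
"""

from __future__ import annotations

from Bio import Align

from .reference import DEFAULT_REGION, RegionSpec, region_reference
from .variants import (DELETION, INSERTION, TRANSITION_KIND,
                       TRANSVERSION_KIND, Motif, Variant, is_transition)

_ACGT = frozenset("ACGT")


class NotControlRegionError(ValueError):
    """Raised when a sequence does not plausibly cover the target region."""


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = -1.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -2.0
    return al


def apply_motif(reference: str, motif: Motif, region: RegionSpec = DEFAULT_REGION) -> str:
    """Mutate the region slice ``reference`` according to ``motif``.

    Reverted ('@') variants describe a return to the reference state and
    leave the sequence unchanged.
    """
    if len(reference) != region.total_length:
        raise ValueError("reference length does not match region")
    subs, dels, ins = {}, set(), {}
    for v in motif.variants:
        if v.reverted:
            continue
        if not region.contains(v.position):
            raise ValueError(f"variant position {v.position} outside region")
        idx = region.to_index(v.position)
        if v.kind in (TRANSITION_KIND, TRANSVERSION_KIND):
            subs[idx] = v.derived
        elif v.kind == DELETION:
            dels.add(idx)
        else:
            ins.setdefault(idx, []).append(v)
    out = []
    for idx, base in enumerate(reference):
        if idx in dels:
            pass
        else:
            out.append(subs.get(idx, base))
        for v in sorted(ins.get(idx, []), key=lambda v: v.insert_index):
            out.append(v.derived)
    return "".join(out)


def _segment_end(region: RegionSpec, position: int) -> int:
    for a, b in region.segments:
        if a <= position <= b:
            return b
    raise ValueError(position)


def _shift_deletion(run, region: RegionSpec, ref: str):
    """3'-shift a run of deleted positions through a homopolymer."""
    positions = [p for p, _ in run]
    bases = [b for _, b in run]
    if len(set(bases)) != 1:
        return positions
    b = bases[0]
    end = positions[-1]
    seg_end = _segment_end(region, end)
    while end + 1 <= seg_end and ref[region.to_index(end + 1)] == b:
        end += 1
    return list(range(end - len(positions) + 1, end + 1))


def _shift_insertion(after: int, inserted: str, region: RegionSpec, ref: str) -> int:
    """3'-shift an insertion point through repeats of the inserted unit."""
    seg_end = _segment_end(region, after) if region.contains(after) else after
    # whole-unit repeats first, then single-base homopolymer creep
    k = len(inserted)
    while after + k <= seg_end and all(
            ref[region.to_index(after + i + 1)] == inserted[i] for i in range(k)):
        after += k
    while (len(set(inserted)) == 1 and after + 1 <= seg_end
           and ref[region.to_index(after + 1)] == inserted[0]):
        after += 1
    return after


def align_and_call(sample: str, reference: str | None = None,
                   region: RegionSpec = DEFAULT_REGION,
                   sample_id: str = "", population: str = "",
                   min_identity: float = 0.70) -> Motif:
    """Align ``sample`` to the region reference and call its motif.

    IUPAC ambiguity codes are treated as missing data (no call at the
    column).  Raises :class:`NotControlRegionError` below ``min_identity``.
    """
    if reference is None:
        reference = region_reference(region)
    sample = sample.strip().upper()
    if not sample or not reference:
        raise ValueError("empty sequence")
    aln = _aligner().align(reference, sample)[0]
    ref_row, smp_row = str(aln[0]), str(aln[1])

    both = sum(1 for r, s in zip(ref_row, smp_row) if r != "-" and s != "-")
    ident = sum(1 for r, s in zip(ref_row, smp_row) if r == s and r != "-")
    if both == 0 or ident / both < min_identity:
        raise NotControlRegionError(
            f"alignment identity {ident / max(both, 1):.2f} below {min_identity}: "
            "not a control-region sequence")

    variants = []
    del_run = []          # [(rcrs position, deleted base), ...]
    ins_after, ins_seq = None, []
    ref_idx = -1

    def flush_dels():
        nonlocal del_run
        if del_run:
            for p in _shift_deletion(del_run, region, reference):
                variants.append(Variant(p, DELETION))
            del_run = []

    def flush_ins():
        nonlocal ins_after, ins_seq
        if ins_seq:
            seq = "".join(ins_seq)
            if set(seq) <= _ACGT and ins_after is not None:
                pos = _shift_insertion(ins_after, seq, region, reference)
                variants.append(Variant(pos, INSERTION, seq))
        ins_after, ins_seq = None, []

    for r, s in zip(ref_row, smp_row):
        if r == "-":
            if ins_seq == [] :
                ins_after = region.to_position(ref_idx) if ref_idx >= 0 else None
            ins_seq.append(s)
            continue
        flush_ins()
        ref_idx += 1
        pos = region.to_position(ref_idx)
        if s == "-":
            del_run.append((pos, r))
            continue
        flush_dels()
        if s not in _ACGT:
            continue            # ambiguity: no call
        if s != r:
            kind = TRANSITION_KIND if is_transition(r, s) else TRANSVERSION_KIND
            variants.append(Variant(pos, kind, s))
    flush_ins()
    flush_dels()
    return Motif(frozenset(variants), sample_id, population)
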