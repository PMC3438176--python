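"""Readers/writers for the plain-text formats the pipeline exchanges."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import DEFAULT_REGION, RegionSpec
from .variants import Motif, format_motif, parse_motif


@dataclass
class SampleRecord:
    sample_id: str
    population: str = ""
    sequence: str = ""
    motif: Optional[Motif] = None
    region: RegionSpec = DEFAULT_REGION


def read_fasta(path):
    """FASTA -> list of (id, sequence) preserving input order."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records):
    """Write (id, sequence) pairs wrapped at 70 columns."""
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_population_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "population"} - set(df.columns)
    if missing:
        raise ValueError(f"population table lacks columns {sorted(missing)}")
    return df


def write_population_table(path, df: pd.DataFrame):
    df.to_csv(path, sep="\t", index=False)


def read_motif_table(path):
    """Motif TSV (sample_id, population, motif) -> list of Motif."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"sample_id", "population", "motif"} - set(df.columns)
    if missing:
        raise ValueError(f"motif table lacks columns {sorted(missing)}")
    return [parse_motif(r.motif, r.sample_id, r.population)
            for r in df.itertuples(index=False)]


def write_motif_table(path, motifs):
    pd.DataFrame(
        {"sample_id": [m.sample_id for m in motifs],
         "population": [m.population for m in motifs],
         "motif": [format_motif(m) for m in motifs]}
    ).to_csv(path, sep="\t", index=False)
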