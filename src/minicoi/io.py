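"""File IO: primer/tag fixtures, FASTA/FASTQ, sample schemes and lineages.

Sequence files go through Bio.SeqIO; tabular files through pandas.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import DegeneratePrimer

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]


def _data_path(name: str):
    return resources.files("minicoi.data").joinpath(name)


def load_primer_table(path=None) -> dict[str, DegeneratePrimer]:
    """Load a primer TSV (name, sequence, orientation, three_prime_block).

    With no path, loads the bundled table of the ten published COI primers.
    """
    src = _data_path("primers.tsv") if path is None else Path(path)
    with resources.as_file(src) if path is None else _nullcontext(src) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    out: dict[str, DegeneratePrimer] = {}
    for row in df.itertuples(index=False):
        out[row.name] = DegeneratePrimer(
            name=row.name,
            sequence=row.sequence,
            orientation=getattr(row, "orientation", "forward") or "forward",
            three_prime_block=str(getattr(row, "three_prime_block", "0")) in ("1", "True", "true"),
        )
    return out


def load_blocking_primers() -> dict[str, DegeneratePrimer]:
    """The three published predator-blocking primers (3'-blocked, 29 nt)."""
    with resources.as_file(_data_path("blocking_primers.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    return {
        row.name: DegeneratePrimer(row.name, row.sequence, row.orientation,
                                   three_prime_block=True)
        for row in df.itertuples(index=False)
    }


def load_tags() -> dict[str, str]:
    """The five published 6-bp sample tags T1..T5."""
    with resources.as_file(_data_path("tags.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    return dict(zip(df["name"], df["sequence"]))


class _nullcontext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def read_reads(path) -> list[tuple[str, str]]:
    """FASTA or FASTQ, by extension."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), fmt)]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: Iterable[tuple[str, str]], path, quality: int = 40) -> None:
    recs = []
    for i, s in records:
        r = SeqRecord(Seq(s), id=i, description="")
        r.letter_annotations["phred_quality"] = [quality] * len(s)
        recs.append(r)
    SeqIO.write(recs, str(path), "fastq")


def load_lineage_table(path) -> pd.DataFrame:
    """Lineage TSV: seq_id then the seven Linnaean ranks.

    Malformed rows (missing fields) are rejected with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["seq_id"] + RANKS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"lineage table missing columns: {missing}")
    bad = df[df[required].isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad.index]  # +2: header + 1-based
        raise ValueError(f"malformed lineage rows at lines {lines}")
    return df


def load_sample_scheme(path) -> pd.DataFrame:
    """Sample scheme TSV: sample_id, mid, tag (and optional predator_species)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "mid", "tag"):
        if col not in df.columns:
            raise ValueError(f"sample scheme missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_ids in scheme: {dup}")
    return df
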