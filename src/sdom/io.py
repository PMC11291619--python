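"""FASTQ and tabular I/O helpers shared across the pipeline stages.

Reads are carried in memory as lightweight ``(id, seq)`` records; FASTQ files
use Phred+33 with a fixed quality of ``I`` (Q40), since downstream stages use
only the base calls.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Read(NamedTuple):
    """A single sequencing read (identifier and base calls)."""

    id: str
    seq: str


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as FASTQ (fixed quality 'I'); returns the number written."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.seq)
        records.append(rec)
    return SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
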