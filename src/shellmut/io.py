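"""Small FASTA/TSV I/O helpers shared by the CLI and pipeline."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as a list of (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
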