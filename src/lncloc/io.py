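"""Plain-text readers and writers for the pipeline's tabular and sequence formats.

All tables are tab-separated. Count matrices are transcripts x samples with the
transcript ID in the first column; pileups are one row per covered transcript
position with 0-based coordinates.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PILEUP_COLUMNS = ["transcript_id", "pos0", "ref_base", "A", "C", "G", "T"]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a transcripts x samples count matrix (TSV, first column = transcript ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="transcript_id")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design table (sample_id, condition, fraction, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str, "fraction": str})
    required = {"sample_id", "condition", "fraction", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_lengths(path: str | Path) -> pd.Series:
    """Read per-transcript lengths (TSV: transcript_id, length_bp)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(int)


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label="transcript_id")


def sequences_to_fasta(sequences: Mapping[str, str], path: str | Path | None = None) -> str:
    """Write sequences as FASTA wrapped at 60 columns; return the text."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    buf = _io.StringIO()
    SeqIO.write(records, buf, "fasta")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def fasta_to_sequences(source: str | Path) -> dict[str, str]:
    """Read FASTA (path or literal text) into an ordered {id: sequence} dict."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        handle = open(source)
    else:
        handle = _io.StringIO(str(source))
    with handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup missing columns: {sorted(missing)}")
    return df


def write_pileup(pileup: pd.DataFrame, path: str | Path) -> None:
    pileup[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)
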