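"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; interval and tabular data are TSV via
pandas. Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name"]


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write 0-based half-open intervals (chrom, start, end, name)."""
    intervals[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> None:
    """Write 4-line FASTQ records given (read_id, sequence, quality) tuples."""
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(os.fspath(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_params_yaml(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        params = yaml.safe_load(fh)
    if not isinstance(params, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    return params


def write_params_yaml(params: Mapping, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(params), fh, sort_keys=False)
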