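"""Plain-text readers/writers for the pipeline's intermediates."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COUNT_COLUMNS = ["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: count table missing columns {sorted(missing)}")
    return df


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    out["called"] = out["called"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["called"] = df["called"].astype(bool)
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
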