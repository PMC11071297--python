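"""Small format helpers: FASTA, count tables, GMT gene sets, BED/TSV output."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO


def read_fasta(path: str | Path) -> dict[str, str]:
    """Genome as a chrom -> uppercase sequence dict (toy-genome scale)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_counts(path: str | Path) -> pd.Series:
    """Two-column gene_id / count TSV as an integer Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"expected two columns (gene_id, count) in {path}")
    return df.set_index(df.columns[0])[df.columns[1]].astype(int)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Wide count table: gene_id index, one column per sample."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
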