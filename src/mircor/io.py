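"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts and design travel as TSV, gene sets as GMT, per-base coverage as
bedGraph, sequences as FASTA. Everything round-trips losslessly at the
scales this package targets (tens of thousands of transcripts, nine
samples).
"""

from __future__ import annotations

import textwrap
from pathlib import Path

import pandas as pd

CONDITIONS = ("WT", "KD", "OE")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a transcript x sample count matrix (first column = transcript ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript IDs in {path}: {dups[:5]}")
    return df.astype(int)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="transcript_id")


def read_design_tsv(path: str | Path) -> pd.Series:
    """Read a two-column sample/condition table into a sample -> condition map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "condition"],
                     dtype=str, comment="#")
    bad = sorted(set(df["condition"]) - set(CONDITIONS))
    if bad:
        raise ValueError(f"unknown conditions in {path}: {bad}; expected {CONDITIONS}")
    return pd.Series(df["condition"].values, index=df["sample_id"].values, name="condition")


def write_design_tsv(design: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": design.index, "condition": design.values}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_id_list(path: str | Path) -> list[str]:
    """One ID per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_id_list(ids, path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT: name <tab> description <tab> member genes."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need >=3 fields): {line[:80]!r}")
        name, desc, members = fields[0], fields[1], fields[2:]
        if name in sets:
            raise ValueError(f"duplicate gene-set name in {path}: {name}")
        sets[name] = (desc, frozenset(m for m in members if m))
    return sets


def write_gmt(sets: dict[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """bedGraph (0-based half-open intervals) -> DataFrame of contig/start/end/value."""
    return pd.read_csv(
        path, sep="\t", header=None, comment="t",  # skips optional 'track' line
        names=["contig", "start", "end", "value"],
        dtype={"contig": str, "start": int, "end": int, "value": float},
    )


def write_bedgraph(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals.to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seq, 70) + "\n")
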