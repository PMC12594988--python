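"""Plain-text genomics I/O: FASTA and narrowPeak (BED6+4).

Generators in this package produce genomes as in-memory ``{chrom: sequence}``
dicts; these helpers move them to and from disk.
"""

from __future__ import annotations

import pandas as pd

NARROWPEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signal",
    "pvalue",
    "qvalue",
    "summit_offset",
]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None and line:
                seqs[name].append(line.upper())
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_narrowpeak(path) -> pd.DataFrame:
    """Read a narrowPeak file (macs2 convention, 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=NARROWPEAK_COLUMNS, comment="#"
    )
    return df


def write_narrowpeak(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in NARROWPEAK_COLUMNS:
        if col not in out.columns:
            out[col] = {"name": ".", "strand": "."}.get(col, -1)
    out[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read the first three BED columns (chrom, start, end)."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        comment="#",
    )


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)
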