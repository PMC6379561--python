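"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open everywhere (BED native); GFF3 input is
converted on read.  Writers emit a provenance comment line (``#seed= ...``)
which every reader skips.
"""

from __future__ import annotations

import io as _io
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

BED_COLUMNS = ["chrom", "start", "end", "name"]


def _provenance(seed) -> str:
    return f"#seed={seed} version={__version__}"


# -- FASTA ------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- chromosome sizes -------------------------------------------------------

def write_chrom_sizes(chrom_sizes: pd.DataFrame, path) -> None:
    chrom_sizes.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return df.astype({"chrom": str, "length": int})


# -- BED --------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(_provenance(seed) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str},
    )
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# -- generic TSV ------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, seed=None, index: bool = False) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(_provenance(seed) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def frame_to_tsv_text(df: pd.DataFrame) -> str:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
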