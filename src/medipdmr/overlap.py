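"""Interval and id-set overlap analysis, gene association, category tallies.

DMR-to-gene association uses the gene body as anchor and counts a gene as
associated when the interval gap is at most 10 kb (inclusive), which admits
flanking regulatory regions such as the promoter; strand is ignored.
Interval Venn counts are reported from both sides because an element of one
set may overlap several of the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


@dataclass
class VennResult:
    """Exact id-set overlap; A_only + common == |A| and likewise for B."""

    a_size: int
    b_size: int
    common: int
    a_only: int
    b_only: int


@dataclass
class IntervalVennResult:
    """Interval overlap counted from each side (>= 1 bp overlap).

    ``a_common`` is the number of A intervals overlapping at least one B
    interval; because one interval may overlap several on the other side the
    two common counts can differ, so both are kept.
    """

    a_size: int
    b_size: int
    a_common: int
    b_common: int

    @property
    def a_only(self) -> int:
        return self.a_size - self.a_common

    @property
    def b_only(self) -> int:
        return self.b_size - self.b_common

    @property
    def common_mean(self) -> float:
        return (self.a_common + self.b_common) / 2.0


def _interval_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Drop rows without a usable interval (unknown location), logging how
    many were excluded."""
    ok = df["chrom"].notna() & df["start"].notna() & df["end"].notna()
    if (~ok).any():
        logger.info("excluding %d features with unknown location from interval overlap",
                    int((~ok).sum()))
    out = df.loc[ok].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def associate_genes(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    max_dist_bp: int = 10_000,
    id_column: str = "dmr_id",
) -> pd.Series:
    """Genes within ``max_dist_bp`` of each DMR (gap <= distance, inclusive).

    Returns a Series mapping the DMR id to a sorted list of gene ids;
    DMRs on chromosomes absent from the gene annotation get empty lists.
    """
    result: dict[str, list[str]] = {d: [] for d in dmrs[id_column]}
    gene_by_chrom = {c: g for c, g in genes.groupby("chrom", sort=False)}
    unknown = 0
    for chrom, grp in dmrs.groupby("chrom", sort=False):
        g = gene_by_chrom.get(chrom)
        if g is None:
            unknown += len(grp)
            continue
        gs = g["start"].to_numpy(np.int64)
        ge = g["end"].to_numpy(np.int64)
        gid = g["gene_id"].to_numpy()
        for _, r in grp.iterrows():
            hit = (gs <= r["end"] + max_dist_bp) & (ge >= r["start"] - max_dist_bp)
            result[r[id_column]] = sorted(gid[hit].tolist())
    if unknown:
        logger.warning("%d DMRs on chromosomes absent from the gene annotation", unknown)
    return pd.Series(result)


def venn_intervals(set_a: pd.DataFrame, set_b: pd.DataFrame) -> IntervalVennResult:
    """Per-side interval overlap counts (>= 1 bp, half-open arithmetic)."""
    a = _interval_frame(set_a)
    b = _interval_frame(set_b)

    def side(x: pd.DataFrame, y: pd.DataFrame) -> int:
        total = 0
        y_by_chrom = {c: g for c, g in y.groupby("chrom", sort=False)}
        for chrom, grp in x.groupby("chrom", sort=False):
            g = y_by_chrom.get(chrom)
            if g is None:
                continue
            ys = g["start"].to_numpy(np.int64)
            ye = g["end"].to_numpy(np.int64)
            xs = grp["start"].to_numpy(np.int64)[:, None]
            xe = grp["end"].to_numpy(np.int64)[:, None]
            total += int(((xs < ye[None, :]) & (ys[None, :] < xe)).any(axis=1).sum())
        return total

    return IntervalVennResult(
        a_size=len(a), b_size=len(b), a_common=side(a, b), b_common=side(b, a)
    )


def venn_ids(list_a, list_b) -> VennResult:
    """Exact set intersection/differences; duplicates dropped with a warning."""
    a_list, b_list = list(list_a), list(list_b)
    a, b = set(a_list), set(b_list)
    if len(a) < len(a_list) or len(b) < len(b_list):
        logger.warning("duplicate ids removed before Venn computation")
    common = len(a & b)
    return VennResult(
        a_size=len(a), b_size=len(b), common=common,
        a_only=len(a) - common, b_only=len(b) - common,
    )


def map_counts(gene_list, mapping: pd.DataFrame) -> pd.DataFrame:
    """Distinct-gene counts per label from a gene -> label map.

    ``mapping`` must have columns gene_id and label (multi-label allowed: a
    gene counts once in each of its labels).  Genes absent from the map are
    tallied under ``unknown``.  Malformed (null) rows raise with their row
    number.
    """
    if not {"gene_id", "label"} <= set(mapping.columns):
        raise ValueError("mapping must have columns 'gene_id' and 'label'")
    bad = mapping["gene_id"].isna() | mapping["label"].isna()
    if bad.any():
        raise ValueError(f"malformed mapping row at line {int(np.flatnonzero(bad)[0]) + 2}")
    genes = set(gene_list)
    sub = mapping[mapping["gene_id"].isin(genes)].drop_duplicates()
    counts = sub.groupby("label")["gene_id"].nunique().sort_index()
    mapped = set(sub["gene_id"])
    out = counts.reset_index().rename(columns={"gene_id": "count"})
    out = pd.concat(
        [out, pd.DataFrame([{"label": "unknown", "count": len(genes - mapped)}])],
        ignore_index=True,
    )
    return out


# ---------------------------------------------------------------------------
# gene model input
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> pd.DataFrame:
    """Gene models from BED (chrom start end name [score strand])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    cols = ["chrom", "start", "end", "gene_id", "score", "strand"][: df.shape[1]]
    df.columns = cols
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"] if "gene_id" in df else df.index.astype(str),
            "symbol": df["gene_id"] if "gene_id" in df else df.index.astype(str),
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "strand": df["strand"] if "strand" in df else ".",
        }
    )
    _validate_genes(out)
    return out


def read_gene_gff3(path) -> pd.DataFrame:
    """Gene models from GFF3 (type == gene), converted to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        symbol = feat.attributes.get("Name", [gid])[0]
        rows.append(
            {
                "gene_id": gid,
                "symbol": symbol,
                "chrom": feat.seqid,
                "start": feat.start - 1,  # GFF3 is 1-based inclusive
                "end": feat.end,
                "strand": feat.strand or ".",
            }
        )
    out = pd.DataFrame(rows, columns=GENE_COLUMNS)
    _validate_genes(out)
    return out


def _validate_genes(genes: pd.DataFrame) -> None:
    if (genes["start"] >= genes["end"]).any():
        raise ValueError("gene with start >= end")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id: {dup}")
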