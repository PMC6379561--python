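"""Genome tiling, CpG counting and the window x sample fragment count matrix.

The genome is broken into fixed-width tiles (100 bp by default).  Each mapped
MeDIP fragment is assigned to exactly one window by its midpoint under
half-open arithmetic (a midpoint on a boundary belongs to the right-hand
window), which makes counting reversible: column sums equal the number of
in-range fragments per sample.  An overlap mode (each touched window counts
the fragment once) is available for comparison but does not conserve totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


def tile_genome(chrom_sizes: pd.DataFrame, width_bp: int = 100) -> pd.DataFrame:
    """Tile chromosomes into consecutive windows of ``width_bp``.

    The terminal remainder (if the length is not a multiple of the width) is
    kept as a truncated window so the tiling partitions the chromosome.

    Returns a frame with columns chrom, start, end, index (ordinal within
    chromosome).
    """
    if width_bp < 1:
        raise ValueError("window width must be >= 1")
    if chrom_sizes["chrom"].duplicated().any():
        dupes = chrom_sizes.loc[chrom_sizes["chrom"].duplicated(), "chrom"].tolist()
        raise ValueError(f"duplicate chromosome names: {dupes}")
    frames = []
    for chrom, length in zip(chrom_sizes["chrom"], chrom_sizes["length"]):
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        starts = np.arange(0, length, width_bp, dtype=np.int64)
        ends = np.minimum(starts + width_bp, length)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "index": np.arange(len(starts), dtype=np.int64),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def count_cpg(sequence: str) -> int:
    """Number of CpG dinucleotides ('CG' occurrences) in ``sequence``.

    Case-insensitive; N is allowed but never participates in a CpG.  Any other
    character raises.
    """
    seq = sequence.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid sequence character: {sorted(bad)[0]!r}")
    return seq.count("CG")


def window_cpg_counts(windows: pd.DataFrame, genome: Mapping[str, str]) -> np.ndarray:
    """Per-window CpG counts from chromosome sequences.

    A CpG straddling a window boundary is credited to the window holding its
    C (consistent with half-open tiling).
    """
    out = np.zeros(len(windows), dtype=np.int64)
    for chrom, grp in windows.groupby("chrom", sort=False):
        seq = genome[chrom].upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid sequence character: {sorted(bad)[0]!r}")
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        # is_cg[i] == True iff a CpG has its C at position i (i in [0, L-1))
        is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        cum = np.concatenate([[0], np.cumsum(is_cg)])
        lo = np.minimum(grp["start"].to_numpy(), len(is_cg))
        hi = np.minimum(grp["end"].to_numpy(), len(is_cg))
        out[grp.index.to_numpy()] = cum[hi] - cum[lo]
    return out


@dataclass
class WindowCountMatrix:
    """Ordered windows plus a window x sample matrix of fragment counts."""

    windows: pd.DataFrame
    counts: pd.DataFrame  # rows align with windows rows; columns are sample ids
    groups: pd.Series  # sample id -> 'control' | 'exposure'
    n_skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.windows):
            raise ValueError("counts and windows row counts differ")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if len(set(self.groups.loc[list(self.counts.columns)])) < 1:
            raise ValueError("need at least one group")

    def feature_ids(self) -> pd.Index:
        w = self.windows
        return pd.Index(
            w["chrom"].astype(str) + ":" + w["start"].astype(str) + "-" + w["end"].astype(str)
        )


def count_fragments(
    fragments_by_sample: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    mode: str = "midpoint",
) -> WindowCountMatrix:
    """Assign BED fragments to windows and build the count matrix.

    ``fragments_by_sample`` maps sample id to a BED-like frame (chrom, start,
    end[, name]).  Fragments on chromosomes absent from ``windows`` are
    skipped with a logged count.  In ``midpoint`` mode each fragment goes to
    the single window containing ``(start + end) // 2``; in ``overlap`` mode
    every window the fragment touches is incremented.
    """
    if mode not in ("midpoint", "overlap"):
        raise ValueError("mode must be 'midpoint' or 'overlap'")
    width = int((windows["end"] - windows["start"]).max())
    offsets: dict[str, int] = {}
    n_win: dict[str, int] = {}
    chrom_len: dict[str, int] = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        offsets[chrom] = int(grp.index.min())
        n_win[chrom] = len(grp)
        chrom_len[chrom] = int(grp["end"].max())

    counts = {}
    skipped = {}
    for sample, bed in fragments_by_sample.items():
        col = np.zeros(len(windows), dtype=np.int64)
        n_skip = 0
        if len(bed):
            if (bed["start"] >= bed["end"]).any():
                raise ValueError(f"malformed fragment (start >= end) in sample {sample}")
            for chrom, grp in bed.groupby("chrom", sort=False):
                if chrom not in offsets:
                    n_skip += len(grp)
                    continue
                starts = grp["start"].to_numpy(np.int64)
                ends = grp["end"].to_numpy(np.int64)
                if mode == "midpoint":
                    mid = (starts + ends) // 2
                    in_range = (mid >= 0) & (mid < chrom_len[chrom])
                    n_skip += int((~in_range).sum())
                    idx = offsets[chrom] + mid[in_range] // width
                    col += np.bincount(idx, minlength=len(windows))
                else:
                    first = np.clip(starts // width, 0, n_win[chrom] - 1)
                    last = np.clip((ends - 1) // width, 0, n_win[chrom] - 1)
                    span = int((last - first).max()) + 1 if len(grp) else 0
                    for k in range(span):
                        sel = first + k <= last
                        idx = offsets[chrom] + first[sel] + k
                        col += np.bincount(idx, minlength=len(windows))
        if n_skip:
            logger.warning("sample %s: skipped %d fragments on unknown/out-of-range positions",
                           sample, n_skip)
            skipped[sample] = n_skip
        counts[sample] = col
    counts_df = pd.DataFrame(counts)
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    return WindowCountMatrix(windows=windows.reset_index(drop=True),
                             counts=counts_df, groups=groups, n_skipped=skipped)
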