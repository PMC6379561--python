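"""DMR construction from per-window test results.

A window with p below the seed threshold starts a DMR; the DMR's edges are
then extended until no window with p below the extension threshold (0.1)
remains within the extension distance (1,000 bp) of the DMR span, and DMRs
whose extensions meet are merged.  Because the span's edges are always
window edges, that fixed point equals single-linkage clustering of the
sub-threshold windows at gap <= extension distance: a cluster containing at
least one seed window becomes one DMR spanning all its members.

A DMR is "multiple-window" when at least two of its significant (seed-level)
windows are immediately adjacent tiles.  Direction (increase/decrease in the
exposure group) is read off the log2 fold change of the most significant
window.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

DMR_COLUMNS = [
    "dmr_id", "chrom", "start", "end", "n_windows_total", "n_windows_significant",
    "is_multiple_window", "min_p", "direction", "length_bp", "cpg_density_per_100bp",
]


def _check_sorted(window_results: pd.DataFrame) -> None:
    chroms = window_results["chrom"].to_numpy()
    # chromosomes must be grouped and starts increasing within each
    seen = set()
    prev = None
    for c in chroms:
        if c != prev:
            if c in seen:
                raise ValueError("window results are not sorted by (chrom, start)")
            seen.add(c)
            prev = c
    for _, grp in window_results.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        if np.any(np.diff(starts) <= 0):
            raise ValueError("window results are not sorted by (chrom, start)")


def classify_multiple_window(
    dmr: pd.Series | dict,
    window_results: pd.DataFrame,
    seed_p: float,
    mode: str = "adjacent",
) -> tuple[bool, int]:
    """(is_multiple_window, significant-window count) for one DMR.

    ``adjacent`` (default): true iff >= 2 seed-level windows inside the DMR
    are immediate neighbours (share a boundary).  ``any_two``: true iff the
    DMR holds >= 2 seed-level windows anywhere.
    """
    if mode not in ("adjacent", "any_two"):
        raise ValueError("mode must be 'adjacent' or 'any_two'")
    w = window_results
    inside = w[
        (w["chrom"] == dmr["chrom"])
        & (w["start"] >= dmr["start"])
        & (w["end"] <= dmr["end"])
        & (w["p_value"] < seed_p)
    ].sort_values("start")
    n_sig = len(inside)
    if n_sig < 2:
        return False, n_sig
    if mode == "any_two":
        return True, n_sig
    starts = inside["start"].to_numpy()
    ends = inside["end"].to_numpy()
    return bool(np.any(starts[1:] == ends[:-1])), n_sig


def call_dmrs(
    window_results: pd.DataFrame,
    seed_p: float = 1e-6,
    extend_p: float = 0.1,
    extend_dist_bp: int = 1000,
    multiple_window_mode: str = "adjacent",
) -> pd.DataFrame:
    """Call DMRs by seed thresholding plus edge extension.

    ``window_results`` must be sorted by (chrom, start) and carry chrom,
    start, end, p_value, log2fc and (optionally) cpg_count.  Output DMRs are
    sorted and non-overlapping; every seed window lies in exactly one DMR.
    """
    for thr in (seed_p, extend_p):
        if not 0 < thr < 1:
            raise ValueError("thresholds must lie in (0, 1)")
    if window_results.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    _check_sorted(window_results)
    has_cpg = "cpg_count" in window_results.columns

    rows = []
    for chrom, grp in window_results.groupby("chrom", sort=False):
        ext = grp[grp["p_value"] < extend_p]
        if ext.empty:
            continue
        starts = ext["start"].to_numpy()
        ends = ext["end"].to_numpy()
        gaps = starts[1:] - ends[:-1]
        cluster_id = np.concatenate([[0], np.cumsum(gaps > extend_dist_bp)])
        seed_mask = (ext["p_value"] < seed_p).to_numpy()
        g_starts = grp["start"].to_numpy()
        g_ends = grp["end"].to_numpy()
        g_p = grp["p_value"].to_numpy()
        g_lfc = grp["log2fc"].to_numpy()
        g_cpg = grp["cpg_count"].to_numpy() if has_cpg else None
        for cid in np.unique(cluster_id):
            members = cluster_id == cid
            if not seed_mask[members].any():
                continue
            span_start = int(starts[members].min())
            span_end = int(ends[members].max())
            inside = (g_starts >= span_start) & (g_ends <= span_end)
            p_in = g_p[inside]
            i_min = int(np.argmin(p_in))
            min_p = float(p_in[i_min])
            lfc = float(g_lfc[inside][i_min])
            sig = inside & (g_p < seed_p)
            sig_starts = g_starts[sig]
            sig_ends = g_ends[sig]
            n_sig = int(sig.sum())
            if multiple_window_mode == "any_two":
                multiple = n_sig >= 2
            else:
                multiple = bool(np.any(sig_starts[1:] == sig_ends[:-1])) if n_sig >= 2 else False
            lengths = g_ends[inside] - g_starts[inside]
            density = float(np.mean(g_cpg[inside] * 100.0 / lengths)) if has_cpg else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": span_start,
                    "end": span_end,
                    "n_windows_total": int(inside.sum()),
                    "n_windows_significant": n_sig,
                    "is_multiple_window": multiple,
                    "min_p": min_p,
                    "direction": "increase" if lfc > 0 else "decrease",
                    "length_bp": span_end - span_start,
                    "cpg_density_per_100bp": density,
                }
            )
    out = pd.DataFrame(rows, columns=[c for c in DMR_COLUMNS if c != "dmr_id"])
    out.insert(0, "dmr_id", [f"DMR{i + 1:05d}" for i in range(len(out))])
    return out


def dmr_threshold_table(
    window_results: pd.DataFrame,
    thresholds: Sequence[float] = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8),
    extend_p: float = 0.1,
    extend_dist_bp: int = 1000,
) -> pd.DataFrame:
    """All-window and multiple-window DMR counts across seed thresholds."""
    thresholds = list(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly descending")
    rows = []
    for thr in thresholds:
        dmrs = call_dmrs(window_results, seed_p=thr, extend_p=extend_p,
                         extend_dist_bp=extend_dist_bp)
        rows.append(
            {
                "threshold": thr,
                "all_window": len(dmrs),
                "multiple_window": int(dmrs["is_multiple_window"].sum()) if len(dmrs) else 0,
            }
        )
    return pd.DataFrame(rows)


def summarize_dmr_features(dmrs: pd.DataFrame) -> dict[str, pd.Series]:
    """CpG-density histogram (nearest integer per 100 bp), length histogram
    (1-kb bins, label = upper edge in kb) and per-chromosome counts."""
    if dmrs.empty:
        return {
            "cpg_density_hist": pd.Series(dtype=int),
            "length_hist": pd.Series(dtype=int),
            "per_chromosome": pd.Series(dtype=int),
        }
    density_bin = np.rint(dmrs["cpg_density_per_100bp"].to_numpy(float)).astype(int)
    length_bin = np.ceil(dmrs["length_bp"].to_numpy(float) / 1000.0).astype(int)
    return {
        "cpg_density_hist": pd.Series(density_bin).value_counts().sort_index(),
        "length_hist": pd.Series(length_bin).value_counts().sort_index(),
        "per_chromosome": dmrs["chrom"].value_counts().sort_index(),
    }


def cluster_dmrs(
    dmrs: pd.DataFrame,
    max_gap_bp: int = 2_000_000,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Maximal runs of >= ``min_cluster_size`` DMRs on one chromosome with
    consecutive start-to-start gaps <= ``max_gap_bp``."""
    rows = []
    cid = 0
    for chrom, grp in dmrs.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        if len(starts) == 0:
            continue
        breaks = np.flatnonzero(np.diff(starts) > max_gap_bp)
        run_bounds = np.concatenate([[0], breaks + 1, [len(starts)]])
        for lo, hi in zip(run_bounds[:-1], run_bounds[1:]):
            if hi - lo >= min_cluster_size:
                cid += 1
                members = grp.iloc[lo:hi]
                rows.append(
                    {
                        "cluster_id": f"CL{cid:03d}",
                        "chrom": chrom,
                        "start": int(members["start"].min()),
                        "end": int(members["end"].max()),
                        "n_members": int(hi - lo),
                        "member_dmr_ids": ";".join(members["dmr_id"]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["cluster_id", "chrom", "start", "end", "n_members", "member_dmr_ids"]
    )


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6 representation: name = DMR id, score = -log10 min p, strand '.'"""
    score = np.minimum(1000, np.rint(-np.log10(dmrs["min_p"].to_numpy(float))))
    return pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["dmr_id"],
            "score": score.astype(int),
            "strand": ".",
        }
    )
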