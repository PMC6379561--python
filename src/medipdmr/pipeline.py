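"""End-to-end orchestration: simulate -> count -> test -> DMRs -> DE ->
overlaps -> pathology -> report, with a recovery scorecard against the
planted ground truth and a manifest of output hashes for reproducibility.

Each analyzed cell type gets its own simulated MeDIP experiment and
transcript table (independent seeds derived from the master seed); when two
or more cell types are analyzed, cross-cell-type overlaps (shared DMRs by
interval, shared DE transcripts by id) are computed as well.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import PipelineConfig, SimulationConfig
from .dmr import (
    call_dmrs,
    cluster_dmrs,
    dmr_threshold_table,
    dmrs_to_bed,
    summarize_dmr_features,
)
from .overlap import associate_genes, map_counts, venn_ids, venn_intervals
from .pathology import compare_lineages
from .simulate import (
    sample_names,
    simulate_gene_category_map,
    simulate_gene_models,
    simulate_genome,
    simulate_medip_experiment,
    simulate_pathology_scores,
    simulate_transcript_counts,
)
from .stats import differential_expression, test_two_groups
from .windows import count_fragments, tile_genome, window_cpg_counts

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scorecard helpers
# ---------------------------------------------------------------------------

def score_dmr_recovery(called: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity (planted regions overlapped by a call), precision (calls
    overlapping a planted region) and the multiple-window fraction."""
    if truth.empty:
        return {
            "n_called": int(len(called)),
            "n_planted": 0,
            "sensitivity": float("nan"),
            "precision": float("nan"),
            "multiple_window_fraction": float("nan"),
        }
    v = venn_intervals(truth, called)
    sens = v.a_common / v.a_size if v.a_size else float("nan")
    prec = v.b_common / v.b_size if v.b_size else float("nan")
    mw = float(called["is_multiple_window"].mean()) if len(called) else float("nan")
    return {
        "n_called": int(len(called)),
        "n_planted": int(len(truth)),
        "sensitivity": float(sens),
        "precision": float(prec),
        "multiple_window_fraction": mw,
    }


def score_de_recovery(results: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """DE sensitivity over planted transcripts and false-positive rate over
    nulls, at the significance flag already present in ``results``."""
    de_ids = set(results.loc[results["significant"], "id"])
    truth_ids = set(truth["id"])
    tested_ids = set(results["id"])
    truth_tested = truth_ids & tested_ids
    nulls = tested_ids - truth_ids
    sens = len(de_ids & truth_tested) / len(truth_tested) if truth_tested else float("nan")
    fpr = len(de_ids & nulls) / len(nulls) if nulls else float("nan")
    return {
        "n_de_called": len(de_ids),
        "n_planted": len(truth_ids),
        "sensitivity": float(sens),
        "false_positive_rate": float(fpr),
    }


def _cell_type_config(sim: SimulationConfig, offset: int) -> SimulationConfig:
    cfg = dataclasses.replace(sim, seed=sim.seed + offset)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# the full analysis
# ---------------------------------------------------------------------------

def run_cell_type(
    config: PipelineConfig,
    sim: SimulationConfig,
    outdir: Path,
    genome: dict[str, str],
    chrom_sizes: pd.DataFrame,
) -> dict:
    """One cell type's MeDIP + RNA arm; returns in-memory results."""
    outdir.mkdir(parents=True, exist_ok=True)
    seed = sim.seed

    fragments, window_counts, truth = simulate_medip_experiment(
        sim, chrom_sizes, emit_fragments=True
    )
    _, groups = sample_names(sim)
    windows = tile_genome(chrom_sizes, sim.window_width_bp)
    windows = windows.assign(cpg_count=window_cpg_counts(windows, genome))

    if config.write_fragment_beds:
        for name, bed in fragments.items():
            mio.write_bed(bed, outdir / f"fragments_{name}.bed", seed=seed)
        fragments = {
            name: mio.read_bed(outdir / f"fragments_{name}.bed") for name in fragments
        }
    matrix = count_fragments(fragments, windows, groups, mode=config.count_mode)

    sim_counts = window_counts[list(groups.index)].to_numpy()
    if config.count_mode == "midpoint" and not np.array_equal(
        matrix.counts.to_numpy(), sim_counts
    ):
        raise RuntimeError("fragment counting failed to reproduce simulated window counts")

    meta = matrix.windows[["chrom", "start", "end", "cpg_count"]]
    results = test_two_groups(
        matrix.counts,
        groups,
        feature_meta=meta,
        min_total_count=config.min_total_count_windows,
        normalization=config.normalization,
    )
    mio.write_tsv(results, outdir / "window_results.tsv", seed=seed)

    dmrs = call_dmrs(
        results,
        seed_p=config.seed_p,
        extend_p=config.extend_p,
        extend_dist_bp=config.extend_dist_bp,
    )
    mio.write_tsv(dmrs, outdir / "dmrs.tsv", seed=seed)
    mio.write_bed(dmrs_to_bed(dmrs), outdir / "dmrs.bed", seed=seed)
    thresholds = dmr_threshold_table(
        results,
        thresholds=config.dmr_threshold_grid,
        extend_p=config.extend_p,
        extend_dist_bp=config.extend_dist_bp,
    )
    mio.write_tsv(thresholds, outdir / "dmr_threshold_table.tsv", seed=seed)
    summaries = summarize_dmr_features(dmrs)
    for name, series in summaries.items():
        mio.write_tsv(
            series.rename("count").rename_axis("bin").reset_index(),
            outdir / f"dmr_{name}.tsv",
            seed=seed,
        )
    clusters = cluster_dmrs(
        dmrs, max_gap_bp=config.cluster_max_gap_bp, min_cluster_size=config.cluster_min_size
    )
    mio.write_tsv(clusters, outdir / "dmr_clusters.tsv", seed=seed)

    transcripts, rna_truth = simulate_transcript_counts(sim, chrom_sizes)
    mio.write_tsv(transcripts, outdir / "transcript_counts.tsv", seed=seed)
    de_results, tallies = differential_expression(
        transcripts,
        groups,
        p_threshold=config.de_p_threshold,
        min_total_count=config.min_total_count_transcripts,
        normalization=config.normalization,
    )
    mio.write_tsv(de_results, outdir / "de_results.tsv", seed=seed)

    genes = simulate_gene_models(sim, chrom_sizes)
    gene_map = simulate_gene_category_map(sim, genes)
    assoc = associate_genes(dmrs, genes, max_dist_bp=config.gene_max_dist_bp)
    dmr_genes = sorted({g for lst in assoc for g in lst})
    category_counts = map_counts(dmr_genes, gene_map)
    mio.write_tsv(category_counts, outdir / "dmr_gene_categories.tsv", seed=seed)

    de_sig = de_results[de_results["significant"]]
    venn_dmr_rna = {}
    for cls in ("mRNA", "lncRNA", "sncRNA"):
        sub = de_sig[de_sig["class"] == cls]
        v = venn_intervals(dmrs, sub)
        venn_dmr_rna[cls] = dataclasses.asdict(v)

    scorecard = {
        "dmr": score_dmr_recovery(dmrs, truth.planted_dmrs),
        "de": score_de_recovery(de_results, rna_truth.de_transcripts),
    }
    return {
        "windows": windows,
        "window_results": results,
        "dmrs": dmrs,
        "threshold_table": thresholds,
        "clusters": clusters,
        "de_results": de_results,
        "de_tallies": tallies,
        "gene_associations": assoc,
        "category_counts": category_counts,
        "venn_dmr_rna": venn_dmr_rna,
        "truth": truth,
        "rna_truth": rna_truth,
        "scorecard": scorecard,
    }


def run_full_analysis(config: PipelineConfig, outdir) -> dict:
    """Run the whole synthetic analysis and write the report bundle.

    Produces, per cell type: window test results, DMR table + threshold
    table + feature histograms + clusters, DE tables with class tallies,
    gene associations and Venn tables; plus pathology and a recovery
    scorecard.  Deterministic given the config seed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("medipdmr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        seed = config.simulation.seed
        logger.info("run starting with seed %d", seed)
        config.to_yaml(outdir / "config.yaml")

        genome, chrom_sizes = simulate_genome(config.simulation)
        mio.write_fasta(genome, outdir / "genome.fa")
        mio.write_chrom_sizes(chrom_sizes, outdir / "genome.chrom.sizes")

        per_cell: dict[str, dict] = {}
        for i, cell in enumerate(config.cell_types):
            logger.info("analysing cell type %s", cell)
            sim = _cell_type_config(config.simulation, offset=1000 * i)
            per_cell[cell] = run_cell_type(
                config, sim, outdir / cell, genome, chrom_sizes
            )

        cross = {}
        cells = list(config.cell_types)
        if len(cells) >= 2:
            a, b = cells[0], cells[1]
            dmr_venn = venn_intervals(per_cell[a]["dmrs"], per_cell[b]["dmrs"])
            cross["dmr_interval_venn"] = dataclasses.asdict(dmr_venn)
            for cls in ("mRNA", "lncRNA", "sncRNA"):
                ids_a = per_cell[a]["de_results"]
                ids_b = per_cell[b]["de_results"]
                v = venn_ids(
                    ids_a.loc[ids_a["significant"] & (ids_a["class"] == cls), "id"],
                    ids_b.loc[ids_b["significant"] & (ids_b["class"] == cls), "id"],
                )
                cross[f"de_id_venn_{cls}"] = dataclasses.asdict(v)

        pathology_records, path_truth = simulate_pathology_scores(config.simulation)
        mio.write_tsv(pathology_records, outdir / "pathology_scores.tsv", seed=seed)
        path_result = compare_lineages(
            pathology_records,
            sd_multiplier=config.disease_sd_multiplier,
            min_observers=config.consensus_min_observers,
        )

        summary = {
            "seed": seed,
            "cell_types": {
                cell: {
                    "n_dmrs": int(len(res["dmrs"])),
                    "de_tallies": res["de_tallies"],
                    "venn_dmr_rna": res["venn_dmr_rna"],
                    "scorecard": res["scorecard"],
                }
                for cell, res in per_cell.items()
            },
            "cross_cell_type": cross,
            "pathology": {
                "frequencies": path_result.frequencies,
                "table_2x2": path_result.table_2x2.tolist(),
                "fisher_p": path_result.fisher_p,
                "n_truth_affected": int(len(path_truth.diseased_animals)),
            },
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)

        manifest = {
            "seed": seed,
            "files": {
                str(p.relative_to(outdir)): _sha256(p)
                for p in sorted(outdir.rglob("*"))
                if p.is_file() and p.name not in ("manifest.json", "run.log")
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        logger.info("run complete")
        return {
            "per_cell": per_cell,
            "pathology": path_result,
            "summary": summary,
            "manifest": manifest,
        }
    finally:
        root.removeHandler(handler)
        handler.close()
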