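"""Ground-truth synthetic data: genome, MeDIP fragments, RNA counts, pathology.

Emulates the structure of a transgenerational MeDIP-seq / RNA-seq study:
two lineages (control vs exposure) with three pooled samples each, a
CpG-sparse genome with occasional denser patches, planted differentially
methylated regions, planted differentially expressed transcripts in three
RNA classes, and observer-scored histopathology for ~26 control vs ~27
exposed animals.  All draws are deterministic given the config seed; every
operation salts the seed so the streams are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    PATHOLOGY_CATEGORIES,
    RNA_CLASSES,
    SimulationConfig,
)
from .windows import tile_genome

_SALT_GENOME = 101
_SALT_MEDIP = 211
_SALT_RNA = 307
_SALT_PATHOLOGY = 401

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3


@dataclass
class TruthTable:
    """What the simulator planted, for downstream recovery scoring."""

    planted_dmrs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "direction", "fold_change"]
        )
    )
    de_transcripts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["id", "class", "subclass", "direction", "fold_change"]
        )
    )
    diseased_animals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["animal_id", "lineage"])
    )


def sample_names(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    n = config.n_samples_per_group
    names = [f"control_{i + 1}" for i in range(n)] + [f"exposure_{i + 1}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["exposure"] * n, index=names)
    return names, groups


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """CpG-sparse genome with occasional denser patches.

    Random sequence is first scrubbed of accidental CG dinucleotides, then
    CpGs are planted window by window at a Poisson rate whose window-level
    mean follows a two-state local-density process (background vs "island"
    windows at ``cpg_island_fold`` times the background), rescaled so the
    genome-wide mean density equals ``cpg_rate_background`` per 100 bp.
    Returns (sequences, chrom_sizes).
    """
    config.validate()
    rng = np.random.default_rng([_SALT_GENOME, config.seed])
    width = config.window_width_bp
    sequences: dict[str, str] = {}
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        L = config.chrom_length_bp
        codes = rng.integers(0, 4, L, dtype=np.uint8)
        # remove accidental CG: turn the G of every C,G pair into T
        acc = np.flatnonzero((codes[:-1] == _C) & (codes[1:] == _G))
        codes[acc + 1] = _T

        starts = np.arange(0, L, width, dtype=np.int64)
        win_len = np.minimum(width, L - starts)
        n_win = len(starts)
        island = rng.random(n_win) < config.cpg_island_fraction
        factor = np.where(island, config.cpg_island_fold, 1.0)
        f, m = config.cpg_island_fraction, config.cpg_island_fold
        factor = factor / ((1.0 - f) + f * m)  # unit mean
        lam = config.cpg_rate_background * (win_len / 100.0) * factor
        k = np.minimum(rng.poisson(lam), win_len // 2)

        if k.sum() > 0:
            # choose k[w] distinct even offsets per window (spacing >= 2 keeps
            # planted CpGs from overlapping)
            max_slots = width // 2 if width >= 2 else 1
            u = rng.random((n_win, max_slots))
            slot_valid = np.arange(max_slots)[None, :] < (win_len // 2)[:, None]
            u[~slot_valid] = np.inf
            order = np.argsort(u, axis=1)
            rows = np.repeat(np.arange(n_win), k)
            ranks = np.arange(k.sum()) - np.repeat(np.concatenate([[0], np.cumsum(k)[:-1]]), k)
            slots = order[rows, ranks]
            pos = starts[rows] + 2 * slots
            codes[pos] = _C
            codes[pos + 1] = _G
        sequences[name] = _BASES[codes].tobytes().decode("ascii")
    chrom_sizes = pd.DataFrame(
        {"chrom": list(sequences), "length": [len(s) for s in sequences.values()]}
    )
    return sequences, chrom_sizes


# ---------------------------------------------------------------------------
# MeDIP experiment
# ---------------------------------------------------------------------------

def _plant_regions(
    rng: np.random.Generator, windows: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Non-overlapping window-aligned planted regions with a direction split
    of ~50/50 increase vs decrease."""
    width = config.window_width_bp
    lo, hi = config.dmr_width_bp
    n = config.n_planted_dmrs
    if n == 0 or config.methylation_fold_change == 1.0:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction", "fold_change"])
    chrom_bounds = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        chrom_bounds[chrom] = (int(grp.index.min()), int(grp.index.max()) + 1)
    total_windows = len(windows)
    occupied = np.zeros(total_windows, dtype=bool)
    chosen: list[tuple[int, int]] = []  # global window index ranges
    max_attempts = 200 * n
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place non-overlapping planted regions; genome too crowded"
            )
        w_bp = int(rng.integers(lo, hi + 1))
        n_w = max(1, int(round(w_bp / width)))
        gi = int(rng.integers(0, total_windows))
        chrom = windows.at[gi, "chrom"]
        c_lo, c_hi = chrom_bounds[chrom]
        if gi + n_w > c_hi:
            continue
        # keep one buffer window between regions so planted truth stays distinct
        b_lo, b_hi = max(c_lo, gi - 1), min(c_hi, gi + n_w + 1)
        if occupied[b_lo:b_hi].any():
            continue
        occupied[gi : gi + n_w] = True
        chosen.append((gi, gi + n_w))
    n_inc = n - n // 2  # "approximately 50%" increase
    directions = np.array(["increase"] * n_inc + ["decrease"] * (n - n_inc))
    directions = directions[rng.permutation(n)]
    rows = []
    for (gi, gj), direction in zip(chosen, directions):
        rows.append(
            {
                "chrom": windows.at[gi, "chrom"],
                "start": int(windows.at[gi, "start"]),
                "end": int(windows.at[gj - 1, "end"]),
                "direction": direction,
                "fold_change": config.methylation_fold_change,
                "window_start_index": gi,
                "window_end_index": gj,
            }
        )
    out = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean mu, Var = mu + phi mu^2); phi = 0 degenerates to Poisson."""
    if phi == 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _emit_fragments(
    counts: np.ndarray, windows: pd.DataFrame, chrom_len: dict[str, int], frag_len: int
) -> pd.DataFrame:
    """Materialize a sample's window counts as BED fragments.

    Each fragment is centred in its window; near chromosome ends both sides
    are trimmed equally so the midpoint (hence the assigned window) is
    preserved.
    """
    centers = ((windows["start"] + windows["end"]) // 2).to_numpy(np.int64)
    lengths = windows["chrom"].map(chrom_len).to_numpy(np.int64)
    half = np.minimum(frag_len // 2, np.minimum(centers, lengths - centers))
    starts = np.repeat(centers - half, counts)
    ends = np.repeat(centers + half, counts)
    chroms = np.repeat(windows["chrom"].to_numpy(), counts)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "name": [f"frag{i}" for i in range(len(starts))],
        }
    )


def simulate_medip_experiment(
    config: SimulationConfig,
    chrom_sizes: pd.DataFrame,
    emit_fragments: bool = True,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, TruthTable]:
    """Window-level MeDIP counts for both groups, plus BED fragments.

    Control window counts are NB(mu, phi); inside planted regions the exposed
    mean is mu * fold (increase) or mu / fold (decrease).  Returns
    (fragments_by_sample, window_counts, truth); ``window_counts`` carries the
    windows plus one count column per sample, and is exactly recoverable by
    midpoint counting of the emitted fragments.
    """
    config.validate()
    rng = np.random.default_rng([_SALT_MEDIP, config.seed])
    windows = tile_genome(chrom_sizes, config.window_width_bp)
    planted = _plant_regions(rng, windows, config)

    names, groups = sample_names(config)
    n = config.n_samples_per_group
    mu = np.full(len(windows), config.mean_fragment_count_per_window, dtype=float)
    exp_mu = mu.copy()
    for _, r in planted.iterrows():
        lo, hi = int(r["window_start_index"]), int(r["window_end_index"])
        if r["direction"] == "increase":
            exp_mu[lo:hi] *= r["fold_change"]
        else:
            exp_mu[lo:hi] /= r["fold_change"]

    counts = pd.DataFrame(index=windows.index)
    for name in names:
        m = mu if groups[name] == "control" else exp_mu
        counts[name] = _nb_draw(rng, m, config.dispersion)

    chrom_len = dict(zip(chrom_sizes["chrom"], chrom_sizes["length"].astype(int)))
    fragments: dict[str, pd.DataFrame] = {}
    if emit_fragments:
        for name in names:
            fragments[name] = _emit_fragments(
                counts[name].to_numpy(), windows, chrom_len, config.fragment_length_bp
            )
    truth = TruthTable(
        planted_dmrs=planted.drop(
            columns=["window_start_index", "window_end_index"], errors="ignore"
        )
    )
    window_counts = pd.concat([windows, counts], axis=1)
    return fragments, window_counts, truth


# ---------------------------------------------------------------------------
# transcript counts
# ---------------------------------------------------------------------------

def simulate_transcript_counts(
    config: SimulationConfig, chrom_sizes: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, TruthTable]:
    """Transcript count table over mRNA / lncRNA / sncRNA with planted DE.

    A fixed fraction of each class carries a multiplicative group effect
    (direction split 50/50).  Transcripts get genomic intervals for overlap
    analyses; a configurable fraction of sncRNA has an unknown location
    (missing chrom/start/end).  Per-transcript baseline means are lognormal
    around ``mean_count``.
    """
    config.validate()
    de = config.de_config
    rng = np.random.default_rng([_SALT_RNA, config.seed])
    if chrom_sizes is None:
        chrom_sizes = pd.DataFrame(
            {
                "chrom": [f"chr{i + 1}" for i in range(config.n_chromosomes)],
                "length": [config.chrom_length_bp] * config.n_chromosomes,
            }
        )
    names, groups = sample_names(config)
    n_ctrl = config.n_samples_per_group

    length_ranges = {"mRNA": (1000, 10000), "lncRNA": (500, 5000), "sncRNA": (20, 200)}
    rows = []
    truth_rows = []
    for cls in RNA_CLASSES:
        n_cls = int(de.n_per_class.get(cls, 0))
        if n_cls == 0:
            continue
        n_de = int(round(de.de_fraction * n_cls))
        de_flags = np.zeros(n_cls, dtype=bool)
        de_flags[rng.choice(n_cls, size=n_de, replace=False)] = True
        n_up = n_de - n_de // 2
        dir_pool = np.array(["up"] * n_up + ["down"] * (n_de - n_up))
        dir_pool = dir_pool[rng.permutation(n_de)]
        if cls == "sncRNA":
            subs = list(de.sncrna_subclass_props)
            probs = np.array([de.sncrna_subclass_props[s] for s in subs], dtype=float)
            probs = probs / probs.sum()
            subclasses = rng.choice(subs, size=n_cls, p=probs)
            unknown = rng.random(n_cls) < de.unknown_location_fraction
        else:
            subclasses = np.array([""] * n_cls)
            unknown = np.zeros(n_cls, dtype=bool)
        base = rng.lognormal(
            math.log(de.mean_count) - de.base_mean_sigma**2 / 2.0,
            de.base_mean_sigma,
            n_cls,
        )
        chrom_idx = rng.integers(0, len(chrom_sizes), n_cls)
        lo, hi = length_ranges[cls]
        lengths = rng.integers(lo, hi + 1, n_cls)
        clens = chrom_sizes["length"].to_numpy()[chrom_idx]
        starts = (rng.random(n_cls) * np.maximum(clens - lengths, 1)).astype(np.int64)
        de_i = 0
        for i in range(n_cls):
            tid = f"{cls}_{i + 1:05d}"
            ctrl_mean = base[i]
            exp_mean = base[i]
            if de_flags[i]:
                direction = dir_pool[de_i]
                de_i += 1
                if direction == "up":
                    exp_mean = base[i] * de.de_fold_change
                else:
                    exp_mean = base[i] / de.de_fold_change
                truth_rows.append(
                    {
                        "id": tid,
                        "class": cls,
                        "subclass": subclasses[i],
                        "direction": direction,
                        "fold_change": de.de_fold_change,
                    }
                )
            ctrl = _nb_draw(rng, np.full(n_ctrl, ctrl_mean), de.dispersion)
            exp = _nb_draw(rng, np.full(n_ctrl, exp_mean), de.dispersion)
            row = {
                "id": tid,
                "class": cls,
                "subclass": subclasses[i],
                "chrom": pd.NA if unknown[i] else chrom_sizes["chrom"].iloc[chrom_idx[i]],
                "start": pd.NA if unknown[i] else int(starts[i]),
                "end": pd.NA if unknown[i] else int(starts[i] + lengths[i]),
            }
            row.update({s: int(c) for s, c in zip(names[:n_ctrl], ctrl)})
            row.update({s: int(c) for s, c in zip(names[n_ctrl:], exp)})
            rows.append(row)
    transcripts = pd.DataFrame(rows)
    truth = TruthTable(
        de_transcripts=pd.DataFrame(
            truth_rows, columns=["id", "class", "subclass", "direction", "fold_change"]
        )
    )
    return transcripts, truth


# ---------------------------------------------------------------------------
# pathology scores
# ---------------------------------------------------------------------------

def simulate_pathology_scores(config: SimulationConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Per-animal per-observer abnormality counts for both lineages.

    Every animal has a latent per-category rate; observers are independent
    Poisson draws around it.  A configured fraction of exposed animals gets an
    excess rate in randomly chosen categories.  Output rows: one per animal
    per observer, columns animal_id, lineage, observer, then one column per
    category.
    """
    config.validate()
    pc = config.pathology_config
    rng = np.random.default_rng([_SALT_PATHOLOGY, config.seed])
    cats = list(PATHOLOGY_CATEGORIES)

    animals = [(f"C{i + 1:03d}", "control") for i in range(pc.n_control)]
    animals += [(f"V{i + 1:03d}", "exposed") for i in range(pc.n_exposed)]
    n_affected = int(round(pc.affected_fraction * pc.n_exposed))
    affected_idx = set(rng.choice(pc.n_exposed, size=n_affected, replace=False).tolist())

    rows = []
    truth_rows = []
    for idx, (animal, lineage) in enumerate(animals):
        latent = {c: pc.baseline_rate for c in cats}
        if lineage == "exposed" and (idx - pc.n_control) in affected_idx:
            hit = rng.choice(len(cats), size=pc.n_affected_categories, replace=False)
            for j in hit:
                latent[cats[j]] = pc.baseline_rate + pc.excess_rate
            truth_rows.append({"animal_id": animal, "lineage": lineage})
        for obs in range(1, pc.n_observers + 1):
            row = {"animal_id": animal, "lineage": lineage, "observer": f"obs{obs}"}
            for c in cats:
                row[c] = int(rng.poisson(latent[c]))
            rows.append(row)
    records = pd.DataFrame(rows)
    truth = TruthTable(
        diseased_animals=pd.DataFrame(truth_rows, columns=["animal_id", "lineage"])
    )
    return records, truth


# ---------------------------------------------------------------------------
# auxiliary annotation inputs (artifact plumbing for the overlap stage)
# ---------------------------------------------------------------------------

def simulate_gene_models(
    config: SimulationConfig, chrom_sizes: pd.DataFrame, n_genes: int = 200
) -> pd.DataFrame:
    """Random non-overlapping gene bodies for the annotation stage."""
    rng = np.random.default_rng([_SALT_RNA + 1, config.seed])
    rows = []
    per_chrom = max(1, n_genes // len(chrom_sizes))
    gi = 0
    for chrom, length in zip(chrom_sizes["chrom"], chrom_sizes["length"].astype(int)):
        slots = np.sort(rng.choice(max(per_chrom * 2, 4), size=per_chrom, replace=False))
        step = length // max(per_chrom * 2, 4)
        for s in slots:
            gi += 1
            start = int(s) * step
            glen = int(rng.integers(2000, max(3000, min(20000, step))))
            rows.append(
                {
                    "gene_id": f"GENE{gi:04d}",
                    "symbol": f"Gene{gi}",
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + glen, length),
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
    return pd.DataFrame(rows)


def simulate_gene_category_map(
    config: SimulationConfig, genes: pd.DataFrame,
    categories: tuple[str, ...] = (
        "signaling", "metabolism", "transcription", "receptor",
        "development", "cytoskeleton", "translation",
    ),
) -> pd.DataFrame:
    """Random gene -> functional-category map (multi-label allowed)."""
    rng = np.random.default_rng([_SALT_RNA + 2, config.seed])
    rows = []
    for gid in genes["gene_id"]:
        n_labels = 1 + int(rng.random() < 0.2)
        for j in rng.choice(len(categories), size=n_labels, replace=False):
            rows.append({"gene_id": gid, "label": categories[j]})
    return pd.DataFrame(rows)
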