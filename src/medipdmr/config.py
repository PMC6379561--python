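"""Configuration objects for the simulator and the analysis pipeline.

All tunable parameters live here so that a run is fully described by one
(serializable) object plus a seed.  Defaults follow the study design the
package emulates: 100 bp genomic windows, DMR seed threshold p < 1e-6 with
edge extension at p < 0.1 within 1,000 bp, differential expression at
p < 0.001, gene association within 10 kb, a mean + 2 SD disease cutoff with
2-of-3 observer consensus, and 3 pooled samples per group.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

PATHOLOGY_CATEGORIES = ("atrophy", "hyperplasia", "vacuoles")
RNA_CLASSES = ("mRNA", "lncRNA", "sncRNA")
SNCRNA_SUBCLASSES = ("miRNA", "piRNA", "tRNA", "other")


@dataclass
class DEConfig:
    """Transcript-count simulation parameters (per RNA class)."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"mRNA": 1500, "lncRNA": 900, "sncRNA": 600}
    )
    sncrna_subclass_props: dict[str, float] = field(
        default_factory=lambda: {"miRNA": 0.40, "piRNA": 0.40, "tRNA": 0.10, "other": 0.10}
    )
    de_fraction: float = 0.05
    de_fold_change: float = 8.0
    mean_count: float = 100.0
    dispersion: float = 0.1
    base_mean_sigma: float = 0.5  # lognormal spread of per-transcript baseline means
    unknown_location_fraction: float = 0.05  # sncRNA without a genomic interval

    def validate(self) -> None:
        if not self.n_per_class:
            raise ValueError("n_per_class must be non-empty")
        for cls in self.n_per_class:
            if cls not in RNA_CLASSES:
                raise ValueError(f"invalid RNA class label: {cls!r}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.de_fold_change <= 0:
            raise ValueError("de_fold_change must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.unknown_location_fraction <= 1.0:
            raise ValueError("unknown_location_fraction must lie in [0, 1]")
        for sub in self.sncrna_subclass_props:
            if sub not in SNCRNA_SUBCLASSES:
                raise ValueError(f"invalid sncRNA subclass: {sub!r}")


@dataclass
class PathologyConfig:
    """Observer-scored histopathology simulation parameters.

    Counts are abnormality tallies per tissue section; each of ``n_observers``
    independently re-scores every animal (independent Poisson draws around a
    per-animal latent rate).  A fraction of exposed-lineage animals carries an
    excess rate in ``n_affected_categories`` randomly chosen categories.
    """

    baseline_rate: float = 0.5
    excess_rate: float = 2.0
    affected_fraction: float = 0.4
    n_control: int = 26
    n_exposed: int = 27
    n_observers: int = 3
    n_affected_categories: int = 2

    def validate(self) -> None:
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        if self.baseline_rate < 0 or self.excess_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if self.n_control < 2 or self.n_exposed < 1:
            raise ValueError("need >= 2 control and >= 1 exposed animals")
        if not 1 <= self.n_affected_categories <= len(PATHOLOGY_CATEGORIES):
            raise ValueError("n_affected_categories out of range")


@dataclass
class SimulationConfig:
    """Ground-truth synthetic experiment: genome, MeDIP counts, RNA, pathology.

    The MeDIP arm plants ``n_planted_dmrs`` non-overlapping window-aligned
    regions where the exposed-group mean is multiplied (half the regions) or
    divided (the other half) by ``methylation_fold_change``; window counts are
    negative binomial with Var = mu + phi * mu^2 (phi = ``dispersion``; phi = 0
    degenerates to Poisson).
    """

    seed: int = 0
    n_chromosomes: int = 1
    chrom_length_bp: int = 5_000_000
    window_width_bp: int = 100
    cpg_rate_background: float = 1.5  # CpG per 100 bp, genome-wide mean
    cpg_island_fraction: float = 0.02  # fraction of windows with elevated density
    cpg_island_fold: float = 8.0
    n_samples_per_group: int = 3
    mean_fragment_count_per_window: float = 50.0
    dispersion: float = 0.1
    n_planted_dmrs: int = 100
    dmr_width_bp: tuple[int, int] = (300, 500)
    methylation_fold_change: float = 8.0
    fragment_length_bp: int = 300
    de_config: DEConfig = field(default_factory=DEConfig)
    pathology_config: PathologyConfig = field(default_factory=PathologyConfig)

    def validate(self) -> None:
        if self.chrom_length_bp <= 0 or self.n_chromosomes <= 0:
            raise ValueError("chromosome number and length must be positive")
        if self.window_width_bp < 1:
            raise ValueError("window_width_bp must be >= 1")
        if self.cpg_rate_background < 0:
            raise ValueError("cpg_rate_background must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion (phi) must be >= 0")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        lo, hi = self.dmr_width_bp
        if not (0 < lo <= hi):
            raise ValueError("dmr_width_bp must be an increasing positive range")
        if self.n_planted_dmrs < 0:
            raise ValueError("n_planted_dmrs must be >= 0")
        genome = self.n_chromosomes * self.chrom_length_bp
        if self.n_planted_dmrs * hi >= genome / 10:
            raise ValueError("planted DMRs would occupy more than a tenth of the genome")
        self.de_config.validate()
        self.pathology_config.validate()


@dataclass
class PipelineConfig:
    """End-to-end analysis parameters.  Defaults are the study's stated ones."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cell_types: tuple[str, ...] = ("epithelial", "stromal")
    seed_p: float = 1e-6
    extend_p: float = 0.1
    extend_dist_bp: int = 1000
    dmr_threshold_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)
    de_p_threshold: float = 0.001
    gene_max_dist_bp: int = 10_000
    fdr_report_threshold: float = 0.1
    disease_sd_multiplier: float = 2.0
    consensus_min_observers: int = 2
    count_mode: str = "midpoint"  # or "overlap"
    min_total_count_windows: int = 0
    min_total_count_transcripts: int = 10
    normalization: str = "tmm"  # or "total"
    cluster_max_gap_bp: int = 2_000_000
    cluster_min_size: int = 3
    write_fragment_beds: bool = True

    def validate(self) -> None:
        self.simulation.validate()
        for p in (self.seed_p, self.extend_p, self.de_p_threshold):
            if not 0 < p < 1:
                raise ValueError("p-value thresholds must lie in (0, 1)")
        if self.count_mode not in ("midpoint", "overlap"):
            raise ValueError("count_mode must be 'midpoint' or 'overlap'")
        if self.normalization not in ("tmm", "total"):
            raise ValueError("normalization must be 'tmm' or 'total'")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain_dict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return _pipeline_config_from_dict(raw)


def _as_plain_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_plain_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _as_plain_dict(v) for k, v in obj.items()}
    return obj


def _pipeline_config_from_dict(raw: dict) -> PipelineConfig:
    sim_raw = dict(raw.pop("simulation", {}))
    de_raw = dict(sim_raw.pop("de_config", {}))
    path_raw = dict(sim_raw.pop("pathology_config", {}))
    if "dmr_width_bp" in sim_raw:
        sim_raw["dmr_width_bp"] = tuple(sim_raw["dmr_width_bp"])
    sim = SimulationConfig(
        de_config=DEConfig(**de_raw),
        pathology_config=PathologyConfig(**path_raw),
        **sim_raw,
    )
    for key in ("cell_types", "dmr_threshold_grid"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(simulation=sim, **raw)
    cfg.validate()
    return cfg
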