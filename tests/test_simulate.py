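"""The synthetic generator: determinism, ground-truth bookkeeping,
distributional targets and conservation of fragments."""

import dataclasses
import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import medipdmr as m
from medipdmr.config import DEConfig, PathologyConfig, SimulationConfig
from medipdmr.simulate import sample_names


def _hash_frames(*frames: pd.DataFrame) -> str:
    h = hashlib.sha256()
    for df in frames:
        h.update(df.to_csv().encode())
    return h.hexdigest()


class TestGenome:
    def test_zero_rate_gives_cpg_free_genome(self):
        cfg = SimulationConfig(seed=1, chrom_length_bp=50_000, cpg_rate_background=0.0,
                               n_planted_dmrs=0)
        genome, _ = m.simulate_genome(cfg)
        assert genome["chr1"].count("CG") == 0

    def test_realized_density_within_20pct_of_config(self, small_sim_config):
        genome, _ = m.simulate_genome(small_sim_config)
        seq = genome["chr1"]
        density = seq.count("CG") * 100.0 / len(seq)
        target = small_sim_config.cpg_rate_background
        assert abs(density - target) <= 0.2 * target

    def test_modal_window_cpg_count_is_1_or_2(self, small_sim_config):
        # the background emulates CpG deserts: most 100 bp windows hold 1-2 CpG
        genome, sizes = m.simulate_genome(small_sim_config)
        win = m.tile_genome(sizes, 100)
        counts = m.window_cpg_counts(win, genome)
        mode = np.bincount(counts).argmax()
        assert mode in (1, 2)

    def test_deterministic_given_seed(self, small_sim_config):
        g1, s1 = m.simulate_genome(small_sim_config)
        g2, s2 = m.simulate_genome(small_sim_config)
        assert g1 == g2
        assert s1.equals(s2)

    def test_rejects_non_positive_length(self):
        cfg = SimulationConfig(chrom_length_bp=0, n_planted_dmrs=0)
        with pytest.raises(ValueError, match="positive"):
            m.simulate_genome(cfg)


class TestMedipExperiment:
    def test_planted_regions_count_and_disjointness(self, small_sim_config):
        _, sizes = m.simulate_genome(small_sim_config)
        _, _, truth = m.simulate_medip_experiment(small_sim_config, sizes,
                                                  emit_fragments=False)
        planted = truth.planted_dmrs
        assert len(planted) == small_sim_config.n_planted_dmrs
        planted = planted.sort_values(["chrom", "start"])
        for c, grp in planted.groupby("chrom"):
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()
        # fully inside the chromosome, aligned to whole windows
        assert (planted["start"] >= 0).all()
        assert (planted["end"] <= small_sim_config.chrom_length_bp).all()
        assert (planted["start"] % 100 == 0).all()
        assert (planted["end"] % 100 == 0).all()

    def test_fold_change_one_means_no_planted_effects(self, small_sim_config):
        cfg = dataclasses.replace(small_sim_config, methylation_fold_change=1.0)
        _, sizes = m.simulate_genome(cfg)
        _, _, truth = m.simulate_medip_experiment(cfg, sizes, emit_fragments=False)
        assert truth.planted_dmrs.empty

    def test_direction_split_roughly_even(self):
        cfg = SimulationConfig(seed=5, chrom_length_bp=1_000_000, n_planted_dmrs=40)
        _, sizes = m.simulate_genome(cfg)
        _, _, truth = m.simulate_medip_experiment(cfg, sizes, emit_fragments=False)
        n_inc = (truth.planted_dmrs["direction"] == "increase").sum()
        assert n_inc == 20  # exact 50/50 split by construction

    def test_fragment_conservation(self, small_sim_config):
        # number of BED fragments per sample equals the sum of window counts
        _, sizes = m.simulate_genome(small_sim_config)
        frags, window_counts, _ = m.simulate_medip_experiment(small_sim_config, sizes)
        names, _ = sample_names(small_sim_config)
        for name in names:
            assert len(frags[name]) == window_counts[name].sum()

    def test_fragment_midpoints_fall_in_their_window(self, small_sim_config):
        _, sizes = m.simulate_genome(small_sim_config)
        frags, window_counts, _ = m.simulate_medip_experiment(small_sim_config, sizes)
        bed = frags["control_1"]
        mid = (bed["start"] + bed["end"]) // 2
        # reconstruct window by midpoint and compare against the count table
        counts = np.bincount(mid // 100, minlength=len(window_counts))
        assert np.array_equal(counts, window_counts["control_1"].to_numpy())

    def test_null_window_mean_matches_config(self):
        # Monte-Carlo check of the NB moment: 1,000 null windows
        cfg = SimulationConfig(seed=9, chrom_length_bp=100_000, n_planted_dmrs=0)
        _, sizes = m.simulate_genome(cfg)
        _, wc, _ = m.simulate_medip_experiment(cfg, sizes, emit_fragments=False)
        mu = cfg.mean_fragment_count_per_window
        var = mu + cfg.dispersion * mu**2
        se = np.sqrt(var / len(wc))
        assert abs(wc["control_1"].mean() - mu) <= 3 * se

    def test_deterministic_given_seed(self, small_sim_config):
        _, sizes = m.simulate_genome(small_sim_config)
        f1, w1, _ = m.simulate_medip_experiment(small_sim_config, sizes)
        f2, w2, _ = m.simulate_medip_experiment(small_sim_config, sizes)
        assert _hash_frames(w1, *f1.values()) == _hash_frames(w2, *f2.values())


class TestTranscripts:
    def test_de_fraction_zero_gives_empty_truth(self, small_sim_config):
        cfg = dataclasses.replace(
            small_sim_config,
            de_config=dataclasses.replace(small_sim_config.de_config, de_fraction=0.0),
        )
        _, truth = m.simulate_transcript_counts(cfg)
        assert truth.de_transcripts.empty

    def test_planted_de_count_exact(self):
        cfg = SimulationConfig(
            seed=2, de_config=DEConfig(n_per_class={"mRNA": 1000}, de_fraction=0.05)
        )
        transcripts, truth = m.simulate_transcript_counts(cfg)
        assert len(transcripts) == 1000
        assert len(truth.de_transcripts) == 50

    def test_class_and_subclass_labels(self, small_sim_config):
        transcripts, _ = m.simulate_transcript_counts(small_sim_config)
        assert set(transcripts["class"]) == {"mRNA", "lncRNA", "sncRNA"}
        snc = transcripts[transcripts["class"] == "sncRNA"]
        assert set(snc["subclass"]) <= {"miRNA", "piRNA", "tRNA", "other"}
        assert (transcripts.loc[transcripts["class"] != "sncRNA", "subclass"] == "").all()

    def test_unknown_locations_only_for_sncrna(self, small_sim_config):
        transcripts, _ = m.simulate_transcript_counts(small_sim_config)
        missing = transcripts["chrom"].isna()
        assert set(transcripts.loc[missing, "class"]) <= {"sncRNA"}


class TestPathology:
    def test_output_shape_matches_study_design(self):
        cfg = SimulationConfig(seed=3)
        records, _ = m.simulate_pathology_scores(cfg)
        # 26 + 27 animals x 3 observers, one row each, 3 category columns
        assert len(records) == (26 + 27) * 3
        assert records["animal_id"].nunique() == 53
        assert records["observer"].nunique() == 3
        assert {"atrophy", "hyperplasia", "vacuoles"} <= set(records.columns)

    def test_affected_fraction_one_flags_all_exposed(self):
        pc = PathologyConfig(affected_fraction=1.0, excess_rate=50.0)
        cfg = dataclasses.replace(SimulationConfig(seed=4), pathology_config=pc)
        records, truth = m.simulate_pathology_scores(cfg)
        assert len(truth.diseased_animals) == pc.n_exposed
        res = m.compare_lineages(records)
        assert res.frequencies["exposed"] == 1.0

    def test_null_truth_empty(self):
        pc = PathologyConfig(excess_rate=0.0, affected_fraction=0.0)
        cfg = dataclasses.replace(SimulationConfig(seed=5), pathology_config=pc)
        _, truth = m.simulate_pathology_scores(cfg)
        assert truth.diseased_animals.empty


class TestNullExchangeability:
    def test_label_permutation_leaves_p_distribution_unchanged(self):
        """With all effects off, a permuted group labelling gives the same
        distribution of window p-values (KS test over 50 replicate seeds)."""
        base = SimulationConfig(chrom_length_bp=20_000, n_planted_dmrs=0,
                                mean_fragment_count_per_window=30.0)
        names, groups = sample_names(base)
        permuted = pd.Series(
            ["control", "exposure", "control", "exposure", "control", "exposure"],
            index=names,
        )
        stat_orig, stat_perm = [], []
        for s in range(50):
            cfg = dataclasses.replace(base, seed=100 + s)
            _, sizes = m.simulate_genome(cfg)
            _, wc, _ = m.simulate_medip_experiment(cfg, sizes, emit_fragments=False)
            counts = wc[names]
            r1 = m.test_two_groups(counts, groups)
            r2 = m.test_two_groups(counts, permuted)
            stat_orig.append(r1["p_value"].median())
            stat_perm.append(r2["p_value"].median())
        ks = sps.ks_2samp(stat_orig, stat_perm)
        assert ks.pvalue > 0.01
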