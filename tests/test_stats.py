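"""Normalization, dispersion estimation, the NB exact test, fold change,
BH FDR and class-wise differential expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps

import medipdmr as m
from medipdmr.config import DEConfig, SimulationConfig
from medipdmr.simulate import sample_names
from medipdmr.stats import _ExactTestCache, exact_test_pvalues

from .oracles import binomial_exact_two_sided

NAMES = ["control_1", "control_2", "control_3", "exposure_1", "exposure_2", "exposure_3"]
GROUPS = pd.Series(["control"] * 3 + ["exposure"] * 3, index=NAMES)


def nb_matrix(rng, mu, phi, shape):
    if phi == 0:
        return rng.poisson(mu, shape)
    size = 1.0 / phi
    return rng.negative_binomial(size, size / (size + mu), shape)


class TestNormalization:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        res = m.normalization_factors(df)
        assert np.allclose(res.scale_factors, [1.0, 1.0])

    def test_pure_depth_scaling(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, 2000)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        res = m.normalization_factors(df)
        assert abs(np.prod(res.scale_factors) - 1.0) < 1e-12
        ratio = res.effective_sizes["b"] / res.effective_sizes["a"]
        assert abs(ratio - 2.0) < 1e-9

    @given(
        counts=hnp.arrays(
            np.int64, (30, 4), elements=st.integers(0, 500)
        ).filter(lambda c: (c.sum(axis=0) > 0).all())
    )
    def test_geometric_mean_of_factors_is_one(self, counts):
        res = m.normalization_factors(pd.DataFrame(counts))
        assert abs(np.exp(np.mean(np.log(res.scale_factors))) - 1.0) < 1e-12

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            m.normalization_factors(df)

    def test_total_mode_keeps_library_sizes(self):
        df = pd.DataFrame({"a": [5, 5], "b": [20, 20]})
        res = m.normalization_factors(df, method="total")
        assert np.allclose(res.scale_factors, 1.0)
        assert res.effective_sizes.tolist() == [10, 40]


class TestDispersion:
    def _estimate(self, counts):
        df = pd.DataFrame(counts, columns=NAMES)
        norm = m.normalization_factors(df)
        return m.estimate_common_dispersion(df, GROUPS, norm)

    def test_poisson_matrix_estimates_near_zero(self):
        rng = np.random.default_rng(1)
        phi = self._estimate(nb_matrix(rng, 50, 0.0, (50_000, 6)))
        assert phi <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(2)
        phi = self._estimate(nb_matrix(rng, 50, 0.2, (50_000, 6)))
        assert 0.1 <= phi <= 0.3

    def test_constant_matrix_gives_zero(self):
        phi = self._estimate(np.full((100, 6), 7))
        assert phi == 0.0


class TestExactTest:
    def _norm(self, df):
        return m.normalization_factors(df, method="total")

    def test_symmetric_mode_gives_p_one(self):
        fc = pd.Series([10, 10, 10, 10, 10, 10], index=NAMES)
        df = pd.DataFrame(np.full((5, 6), 10), columns=NAMES)
        p = m.nb_exact_test(fc, GROUPS, self._norm(df), phi=0.1)
        assert p == 1.0

    def test_label_swap_invariance(self):
        fc = pd.Series([5, 8, 12, 40, 55, 60], index=NAMES)
        df = pd.DataFrame(np.full((5, 6), 30), columns=NAMES)
        swapped = GROUPS.map({"control": "exposure", "exposure": "control"})
        norm = self._norm(df)
        assert m.nb_exact_test(fc, GROUPS, norm, 0.1) == m.nb_exact_test(
            fc, swapped, norm, 0.1
        )

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            _ExactTestCache(3, 3, -0.5)

    def test_zero_total_gives_p_one(self):
        assert _ExactTestCache(3, 3, 0.1).p_value(0, 0) == 1.0

    def test_poisson_limit_matches_binomial_enumeration(self):
        # phi = 0: the conditional test is an exact binomial test
        rng = np.random.default_rng(3)
        cache = _ExactTestCache(3, 3, 0.0)
        cache_unequal = _ExactTestCache(2, 4, 0.0)
        for _ in range(200):
            T = int(rng.integers(1, 200))
            A = int(rng.integers(0, T + 1))
            assert abs(cache.p_value(A, T) - float(binomial_exact_two_sided(A, T, 3, 3))) < 1e-9
            assert (
                abs(cache_unequal.p_value(A, T) - float(binomial_exact_two_sided(A, T, 2, 4)))
                < 1e-9
            )

    def test_poisson_limit_matches_scipy_binomtest(self):
        rng = np.random.default_rng(4)
        cache = _ExactTestCache(2, 4, 0.0)
        for _ in range(100):
            T = int(rng.integers(1, 150))
            A = int(rng.integers(0, T + 1))
            expected = sps.binomtest(A, T, 2 / 6).pvalue
            assert abs(cache.p_value(A, T) - expected) < 1e-9

    def test_p_monotone_away_from_mode(self):
        for phi in (0.0, 0.1, 0.5):
            cache = _ExactTestCache(3, 3, phi)
            T = 120
            ps = np.array([cache.p_value(a, T) for a in range(T + 1)])
            mode = int(np.argmax(ps))
            assert np.all(np.diff(ps[: mode + 1]) >= 0)
            assert np.all(np.diff(ps[mode:]) <= 0)

    def test_type_one_error_conservative_small_null(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(nb_matrix(rng, 50, 0.1, (5000, 6)), columns=NAMES)
        norm = m.normalization_factors(df)
        p = exact_test_pvalues(df, GROUPS, norm, 0.1)
        for alpha in (0.05, 0.01):
            assert (p < alpha).mean() <= alpha + 3 * np.sqrt(alpha / len(p))


class TestFoldChange:
    def _norm(self, n_features=1):
        df = pd.DataFrame(np.full((max(n_features, 2), 6), 10), columns=NAMES)
        return m.normalization_factors(df, method="total")

    def test_equal_means_give_zero(self):
        fc = pd.Series([10] * 6, index=NAMES)
        assert m.log2_fold_change(fc, GROUPS, self._norm()) == 0.0

    def test_all_zero_counts_give_zero(self):
        fc = pd.Series([0] * 6, index=NAMES)
        assert m.log2_fold_change(fc, GROUPS, self._norm()) == 0.0

    def test_pseudocount_arithmetic(self):
        # control mean 9.5, exposure mean 19.5 -> log2(20/10) = 1
        fc = pd.Series([9.5] * 3 + [19.5] * 3, index=NAMES)
        assert abs(m.log2_fold_change(fc, GROUPS, self._norm()) - 1.0) < 1e-12


class TestBhFdr:
    def test_single_p(self):
        assert m.bh_fdr([0.01]) == pytest.approx([0.01])

    def test_step_up_example(self):
        assert m.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(
        st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=60)
    )
    def test_monotone_in_sorted_order_and_matches_statsmodels(self, ps):
        q = m.bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-15)
        from statsmodels.stats.multitest import multipletests

        _, q_sm, _, _ = multipletests(ps, method="fdr_bh")
        assert np.allclose(q, q_sm)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            m.bh_fdr([1.5])


class TestDifferentialExpression:
    def test_null_yields_few_discoveries(self):
        cfg = SimulationConfig(
            seed=21,
            de_config=DEConfig(
                n_per_class={"mRNA": 400, "lncRNA": 200, "sncRNA": 100}, de_fraction=0.0
            ),
        )
        transcripts, _ = m.simulate_transcript_counts(cfg)
        _, groups = sample_names(cfg)
        results, tallies = m.differential_expression(transcripts, groups)
        assert tallies["total"] <= max(3, int(0.005 * len(results)))

    def test_planted_de_recovered_and_tallies_partition(self, small_sim_config):
        transcripts, truth = m.simulate_transcript_counts(small_sim_config)
        _, groups = sample_names(small_sim_config)
        results, tallies = m.differential_expression(transcripts, groups)
        de_ids = set(results.loc[results["significant"], "id"])
        truth_ids = set(truth.de_transcripts["id"]) & set(results["id"])
        assert len(de_ids & truth_ids) / len(truth_ids) >= 0.9
        assert tallies["total"] == sum(tallies["by_class"].values())
        assert sum(tallies["by_sncrna_subclass"].values()) == tallies["by_class"]["sncRNA"]

    def test_fold_change_sign_matches_planted_direction(self, small_sim_config):
        transcripts, truth = m.simulate_transcript_counts(small_sim_config)
        _, groups = sample_names(small_sim_config)
        results, _ = m.differential_expression(transcripts, groups)
        merged = results.merge(truth.de_transcripts[["id", "direction"]], on="id")
        sign_ok = np.where(merged["direction"] == "up", merged["log2fc"] > 0,
                           merged["log2fc"] < 0)
        assert sign_ok.mean() >= 0.99

    def test_missing_class_label_rejected(self):
        df = pd.DataFrame(
            {"id": ["t1"], "class": [None], "subclass": [""],
             **{n: [5] for n in NAMES}}
        )
        with pytest.raises(ValueError, match="class"):
            m.differential_expression(df, GROUPS)

    def test_invalid_class_label_rejected(self):
        df = pd.DataFrame(
            {"id": ["t1", "t2"], "class": ["mRNA", "rRNA"], "subclass": ["", ""],
             **{n: [5, 5] for n in NAMES}}
        )
        with pytest.raises(ValueError, match="rRNA"):
            m.differential_expression(df, GROUPS)
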