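import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from monosig import (
    InsufficientDataError,
    ParameterError,
    UndefinedEffectError,
    benjamini_hochberg,
    hedges_g,
    pool_random_effects,
    run_meta,
    simulate_sorted_studies,
)
from monosig.meta import StudyEffect

from conftest import make_dataset


def bh_stepup_oracle(p):
    """Brute-force BH: sort, scale by m/rank, enforce monotonicity, cap."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestHedgesG:
    def test_hand_worked_example(self):
        g, var_g = hedges_g([10, 12, 14], [4, 6, 8])
        assert g == pytest.approx(2.4, abs=1e-12)
        assert var_g == pytest.approx(6 / 9 + 2.4**2 / 12, abs=1e-12)

    def test_equal_means_give_zero(self):
        g, _ = hedges_g([1, 2, 3], [3, 2, 1])
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_swapping_groups_negates_g_keeps_variance(self):
        g1, v1 = hedges_g([10, 12, 14], [4, 6, 8])
        g2, v2 = hedges_g([4, 6, 8], [10, 12, 14])
        assert g2 == pytest.approx(-g1)
        assert v2 == pytest.approx(v1)

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
        seed=st.integers(0, 50),
    )
    def test_location_scale_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1, 1, 6)
        b = rng.normal(0, 1, 8)
        g0, v0 = hedges_g(a, b)
        g1, v1 = hedges_g(a * scale + shift, b * scale + shift)
        assert g1 == pytest.approx(g0, rel=1e-9, abs=1e-9)
        assert v1 == pytest.approx(v0, rel=1e-9, abs=1e-9)

    def test_zero_spread_undefined(self):
        with pytest.raises(UndefinedEffectError):
            hedges_g([5, 5, 5], [3, 3, 3])

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            hedges_g([1], [2, 3])


class TestPooling:
    def test_hand_worked_two_study_example(self):
        effects = [
            StudyEffect("g", "s1", 0.5, 0.1, 5, 5),
            StudyEffect("g", "s2", 0.7, 0.1, 5, 5),
        ]
        res = pool_random_effects(effects)
        assert res.pooled_g == pytest.approx(0.6, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(0.05), abs=1e-8)
        assert res.tau2 == 0.0
        assert res.q_stat == pytest.approx(0.2, abs=1e-12)

    def test_single_study_reduction(self):
        res = pool_random_effects([StudyEffect("g", "s1", 1.3, 0.2, 4, 4)])
        assert res.pooled_g == pytest.approx(1.3)
        assert res.se == pytest.approx(np.sqrt(0.2))
        assert res.tau2 == 0.0

    def test_homogeneous_studies(self):
        effects = [StudyEffect("g", f"s{i}", 0.8, 0.15, 5, 5) for i in range(4)]
        res = pool_random_effects(effects)
        assert res.pooled_g == pytest.approx(0.8)
        assert res.tau2 == 0.0

    def test_fixed_effect_equivalence_when_tau_zero(self):
        g = np.array([0.2, 0.25, 0.3])
        v = np.array([0.3, 0.4, 0.5])
        effects = [StudyEffect("g", f"s{i}", gi, vi, 5, 5) for i, (gi, vi) in enumerate(zip(g, v))]
        res = pool_random_effects(effects)
        w = 1 / v
        assert res.tau2 == 0.0
        assert res.pooled_g == pytest.approx((w * g).sum() / w.sum())

    def test_p_value_is_two_sided_normal(self):
        res = pool_random_effects([StudyEffect("g", "s", -0.9, 0.04, 6, 6)])
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(res.z)))

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            pool_random_effects([])


class TestBenjaminiHochberg:
    def test_hand_enumerated_stepup(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    @given(st.integers(0, 200))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 100))
        assert np.allclose(benjamini_hochberg(p), bh_stepup_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            benjamini_hochberg([0.5, 1.2])


class TestRunMeta:
    def test_single_study_pooled_equals_study_g(self):
        rng = np.random.default_rng(7)
        ds = make_dataset(
            {f"s{i}": rng.lognormal(5, 0.5, 20).tolist() for i in range(8)},
            ["classical"] * 4 + ["nonclassical"] * 4,
        )
        table = run_meta([ds], "classical")
        lab = ds.subset_labels()
        c = list(lab.index[lab == "classical"])
        n = list(lab.index[lab == "nonclassical"])
        for gene in ds.values.index:
            g, v = hedges_g(np.log2(ds.values.loc[gene, c]), np.log2(ds.values.loc[gene, n]))
            assert table.loc[gene, "pooled_g"] == pytest.approx(g, abs=1e-10)
            assert table.loc[gene, "se"] == pytest.approx(np.sqrt(v), abs=1e-10)

    def test_vectorized_path_matches_scalar_ops(self, small_sim_config):
        datasets, _ = simulate_sorted_studies(small_sim_config)
        from monosig.io import align_genes
        aligned, _ = align_genes(datasets, mode="union")
        table = run_meta(aligned, "classical")
        # recompute a handful of genes via the scalar route
        genes = list(table.index[:5]) + list(table.index[-3:])
        for gene in genes:
            effects = []
            for ds in aligned:
                row = ds.values.loc[gene]
                if row.isna().all():
                    continue
                lab = ds.subset_labels()
                case = np.log2(row[lab.index[lab == "classical"]].dropna())
                ctrl = np.log2(row[lab.index[lab == "nonclassical"]].dropna())
                g, v = hedges_g(case, ctrl)
                md = row[lab.index[lab == "classical"]].mean() - \
                    row[lab.index[lab == "nonclassical"]].mean()
                effects.append(StudyEffect(gene, ds.study_id, g, v, len(case), len(ctrl), md))
            expected = pool_random_effects(effects)
            assert table.loc[gene, "pooled_g"] == pytest.approx(expected.pooled_g, abs=1e-9)
            assert table.loc[gene, "se"] == pytest.approx(expected.se, abs=1e-9)
            assert table.loc[gene, "tau2"] == pytest.approx(expected.tau2, abs=1e-9)
            assert table.loc[gene, "n_studies"] == expected.n_studies
            assert table.loc[gene, "pooled_mean_diff_linear"] == pytest.approx(
                expected.pooled_mean_diff_linear, abs=1e-6
            )

    def test_planted_markers_rank_on_top(self, small_sim_config):
        datasets, truth = simulate_sorted_studies(small_sim_config)
        from monosig.io import align_genes
        aligned, _ = align_genes(datasets, mode="union")
        table = run_meta(aligned, "classical")
        top = set(table.index[: small_sim_config.n_markers_per_subset])
        planted = set(truth.marker_genes_by_subset["classical"])
        assert len(top & planted) >= small_sim_config.n_markers_per_subset - 1

    def test_min_studies_filters_low_coverage_genes(self, small_sim_config):
        datasets, _ = simulate_sorted_studies(small_sim_config)
        from monosig.io import align_genes
        aligned, _ = align_genes(datasets, mode="union")
        strict = run_meta(aligned, "classical", min_studies=small_sim_config.n_studies)
        assert (strict["n_studies"] == small_sim_config.n_studies).all()

    def test_fdr_no_smaller_than_p(self, small_sim_config):
        datasets, _ = simulate_sorted_studies(small_sim_config)
        from monosig.io import align_genes
        aligned, _ = align_genes(datasets, mode="union")
        table = run_meta(aligned, "classical")
        assert (table["fdr"] >= table["p"] - 1e-15).all()

    def test_no_eligible_study_errors(self):
        ds = make_dataset(
            {"a": [1, 2], "b": [2, 3], "c": [3, 4]},
            ["classical", "nonclassical", "nonclassical"],
        )
        with pytest.raises(InsufficientDataError):
            run_meta([ds], "classical")
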