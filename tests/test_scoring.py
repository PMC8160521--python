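import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from monosig import (
    CoverageError,
    InsufficientDataError,
    ParameterError,
    Signature,
    auroc,
    compare_groups,
    correlate_with_fractions,
    ordering_check,
    score_samples,
    score_table,
)

from conftest import make_dataset


def auroc_pair_enumeration(scores, labels):
    """Independent oracle: average over all pos-neg pairs (ties = 0.5)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


@pytest.fixture
def sig2():
    return Signature("toy_score", "classical", ["G1", "G2"])


class TestScoreSamples:
    def test_constant_gene_vector_scores_itself(self):
        sig = Signature("c10", "classical", [f"G{i}" for i in range(1, 11)])
        ds = make_dataset(
            {"a": [100.0] * 10, "b": [100.0] * 10}, ["classical", "nonclassical"]
        )
        out = score_samples(ds, sig)
        assert np.allclose(out["c10"], 100.0)

    def test_geometric_mean_of_4_and_16_is_8(self, sig2):
        ds = make_dataset({"a": [4.0, 16.0], "b": [9.0, 25.0]},
                          ["classical", "nonclassical"])
        out = score_samples(ds, sig2)
        assert out.loc["a", "toy_score"] == pytest.approx(8.0)
        assert out.loc["b", "toy_score"] == pytest.approx(15.0)

    def test_gene_order_irrelevant(self, sig2):
        ds = make_dataset({"a": [4.0, 16.0], "b": [2.0, 32.0]},
                          ["classical", "nonclassical"])
        reversed_sig = Signature("toy_score", "classical", ["G2", "G1"])
        a = score_samples(ds, sig2)["toy_score"]
        b = score_samples(ds, reversed_sig)["toy_score"]
        assert np.allclose(a, b)

    @given(c=st.floats(0.01, 1000), seed=st.integers(0, 30))
    def test_homogeneity_of_degree_one(self, c, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(2, 500, size=(4, 2))
        sig = Signature("s", "classical", [f"G{i}" for i in range(1, 5)])
        ds = make_dataset({"a": vals[:, 0].tolist(), "b": vals[:, 1].tolist()},
                          ["classical", "nonclassical"])
        scaled = make_dataset({"a": (vals[:, 0] * c).tolist(), "b": (vals[:, 1] * c).tolist()},
                              ["classical", "nonclassical"])
        base = score_samples(ds, sig)["s"].to_numpy()
        # the floor breaks exact homogeneity only below 1 unit; keep values above it
        if (vals * c).min() >= 1.0 and vals.min() >= 1.0:
            assert np.allclose(score_samples(scaled, sig)["s"].to_numpy(), base * c,
                               rtol=1e-9)

    def test_missing_genes_reduce_k(self):
        sig = Signature("s", "classical", ["G1", "G2", "GZ"])
        ds = make_dataset({"a": [4.0, 16.0], "b": [9.0, 25.0]},
                          ["classical", "nonclassical"])
        out = score_samples(ds, sig, min_coverage=0.5)
        assert out.loc["a", "s"] == pytest.approx(8.0)
        assert out.attrs["coverage"]["s"] == pytest.approx(2 / 3)

    def test_below_min_coverage_errors(self):
        sig = Signature("s", "classical", ["G1", "GX", "GY", "GZ"])
        ds = make_dataset({"a": [4.0, 16.0], "b": [9.0, 25.0]},
                          ["classical", "nonclassical"])
        with pytest.raises(CoverageError, match="coverage"):
            score_samples(ds, sig)

    def test_no_genes_present_errors(self):
        sig = Signature("s", "classical", ["GX"])
        ds = make_dataset({"a": [4.0, 16.0], "b": [9.0, 25.0]},
                          ["classical", "nonclassical"])
        with pytest.raises(CoverageError):
            score_samples(ds, sig)

    def test_case_insensitive_gene_matching(self):
        sig = Signature("s", "classical", ["g1", "g2"])
        ds = make_dataset({"a": [4.0, 16.0], "b": [9.0, 25.0]},
                          ["classical", "nonclassical"])
        assert score_samples(ds, sig).loc["a", "s"] == pytest.approx(8.0)

    def test_floor_guards_zeros(self):
        sig = Signature("s", "classical", ["G1", "G2"])
        ds = make_dataset({"a": [0.0, 16.0], "b": [9.0, 25.0]},
                          ["classical", "nonclassical"])
        out = score_samples(ds, sig, floor=1.0)
        assert out.loc["a", "s"] == pytest.approx(4.0)  # sqrt(1 * 16)

    def test_score_table_multiple_signatures(self, sig2):
        other = Signature("second", "nonclassical", ["G2"])
        ds = make_dataset({"a": [4.0, 16.0], "b": [9.0, 25.0]},
                          ["classical", "nonclassical"])
        table = score_table(ds, [sig2, other])
        assert list(table.columns[:2]) == ["toy_score", "second"]
        assert table.loc["b", "second"] == pytest.approx(25.0)


class TestAuroc:
    def test_perfect_separation(self):
        res = auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auroc == 1.0
        assert res.ci_low <= res.auroc <= res.ci_high

    def test_hand_enumerated_tied_example(self):
        res = auroc([1, 2, 2, 3], [0, 0, 1, 1])
        assert res.auroc == pytest.approx(0.875)

    def test_label_inversion_complements_auroc(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = (rng.random(30) > 0.5).astype(int)
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        a = auroc(s, y).auroc
        b = auroc(s, 1 - y).auroc
        assert a + b == pytest.approx(1.0)

    @given(seed=st.integers(0, 100))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.choice([0.5, 1.0, 2.0, 3.5, 7.0], size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[0] = 1
        if labels.sum() == n:
            labels[0] = 0
        res = auroc(scores, labels)
        assert res.auroc == pytest.approx(auroc_pair_enumeration(scores, labels), abs=1e-12)
        assert res.n_pos == labels.sum() and res.n_neg == n - labels.sum()
        assert 0.0 <= res.ci_low <= res.auroc <= res.ci_high <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            auroc([1, 2, 3], [1, 1, 1])


class TestCompareGroups:
    def test_identical_groups_wilcoxon_p_one(self):
        s = [1, 2, 3, 1, 2, 3]
        g = [0, 0, 0, 1, 1, 1]
        stat, p = compare_groups(s, g, test="wilcoxon")
        assert p == pytest.approx(1.0)

    def test_hand_computed_welch_t(self):
        s = [1, 2, 3, 11, 12, 13]
        g = ["a", "a", "a", "b", "b", "b"]
        stat, p = compare_groups(s, g, test="t")
        assert abs(stat) == pytest.approx(10 * np.sqrt(3 / 2), rel=1e-9)
        assert p < 0.01

    def test_swapping_labels_negates_t_preserves_p(self):
        s = [1.0, 2.5, 3.0, 5.0, 6.5, 9.0]
        g = np.array([0, 0, 0, 1, 1, 1])
        t1, p1 = compare_groups(s, g, test="t")
        t2, p2 = compare_groups(s, 1 - g, test="t")
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_paired_wilcoxon_runs(self):
        s = [1, 2, 3, 4, 2, 3, 4, 6]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        stat, p = compare_groups(s, g, test="wilcoxon", paired=True)
        assert 0 <= p <= 1

    def test_unknown_test_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups([1, 2, 3, 4], [0, 0, 1, 1], test="anova")

    def test_degenerate_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1, 2, 3], [0, 1, 1], test="t")


class TestCorrelation:
    def test_affine_transform_gives_r_one(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fractions = 0.1 + 0.15 * scores
        r, p = correlate_with_fractions(scores, fractions / fractions.max())
        assert r == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        r, _ = correlate_with_fractions([1, 2, 3, 4, 5], [0.5, 0.4, 0.3, 0.2, 0.1])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            correlate_with_fractions([1, 1, 1], [0.1, 0.2, 0.3])

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlate_with_fractions([1, 2], [0.1, 0.2])


class TestOrderingCheck:
    def _table(self, c, i, n):
        rows = []
        for label, vals in (("classical", c), ("intermediate", i), ("nonclassical", n)):
            rows += [{"subset": label, "cMSS": v} for v in vals]
        return pd.DataFrame(rows)

    def test_between_means_true(self):
        ok, means = ordering_check(self._table([10, 10], [6, 6], [2, 2]), "cMSS")
        assert ok is True
        assert means == {"classical": 10.0, "intermediate": 6.0, "nonclassical": 2.0}

    def test_outside_means_false(self):
        ok, _ = ordering_check(self._table([10, 10], [12, 12], [2, 2]), "cMSS")
        assert ok is False

    def test_missing_subset_errors(self):
        table = self._table([10], [6], [2])
        with pytest.raises(ParameterError):
            ordering_check(table[table["subset"] != "intermediate"], "cMSS")
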