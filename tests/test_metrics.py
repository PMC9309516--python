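"""Diversity, dissimilarity, PERMANOVA, SIMPER and PCA behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frpipe.metrics import (
    benjamini_hochberg, bray_curtis, distance_matrix, pairwise_permanova, pca,
    permanova, pielou, simper, simpson,
)

abund = st.lists(st.floats(0.01, 100), min_size=2, max_size=20)


class TestAlphaDiversity:
    def test_simpson_identities(self):
        assert simpson([7.0]) == 0.0
        assert simpson([50, 50]) == pytest.approx(0.5)
        assert simpson([10] * 10) == pytest.approx(0.9)

    def test_pielou_identities(self):
        for s in (2, 5, 11):
            assert pielou([4.2] * s) == pytest.approx(1.0)
        assert pielou([0.9, 0.1]) == pytest.approx(0.469, abs=5e-4)

    def test_pielou_single_taxon_flagged(self):
        assert math.isnan(pielou([5.0]))
        assert math.isnan(pielou([5.0, 0.0]))

    def test_zero_abundance_taxa_ignored(self):
        assert pielou([0.9, 0.1, 0.0]) == pytest.approx(pielou([0.9, 0.1]))
        assert simpson([1, 1, 0]) == pytest.approx(simpson([1, 1]))

    @given(abund)
    @settings(max_examples=50, deadline=None)
    def test_scale_and_permutation_invariance(self, p):
        assert simpson(p) == pytest.approx(simpson([x / 100 for x in p]))
        assert simpson(p) == pytest.approx(simpson(p[::-1]))
        if len([x for x in p if x > 0]) >= 2:
            assert pielou(p) == pytest.approx(pielou([x * 3 for x in p]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            simpson([0.0, 0.0])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([2, 0, 1], [0, 2, 1]) == pytest.approx(4 / 6)

    @given(abund, abund)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        d = bray_curtis(x, y)
        assert d == pytest.approx(bray_curtis(y, x))
        assert 0.0 <= d <= 1.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


def clustered_table(rng, n_per_group=4):
    # disjoint taxon supports: between-group Bray-Curtis is exactly 1
    a = np.hstack([rng.dirichlet([5, 5], n_per_group) * 100,
                   np.zeros((n_per_group, 2))])
    b = np.hstack([np.zeros((n_per_group, 2)),
                   rng.dirichlet([5, 5], n_per_group) * 100])
    table = pd.DataFrame(
        np.vstack([a, b]), columns=list("wxyz"),
        index=[f"A{i}" for i in range(n_per_group)]
        + [f"B{i}" for i in range(n_per_group)],
    )
    return table, ["A"] * n_per_group + ["B"] * n_per_group


class TestPermanova:
    def test_separated_clusters_saturate_p(self):
        # enough samples that no random permutation replays the partition
        rng = np.random.default_rng(11)
        table, groups = clustered_table(rng, n_per_group=10)
        res = permanova(distance_matrix(table), groups, n_permutations=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.pseudo_F > 1.0

    def test_identical_samples_flagged_degenerate(self):
        d = np.zeros((6, 6))
        res = permanova(d, ["A"] * 3 + ["B"] * 3, n_permutations=49, seed=0)
        assert math.isnan(res.pseudo_F) and math.isnan(res.p_value)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.dirichlet(np.ones(6), 9) * 100,
                             index=[f"s{i}" for i in range(9)])
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        dm = distance_matrix(table)
        ours = permanova(dm, groups, n_permutations=99, seed=0)
        ref = skbio_permanova(DistanceMatrix(dm.values, ids=dm.index), groups,
                              permutations=99)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permanova(np.zeros((3, 3)), ["A"] * 3)

    def test_p_floor_respected(self):
        rng = np.random.default_rng(11)
        table, groups = clustered_table(rng)
        res = permanova(distance_matrix(table), groups, n_permutations=19, seed=3)
        assert res.p_value >= 1 / 20


class TestPairwisePermanova:
    def test_three_groups_give_three_comparisons(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.dirichlet(np.ones(5), 9) * 100)
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = pairwise_permanova(distance_matrix(table), groups,
                                 n_permutations=49, seed=0)
        assert len(res) == 3
        assert {r.groups for r in res} == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_pairwise_f_matches_standalone(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(rng.dirichlet(np.ones(5), 9) * 100)
        groups = np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        dm = distance_matrix(table)
        res = pairwise_permanova(dm, groups, n_permutations=49, seed=0)
        for r in res:
            mask = np.isin(groups, r.groups)
            sub = dm.values[np.ix_(mask, mask)]
            alone = permanova(sub, groups[mask], n_permutations=49, seed=0)
            assert r.pseudo_F == pytest.approx(alone.pseudo_F)

    def test_bh_adjustment_never_below_raw(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04, 0.8])
        assert (adj >= [0.01, 0.02, 0.04, 0.8]).all()
        assert (np.diff(adj[np.argsort([0.01, 0.02, 0.04, 0.8])]) >= 0).all()


class TestSimper:
    def test_single_differing_taxon_contributes_everything(self):
        table = pd.DataFrame({
            "t1": [10, 10, 30, 30], "t2": [5, 5, 5, 5],
        }, index=list("abcd"))
        out = simper(table, ["A", "A", "B", "B"])
        t1 = out[out["taxon"] == "t1"]
        assert t1["contribution_pct"].iloc[0] == pytest.approx(100.0)

    def test_symmetric_swap_ties(self):
        table = pd.DataFrame({
            "t1": [10, 10, 0, 0], "t2": [0, 0, 10, 10], "t3": [5, 5, 5, 5],
        }, index=list("abcd"))
        out = simper(table, ["A", "A", "B", "B"]).set_index("taxon")
        assert out.loc["t1", "contribution"] == pytest.approx(
            out.loc["t2", "contribution"])

    def test_contributions_sum_to_mean_bray_curtis(self):
        rng = np.random.default_rng(21)
        table = pd.DataFrame(rng.dirichlet(np.ones(8), 9) * 100,
                             index=[f"s{i}" for i in range(9)])
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        out = simper(table, groups)
        for (ga, gb), sub in out.groupby(["group_a", "group_b"]):
            ia = [i for i, g in enumerate(groups) if g == ga]
            ib = [i for i, g in enumerate(groups) if g == gb]
            bc = np.mean([
                bray_curtis(table.iloc[i], table.iloc[j]) for i in ia for j in ib
            ])
            assert sub["contribution"].sum() == pytest.approx(bc, abs=1e-9)

    def test_empty_group_rejected(self):
        table = pd.DataFrame({"t1": [1.0, 2.0]})
        with pytest.raises(ValueError):
            simper(table, ["A", "A"])


class TestPca:
    def test_low_abundance_taxa_filtered(self):
        rng = np.random.default_rng(31)
        data = pd.DataFrame(rng.uniform(1, 10, (5, 3)), columns=["a", "b", "c"])
        data["rare"] = 0.89  # max 0.89% < threshold
        res = pca(data)
        assert "rare" not in res.loadings.index
        data["rare"] = 0.9  # exactly at threshold: kept
        assert "rare" in pca(data).loadings.index

    def test_reconstruction(self):
        rng = np.random.default_rng(32)
        data = pd.DataFrame(rng.uniform(1, 30, (6, 4)), columns=list("abcd"))
        res = pca(data)
        rebuilt = res.scores.values @ res.loadings.values.T + data.values.mean(0)
        assert np.allclose(rebuilt, data.values, atol=1e-8)

    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(33)
        table, groups = clustered_table(rng)
        res = pca(table)
        pc1 = res.scores["PC1"].values
        assert res.variance_explained[0] > 0.5
        assert (pc1[:4].mean() > pc1[4:].mean()) or (pc1[:4].mean() < pc1[4:].mean())
        lo = max(pc1[:4].max(), pc1[4:].max())
        hi = min(pc1[:4].min(), pc1[4:].min())
        # the clusters do not interleave on PC1
        assert pc1[:4].max() < pc1[4:].min() or pc1[4:].max() < pc1[:4].min()

    def test_variance_explained_sorted_and_normalised(self):
        rng = np.random.default_rng(34)
        data = pd.DataFrame(rng.uniform(1, 30, (7, 5)))
        res = pca(data)
        ve = res.variance_explained
        assert (np.diff(ve) <= 1e-12).all()
        assert ve.sum() == pytest.approx(1.0)

    def test_duplicated_samples_zero_variance_flagged(self):
        data = pd.DataFrame([[10.0, 20.0, 30.0]] * 4, columns=list("abc"))
        with pytest.raises(ValueError, match="variance"):
            pca(data)

    def test_too_few_passing_taxa_rejected(self):
        data = pd.DataFrame({"a": [10.0, 12.0], "b": [0.1, 0.2]})
        with pytest.raises(ValueError, match="taxa"):
            pca(data)
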