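"""Alpha/beta diversity, ordination, PERMANOVA and niche breadth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from wetmicro import (
    AbundanceTable,
    alpha_diversity,
    bray_curtis,
    chao1,
    levins_niche_breadth,
    pcoa,
    permanova,
    shannon,
)

counts_vectors = st.lists(st.integers(0, 50), min_size=1, max_size=30).filter(
    lambda v: sum(v) > 0)


class TestChao1:
    @pytest.mark.parametrize("counts, expected", [
        ([5, 3, 2], 3.0),                 # no singletons -> S_obs
        ([1, 1, 2, 5], 4.5),              # 4 + 2*1/(2*2)
        ([], 0.0),
        ([0, 0], 0.0),
    ])
    def test_values(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_rejects_relative_abundances(self):
        with pytest.raises(ValueError):
            chao1([0.5, 0.25, 0.25])

    @given(counts_vectors)
    @settings(max_examples=50, deadline=None)
    def test_at_least_observed_richness(self, v):
        s_obs = sum(1 for x in v if x > 0)
        est = chao1(v)
        assert est >= s_obs
        if sum(1 for x in v if x == 1) == 0:
            assert est == s_obs

    def test_matches_skbio(self):
        from skbio.diversity.alpha import chao1 as sk_chao1
        v = [1, 1, 1, 2, 2, 3, 8, 10]
        assert chao1(v) == pytest.approx(sk_chao1(v))


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon([3, 3, 3, 3]) == pytest.approx(np.log(4))

    def test_single_taxon_is_zero(self):
        assert shannon([9]) == 0.0

    def test_hand_value(self):
        assert shannon([1, 1, 2]) == pytest.approx(1.039720771)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    @given(counts_vectors)
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_log_richness(self, v):
        s_obs = sum(1 for x in v if x > 0)
        assert -1e-12 <= shannon(v) <= np.log(s_obs) + 1e-12


class TestBrayCurtis:
    def test_examples(self):
        counts = pd.DataFrame([[2, 0, 1], [1, 1, 1], [2, 0, 1], [0, 3, 0]],
                              index=list("ABCD"), columns=["t1", "t2", "t3"])
        d = bray_curtis(AbundanceTable(counts))
        assert d["A", "B"] == pytest.approx(1 / 3)
        assert d["A", "C"] == 0.0          # identical samples
        assert d["A", "D"] == 1.0          # disjoint samples

    @given(st.lists(st.lists(st.integers(0, 20), min_size=4, max_size=4)
                    .filter(lambda v: sum(v) > 0), min_size=2, max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_bounds_symmetry_zero_diagonal(self, rows):
        counts = pd.DataFrame(rows, index=[f"S{i}" for i in range(len(rows))],
                              columns=["a", "b", "c", "d"])
        d = bray_curtis(AbundanceTable(counts)).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()


class TestPcoa:
    def test_two_points(self):
        d = DistanceMatrix([[0, 2], [2, 0]], ids=["A", "B"])
        res = pcoa(d)
        assert np.sum(res.eigenvalues > 1e-10) == 1
        assert sorted(res.coordinates["PCo1"]) == pytest.approx([-1.0, 1.0])

    def test_all_zero_distances(self):
        d = DistanceMatrix(np.zeros((3, 3)), ids=list("ABC"))
        res = pcoa(d)
        assert np.allclose(res.eigenvalues, 0)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_embedding_reconstructs_distances(self):
        # 3-4-5 right triangle is exactly Euclidean-embeddable
        d = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=list("ABC"))
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    d.data[i, j], abs=1e-8)

    def test_truncation_warning(self):
        d = DistanceMatrix([[0, 2], [2, 0]], ids=["A", "B"])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            res = pcoa(d, n_axes=5)
        assert res.coordinates.shape[1] == 1

    def test_matches_skbio(self, small_table):
        from skbio.stats.ordination import pcoa as sk_pcoa
        d = bray_curtis(small_table)
        mine = pcoa(d)
        theirs = sk_pcoa(d, number_of_dimensions=2)
        # eigenvalues agree; coordinates agree up to per-axis sign
        assert mine.eigenvalues[:2] == pytest.approx(
            theirs.eigvals.to_numpy()[:2], abs=1e-10)
        for k in range(2):
            a = mine.coordinates.iloc[:, k].to_numpy()
            b = theirs.samples.iloc[:, k].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


class TestPermanova:
    def _separated_table(self, per_group=8):
        """Two groups of identical replicates on disjoint taxa."""
        a = np.zeros((per_group, 10), int); a[:, :5] = [7, 3, 5, 1, 4]
        b = np.zeros((per_group, 10), int); b[:, 5:] = [2, 8, 1, 6, 3]
        counts = pd.DataFrame(np.vstack([a, b]),
                              index=[f"S{i}" for i in range(2 * per_group)],
                              columns=[f"t{j}" for j in range(10)])
        return AbundanceTable(counts)

    def test_strong_separation_minimal_p(self):
        """Identical replicates at maximal separation: only a permutation
        that reproduces the partition could tie, which is vanishingly
        unlikely with groups of 8 — p attains its minimum."""
        d = bray_curtis(self._separated_table())
        res = permanova(d, ["A"] * 8 + ["B"] * 8, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_constant_labels_error(self):
        d = bray_curtis(self._separated_table())
        with pytest.raises(ValueError):
            permanova(d, ["A"] * 16, n_perm=99, seed=0)

    def test_singleton_group_error(self):
        d = bray_curtis(self._separated_table())
        with pytest.raises(ValueError):
            permanova(d, ["A"] * 15 + ["B"], n_perm=99, seed=0)

    def test_pseudo_f_matches_skbio(self):
        from skbio.stats.distance import permanova as sk_permanova
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(rng.poisson(8, size=(10, 12)) + 1,
                              index=[f"S{i}" for i in range(10)],
                              columns=[f"t{j}" for j in range(12)])
        d = bray_curtis(AbundanceTable(counts))
        groups = ["A"] * 5 + ["B"] * 5
        mine = permanova(d, groups, n_perm=99, seed=0)
        theirs = sk_permanova(d, grouping=groups, permutations=99)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)


class TestLevins:
    def test_uniform_taxon_maximal_breadth(self):
        counts = pd.DataFrame(np.ones((5, 1)), index=[f"S{i}" for i in range(5)],
                              columns=["t1"])
        b, _ = levins_niche_breadth(AbundanceTable(counts))
        assert b["t1"] == pytest.approx(5.0)

    def test_single_sample_taxon_minimal_breadth_and_hand_value(self):
        counts = pd.DataFrame([[4, 2], [0, 1], [0, 1]],
                              index=["S1", "S2", "S3"], columns=["t1", "t2"])
        b, bcom = levins_niche_breadth(AbundanceTable(counts))
        assert b["t1"] == pytest.approx(1.0)
        # proportions (0.5, 0.25, 0.25) -> 8/3
        assert b["t2"] == pytest.approx(8 / 3)
        # S1 community mean: weights 4/6 and 2/6
        assert bcom["S1"] == pytest.approx((4 / 6) * 1.0 + (2 / 6) * (8 / 3))

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        counts = pd.DataFrame([[4.0, 2], [1, 1], [3, 1]],
                              index=["S1", "S2", "S3"], columns=["t1", "t2"])
        b1, _ = levins_niche_breadth(AbundanceTable(counts))
        counts2 = counts.copy()
        counts2["t1"] *= scale
        b2, _ = levins_niche_breadth(AbundanceTable(counts2))
        assert b2["t1"] == pytest.approx(b1["t1"])
        assert (b1 >= 1 - 1e-12).all() and (b1 <= 3 + 1e-12).all()


def test_alpha_diversity_frame(small_table):
    div = alpha_diversity(small_table)
    assert set(div.columns) == {"observed_richness", "chao1", "shannon"}
    assert div.loc["S4", "shannon"] == pytest.approx(np.log(5))
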