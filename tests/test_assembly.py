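"""Phylogenetic null models: bMNTD, bNTI, Raup-Crick, process partition.

The small-instance oracles enumerate nearest-taxon distances (and, for
bNTI, the full permutation null) by brute force, independently of the
vectorised implementation.
"""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from wetmicro import (
    AbundanceTable,
    beta_nti,
    bmntd_matrix,
    bmntd_weighted,
    partition_processes,
    patristic_distances,
    raup_crick_bray,
)
from wetmicro.assembly import _pair_list


def brute_force_bmntd(fa, fb, d):
    """Triple-loop nearest-taxon oracle."""
    ia = [i for i, w in enumerate(fa) if w > 0]
    ib = [j for j, w in enumerate(fb) if w > 0]
    wa = np.array([fa[i] for i in ia], dtype=float)
    wb = np.array([fb[j] for j in ib], dtype=float)
    wa, wb = wa / wa.sum(), wb / wb.sum()
    term_a = sum(w * min(d[i][j] for j in ib) for w, i in zip(wa, ia))
    term_b = sum(w * min(d[i][j] for i in ia) for w, j in zip(wb, ib))
    return 0.5 * (term_a + term_b)


@pytest.fixture(scope="module")
def five_tip_tree():
    newick = "((a:1,b:1):2,((c:0.5,d:0.5):1.5,e:2):1);"
    return dendropy.Tree.get(data=newick, schema="newick")


class TestBmntd:
    def test_identical_samples_zero(self, five_tip_tree):
        d = patristic_distances(five_tip_tree).to_numpy()
        f = np.array([0.2, 0.3, 0.5, 0.0, 0.0])
        assert bmntd_weighted(f, f, d) == 0.0

    def test_single_pair(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert bmntd_weighted([1, 0], [0, 1], d) == pytest.approx(2.0)

    def test_missing_taxon_error(self, five_tip_tree):
        with pytest.raises(ValueError, match="missing"):
            patristic_distances(five_tip_tree, ["a", "b", "zz"])

    def test_brute_force_oracle_all_permutations(self, five_tip_tree):
        """Vectorised bMNTD equals the triple-loop oracle under every
        relabeling of taxa across tips (the bNTI null's moves)."""
        dist = patristic_distances(five_tip_tree).to_numpy()
        fa = np.array([0.5, 0.2, 0.3, 0.0, 0.0])
        fb = np.array([0.0, 0.0, 0.1, 0.4, 0.5])
        for perm in itertools.permutations(range(5)):
            dp = dist[np.ix_(perm, perm)]
            assert bmntd_weighted(fa, fb, dp) == pytest.approx(
                brute_force_bmntd(fa, fb, dp.tolist()), abs=1e-12)

    def test_pairwise_matrix_symmetry(self, small_table, five_tip_tree):
        dist = patristic_distances(five_tip_tree)
        dist.index = dist.columns = small_table.taxon_ids
        m = bmntd_matrix(small_table, dist=dist)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)
        assert (m.to_numpy() >= 0).all()


class TestBetaNti:
    def test_exhaustive_null_oracle(self, five_tip_tree):
        """Sampled null z-score matches the exact all-permutations null."""
        dist = patristic_distances(five_tip_tree)
        counts = pd.DataFrame([[5, 3, 2, 0, 0], [0, 0, 2, 6, 2]],
                              index=["A", "B"], columns=list(dist.index))
        table = AbundanceTable(counts)
        d = dist.to_numpy()
        fa = counts.iloc[0].to_numpy() / counts.iloc[0].sum()
        fb = counts.iloc[1].to_numpy() / counts.iloc[1].sum()
        obs = bmntd_weighted(fa, fb, d)
        exact = np.array([
            bmntd_weighted(fa, fb, d[np.ix_(p, p)])
            for p in itertools.permutations(range(5))
        ])
        z_exact = (obs - exact.mean()) / exact.std(ddof=1)
        res = beta_nti(table, dist=dist, n_null=999, seed=0)
        assert res["bnti"].iloc[0] == pytest.approx(z_exact, abs=0.25)

    def test_star_tree_degenerate_null(self):
        tree = dendropy.Tree.get(data="(a:1,b:1,c:1,d:1);", schema="newick")
        dist = patristic_distances(tree)
        counts = pd.DataFrame([[3, 1, 0, 0], [0, 0, 2, 2]],
                              index=["A", "B"], columns=list(dist.index))
        res = beta_nti(AbundanceTable(counts), dist=dist, n_null=99, seed=0)
        assert res["degenerate_null"].iloc[0]
        assert res["bnti"].iloc[0] == 0.0

    def test_seeded_reproducibility_and_relabeling_invariance(
            self, neutral_table, fixture_tree):
        sub = neutral_table.select_samples(neutral_table.sample_ids[:4])
        dist = patristic_distances(fixture_tree, sub.taxon_ids)
        a = beta_nti(sub, dist=dist, n_null=199, seed=7)
        b = beta_nti(sub, dist=dist, n_null=199, seed=7)
        pd.testing.assert_frame_equal(a, b)
        # renaming samples leaves the values untouched
        renamed = AbundanceTable(
            sub.counts.rename(index=lambda s: s + "_x"))
        c = beta_nti(renamed, dist=dist, n_null=199, seed=7)
        assert np.allclose(a["bnti"], c["bnti"])

    def test_groups_restrict_pairs(self, neutral_table):
        ids = neutral_table.sample_ids[:6]
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=ids)
        pairs = _pair_list(ids, groups)
        assert len(pairs) == 6  # 3 choose 2 per group
        assert all(groups[a] == groups[b] for a, b in pairs)


class TestRaupCrick:
    def test_identical_samples_near_minus_one(self):
        row = [10, 10, 10, 10, 10, 10]
        counts = pd.DataFrame([row, row], index=["A", "B"],
                              columns=[f"t{i}" for i in range(6)])
        res = raup_crick_bray(AbundanceTable(counts), n_null=199, seed=0)
        assert res["rc"].iloc[0] < -0.95

    def test_disjoint_samples_near_plus_one(self):
        rng = np.random.default_rng(0)
        n = 40
        a = np.zeros(n, int)
        b = np.zeros(n, int)
        a[:20] = rng.poisson(10, 20) + 1
        b[20:] = rng.poisson(10, 20) + 1
        # extra samples define a shared occurrence pool
        pool = np.vstack([rng.poisson(5, n) + 1 for _ in range(4)])
        counts = pd.DataFrame(np.vstack([a, b, pool]),
                              index=[f"S{i}" for i in range(6)],
                              columns=[f"t{j}" for j in range(n)])
        res = raup_crick_bray(AbundanceTable(counts), n_null=199, seed=0,
                              groups=pd.Series(["x", "x", "y", "y", "y", "y"],
                                               index=counts.index))
        ab = res[(res.sample_i == "S0") & (res.sample_j == "S1")]
        assert ab["rc"].iloc[0] > 0.95

    def test_single_taxon_all_ties_gives_zero(self):
        counts = pd.DataFrame([[5], [3]], index=["A", "B"], columns=["t1"])
        res = raup_crick_bray(AbundanceTable(counts), n_null=99, seed=0)
        assert res["rc"].iloc[0] == 0.0

    def test_exact_enumeration_oracle(self):
        """Two single-taxon samples on different taxa: the null picks each
        taxon with probability 1/2, so BC_null is 0 (tie impossible) or 1
        (tie with BC_obs = 1): E[RC] = 2(1/2 + 1/2 * 1/2) - 1 = 1/2."""
        counts = pd.DataFrame([[5, 0], [0, 5]], index=["A", "B"],
                              columns=["t1", "t2"])
        res = raup_crick_bray(AbundanceTable(counts), n_null=4999, seed=0)
        assert res["rc"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_bounds(self, neutral_table):
        sub = neutral_table.select_samples(neutral_table.sample_ids[:4])
        res = raup_crick_bray(sub, n_null=99, seed=1)
        assert res["rc"].between(-1, 1).all()


class TestPartition:
    def test_rule_application(self):
        bnti = pd.DataFrame({
            "sample_i": ["a", "a", "a", "b"],
            "sample_j": ["b", "c", "d", "c"],
            "bnti": [-3.0, -2.5, 0.0, 0.0],
            "degenerate_null": [False] * 4,
        })
        rc = pd.DataFrame({
            "sample_i": ["a", "b"], "sample_j": ["d", "c"],
            "rc": [0.99, 0.0],
        })
        part = partition_processes(bnti, rc)
        assert part.fractions["homogeneous_selection"] == pytest.approx(0.5)
        assert part.fractions["dispersal_limitation"] == pytest.approx(0.25)
        assert part.fractions["undominated"] == pytest.approx(0.25)
        assert sum(part.fractions.values()) == pytest.approx(1.0)

    def test_all_heterogeneous(self):
        bnti = pd.DataFrame({"sample_i": ["a"], "sample_j": ["b"],
                             "bnti": [5.0], "degenerate_null": [False]})
        part = partition_processes(bnti)
        assert part.fractions["heterogeneous_selection"] == 1.0

    def test_empty_pairs_error(self):
        with pytest.raises(ValueError):
            partition_processes(pd.DataFrame(columns=["sample_i", "sample_j", "bnti"]))

    def test_missing_rc_error(self):
        bnti = pd.DataFrame({"sample_i": ["a"], "sample_j": ["b"],
                             "bnti": [0.5], "degenerate_null": [False]})
        with pytest.raises(ValueError, match="RC"):
            partition_processes(bnti)
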