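import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from commassembly.io import CommunityMatrix
from commassembly.stegen import (
    BetaNTIResult,
    RCResult,
    beta_mntd,
    beta_nti,
    classify_processes,
    rc_bray,
)

# cross-checked against picante::comdistnt on the same matrix and tree
PICANTE_WEIGHTED = {
    ("S1", "S2"): 1.15,
    ("S1", "S3"): 0.9821428571428572,
    ("S2", "S3"): 1.0571428571428572,
}
PICANTE_UNWEIGHTED = {
    ("S1", "S2"): 7 / 6,
    ("S1", "S3"): 5 / 6,
    ("S2", "S3"): 1.0,
}


class TestBetaMNTD:
    def test_equal_weight_hand_example(self, toy_tree):
        """k={A}, l={B,C}: 0.5 * [min(2,4) + (2+4)/2] = 2.5."""
        m = CommunityMatrix(
            pd.DataFrame([[1, 0, 0], [0, 1, 1]], index=["k", "l"], columns=list("ABC"))
        )
        dm = beta_mntd(m, toy_tree, abundance_weighted=False)
        assert dm[("k", "l")] == pytest.approx(2.5, abs=1e-12)

    def test_abundance_weighted_hand_example(self, toy_tree):
        """k={A:2,C:1}, l={B:3}: 0.5 * [(2/3)*2 + (1/3)*4 + 2] = 7/3."""
        m = CommunityMatrix(
            pd.DataFrame([[2, 0, 1], [0, 3, 0]], index=["k", "l"], columns=list("ABC"))
        )
        dm = beta_mntd(m, toy_tree, abundance_weighted=True)
        assert dm[("k", "l")] == pytest.approx(7 / 3, abs=1e-12)

    @pytest.mark.parametrize(
        "weighted,expected", [(True, PICANTE_WEIGHTED), (False, PICANTE_UNWEIGHTED)]
    )
    def test_matches_picante_comdistnt(self, five_tip_matrix, five_tip_tree, weighted, expected):
        dm = beta_mntd(five_tip_matrix, five_tip_tree, abundance_weighted=weighted)
        for pair, value in expected.items():
            assert dm[pair] == pytest.approx(value, abs=1e-9)

    def test_identical_single_taxon_communities_zero(self, toy_tree):
        m = CommunityMatrix(
            pd.DataFrame([[4, 0, 0], [7, 0, 0]], index=["a", "b"], columns=list("ABC"))
        )
        assert beta_mntd(m, toy_tree)[("a", "b")] == 0.0

    def test_star_tree_disjoint_singletons(self):
        tree = TreeNode.read(["(A:3,B:3,C:3);"])
        m = CommunityMatrix(
            pd.DataFrame([[1, 0, 0], [0, 1, 0]], index=["a", "b"], columns=list("ABC"))
        )
        assert beta_mntd(m, tree)[("a", "b")] == pytest.approx(6.0, abs=1e-12)

    def test_taxa_missing_from_tree_error(self, toy_tree):
        m = CommunityMatrix(
            pd.DataFrame([[1, 1], [1, 1]], index=["a", "b"], columns=["A", "ZZZ"])
        )
        with pytest.raises(ValueError, match="missing"):
            beta_mntd(m, toy_tree)


class TestBetaNTI:
    def test_star_tree_null_is_degenerate(self):
        """Equal tip distances: every tip shuffle reproduces the observed
        value, so the standardized score is undefined (NaN)."""
        tree = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        m = CommunityMatrix(
            pd.DataFrame(
                [[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]],
                index=["a", "b", "c"],
                columns=list("ABCD"),
            )
        )
        res = beta_nti(m, tree, n_null=99, seed=0)
        assert res.n_undefined_pairs == 3
        assert np.isnan(res.bnti[0, 1])

    def test_deterministic_given_seed(self, five_tip_matrix, five_tip_tree):
        a = beta_nti(five_tip_matrix, five_tip_tree, n_null=99, seed=5).bnti
        b = beta_nti(five_tip_matrix, five_tip_tree, n_null=99, seed=5).bnti
        np.testing.assert_array_equal(a, b)

    def test_rejects_too_few_nulls(self, five_tip_matrix, five_tip_tree):
        with pytest.raises(ValueError):
            beta_nti(five_tip_matrix, five_tip_tree, n_null=10, seed=0)

    def test_label_shuffled_data_centres_near_zero(self):
        """When community assembly ignores the phylogeny, βNTI over pairs
        should centre near 0 with spread near 1."""
        rng = np.random.default_rng(4)
        from commassembly.synth import simulate_yule_tree

        tree = simulate_yule_tree(40, seed=11)
        X = rng.integers(0, 30, size=(12, 40))
        X[:, 0] += 1
        m = CommunityMatrix(
            pd.DataFrame(X, index=[f"s{i}" for i in range(12)],
                         columns=[f"OTU_{k}" for k in range(1, 41)])
        )
        res = beta_nti(m, tree, n_null=299, seed=1)
        vals = res.bnti[np.triu_indices(12, 1)]
        vals = vals[~np.isnan(vals)]
        assert abs(vals.mean()) < 0.5
        assert 0.4 < vals.std() < 2.0


class TestRCBray:
    def test_boundaries_and_symmetry(self):
        """Identical rich samples are closer than probabilistic nulls (-1);
        the RC matrix is symmetric and bounded."""
        rng = np.random.default_rng(0)
        base = rng.multinomial(400, np.ones(30) / 30)
        X = np.vstack([base, base, rng.multinomial(400, np.ones(30) / 30)])
        m = CommunityMatrix(
            pd.DataFrame(X, index=["a", "b", "c"], columns=[f"t{i}" for i in range(30)])
        )
        res = rc_bray(m, n_null=199, seed=3)
        assert res.rc[0, 1] == -1.0
        assert np.allclose(res.rc, res.rc.T)
        assert (res.rc >= -1).all() and (res.rc <= 1).all()

    def test_antisymmetric_response_to_extreme_observations(self):
        """Pushing the observed dissimilarity beyond every null flips the
        sign of RC."""
        rng = np.random.default_rng(1)
        X = rng.multinomial(300, np.ones(20) / 20, size=4)
        m = CommunityMatrix(
            pd.DataFrame(X, index=list("abcd"), columns=[f"t{i}" for i in range(20)])
        )
        res = rc_bray(m, n_null=99, seed=2)
        # all samples are draws from one even pool: no pair should sit at +1
        iu = np.triu_indices(4, 1)
        assert (res.rc[iu] < 1.0).all()


class TestClassification:
    @pytest.mark.parametrize(
        "bnti,rc,label",
        [
            (2.5, 0.0, "variable_selection"),
            (-2.5, 0.0, "homogeneous_selection"),
            (-1.0, -0.97, "homogenizing_dispersal"),
            (1.0, 0.97, "dispersal_limitation"),
            (0.5, 0.2, "undominated"),
            (2.0, 0.0, "undominated"),   # thresholds are strict
            (0.0, 0.95, "undominated"),
        ],
    )
    def test_threshold_rules(self, bnti, rc, label):
        b = np.array([[np.nan, bnti], [bnti, np.nan]])
        r = np.array([[0.0, rc], [rc, 0.0]])
        bres = BetaNTIResult(sample_ids=["x", "y"], observed=np.zeros((2, 2)), bnti=b, n_null=999)
        rres = RCResult(sample_ids=["x", "y"], rc=r, n_null=999)
        summary = classify_processes(bres, rres)
        assert summary.pairs["label"].iloc[0] == label
        assert summary.fractions[label] == 1.0

    def test_fractions_sum_to_one_and_undefined_excluded(self):
        bnti = np.full((4, 4), np.nan)
        vals = {(0, 1): 3.0, (0, 2): -3.0, (0, 3): 0.0, (1, 2): 1.0, (1, 3): np.nan, (2, 3): 0.1}
        rc = np.zeros((4, 4))
        rc[0, 3] = rc[3, 0] = 0.99
        rc[2, 3] = rc[3, 2] = -0.99
        for (i, j), v in vals.items():
            bnti[i, j] = bnti[j, i] = v
        bres = BetaNTIResult(sample_ids=list("wxyz"), observed=np.zeros((4, 4)), bnti=bnti, n_null=999)
        rres = RCResult(sample_ids=list("wxyz"), rc=rc, n_null=999)
        summary = classify_processes(bres, rres)
        assert summary.n_undefined == 1
        assert summary.n_pairs == 5
        assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        counts = summary.pairs["label"].value_counts()
        assert counts["undefined"] == 1
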