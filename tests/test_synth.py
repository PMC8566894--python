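import numpy as np
import pytest

from commassembly.diversity import pairwise_dissimilarity
from commassembly.synth import (
    SimulationConfig,
    build_metacommunity,
    simulate_bm_trait,
    simulate_dataset,
    simulate_neutral_community,
    simulate_selected_community,
    simulate_yule_tree,
)


class TestYuleTree:
    def test_smallest_tree_is_a_cherry(self):
        tree = simulate_yule_tree(2, seed=0)
        assert len(list(tree.tips())) == 2
        assert all(t.length > 0 for t in tree.tips())

    def test_same_seed_same_newick(self):
        assert str(simulate_yule_tree(20, seed=5)) == str(simulate_yule_tree(20, seed=5))
        assert str(simulate_yule_tree(20, seed=5)) != str(simulate_yule_tree(20, seed=6))

    def test_binary_internal_node_count(self):
        tree = simulate_yule_tree(100, seed=1)
        internal = [n for n in tree.non_tips(include_self=True)]
        assert len(internal) == 99
        assert all(len(n.children) == 2 for n in internal)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, seed=0)


class TestBMTrait:
    def test_zero_variance_limit(self):
        tree = simulate_yule_tree(10, seed=3)
        tr = simulate_bm_trait(tree, sigma2=1e-18, root=7.0, seed=1)
        assert np.allclose(tr.values, 7.0, atol=1e-6)

    def test_cherry_contrast_variance(self):
        """Var(t_A - t_B) on a cherry with equal branches b is 2*sigma2*b."""
        from skbio import TreeNode

        tree = TreeNode.read(["(A:0.5,B:0.5);"])
        sigma2 = 2.0
        diffs = np.array(
            [np.diff(simulate_bm_trait(tree, sigma2, 0.0, seed=k).values)[0] for k in range(5000)]
        )
        assert diffs.var() == pytest.approx(2 * sigma2 * 0.5, rel=0.1)

    def test_sister_tips_covary_more_than_distant(self):
        from skbio import TreeNode

        tree = TreeNode.read(["((A:1,B:1):3,C:4);"])
        vals = np.array([simulate_bm_trait(tree, 1.0, 0.0, seed=k).values for k in range(3000)])
        cov = np.cov(vals.T)
        assert cov[0, 1] > cov[0, 2] + 1.0  # shared path 3 vs 0

    def test_invalid_sigma(self):
        tree = simulate_yule_tree(4, seed=0)
        with pytest.raises(ValueError):
            simulate_bm_trait(tree, sigma2=0.0)


class TestMetacommunity:
    def test_even_limit_and_normalisation(self):
        meta = build_metacommunity(10, lognormal_sigma=0.0, seed=0)
        assert np.allclose(meta.abundances, 0.1)
        meta2 = build_metacommunity(50, lognormal_sigma=2.0, seed=1)
        assert meta2.abundances.sum() == pytest.approx(1.0, abs=1e-12)

    def test_skew_increases_with_sigma(self):
        def gini(x):
            x = np.sort(x)
            n = x.size
            return (2 * np.arange(1, n + 1) - n - 1) @ x / (n * x.sum())

        ginis = []
        for sigma in (0.5, 1.5, 3.0):
            g = [gini(build_metacommunity(100, sigma, seed=k).abundances) for k in range(100)]
            ginis.append(np.mean(g))
        assert ginis[0] < ginis[1] < ginis[2]


class TestNeutralCommunity:
    def test_counts_conserved(self):
        meta = build_metacommunity(20, 1.0, seed=0)
        c = simulate_neutral_community(meta, N=500, m=0.4, generations=5, seed=1)
        assert c.sum() == 500
        assert (c >= 0).all()

    def test_full_immigration_matches_metacommunity(self):
        """At m=1 every replacement is a metacommunity draw: stationary counts
        are multinomial, so per-taxon means approach N * gamma."""
        meta = build_metacommunity(10, 1.0, seed=2)
        N = 200
        reps = np.array(
            [simulate_neutral_community(meta, N, 1.0, generations=3, seed=k) for k in range(1000)]
        )
        expect = N * meta.abundances
        sd_mean = np.sqrt(N * meta.abundances * (1 - meta.abundances)) / np.sqrt(1000)
        assert (np.abs(reps.mean(axis=0) - expect) < 5 * sd_mean + 0.2).all()

    def test_zero_immigration_drifts_to_fixation(self):
        meta = build_metacommunity(5, 0.5, seed=3)
        mono = 0
        for k in range(30):
            c = simulate_neutral_community(meta, N=50, m=0.0, generations=200, seed=k)
            mono += (c > 0).sum() == 1
        assert mono >= 27

    def test_invalid_m(self):
        meta = build_metacommunity(5, 0.5, seed=0)
        with pytest.raises(ValueError):
            simulate_neutral_community(meta, 100, m=1.5)


class TestSelectedCommunity:
    def test_wide_niche_reduces_to_metacommunity(self):
        meta = build_metacommunity(10, 1.0, seed=4)
        tree = simulate_yule_tree(10, seed=4)
        traits = simulate_bm_trait(tree, 1.0, 0.0, seed=4)
        reps = np.array(
            [
                simulate_selected_community(meta, traits, env=0.0, sigma_w=1e6, N=300, seed=k)
                for k in range(500)
            ]
        )
        assert np.allclose(reps.mean(axis=0) / 300, meta.abundances, atol=0.02)

    def test_delta_filter_limit(self):
        meta = build_metacommunity(5, 0.5, seed=5)
        traits_vals = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        from commassembly.synth import NicheTraits

        traits = NicheTraits(meta.taxon_ids, traits_vals)
        c = simulate_selected_community(meta, traits, env=10.0, sigma_w=0.01, N=200, seed=0)
        assert c[2] == 200

    def test_underflow_error(self):
        meta = build_metacommunity(3, 0.5, seed=6)
        from commassembly.synth import NicheTraits

        traits = NicheTraits(meta.taxon_ids, np.array([1e4, 1e4, 1e4]))
        with pytest.raises(ValueError, match="sigma_w"):
            simulate_selected_community(meta, traits, env=0.0, sigma_w=1.0, N=100, seed=0)

    def test_environmental_contrast_beats_within_group_turnover(self):
        meta = build_metacommunity(30, 1.0, seed=7)
        tree = simulate_yule_tree(30, seed=7)
        traits = simulate_bm_trait(tree, 1.0, 0.0, seed=7)
        lo, hi = np.percentile(traits.values, [20, 80])
        between, within = [], []
        for k in range(100):
            a = simulate_selected_community(meta, traits, lo, 0.3, 500, seed=2 * k)
            b = simulate_selected_community(meta, traits, hi, 0.3, 500, seed=2 * k + 1)
            a2 = simulate_selected_community(meta, traits, lo, 0.3, 500, seed=10_000 + k)
            d = pairwise_dissimilarity(np.vstack([a, b, a2]), "bray")
            between.append(d[0, 1])
            within.append(d[0, 2])
        assert np.mean(between) > np.mean(within)


class TestSimulateDataset:
    def test_row_sums_equal_depth_and_regimes_recorded(self):
        cfg = SimulationConfig(regime="mixed", n_samples=10, n_taxa=30, depth=400, seed=0)
        ds = simulate_dataset(cfg)
        assert (ds.matrix.counts.sum(axis=1) == 400).all()
        assert set(ds.sample_regime) == {"neutral", "homogeneous_selection"}
        assert len(ds.sample_regime) == 10

    def test_same_config_same_bytes(self, tmp_path):
        cfg = SimulationConfig(regime="neutral", n_samples=6, n_taxa=20, depth=200, seed=3)
        for sub in ("a", "b"):
            simulate_dataset(cfg).write(tmp_path / sub)
        for name in ("otu_table.tsv", "tree.nwk", "metadata.csv", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError, match="regime"):
            SimulationConfig(regime="anarchy")

    def test_variable_selection_needs_two_groups(self):
        cfg = SimulationConfig(regime="variable_selection", n_samples=3, n_taxa=10, seed=0)
        with pytest.raises(ValueError, match="two groups"):
            simulate_dataset(cfg)
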