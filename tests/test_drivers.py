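import networkx as nx
import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from commassembly.drivers import (
    correlation_network,
    mantel,
    node_topology,
    permanova,
    subnetwork,
)
from commassembly.io import CommunityMatrix


def _random_dm(rng, n, ids=None):
    x = rng.random((n, 2))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(n)])


class TestMantel:
    def test_perfect_monotone_hits_floor(self):
        rng = np.random.default_rng(0)
        d1 = _random_dm(rng, 10)
        d2 = DistanceMatrix(2.0 * d1.data, ids=d1.ids)
        r, p = mantel(d1, d2, method="spearman", n_perm=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_constant_matrix_errors(self):
        rng = np.random.default_rng(1)
        d1 = _random_dm(rng, 6)
        flat = np.ones((6, 6)) - np.eye(6)
        d2 = DistanceMatrix(flat, ids=d1.ids)
        with pytest.raises(ValueError, match="zero variance"):
            mantel(d1, d2)

    def test_mismatched_ids_error(self):
        rng = np.random.default_rng(2)
        d1 = _random_dm(rng, 5)
        d2 = _random_dm(rng, 5, ids=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError, match="different samples"):
            mantel(d1, d2)


class TestPermanova:
    def test_perfect_separation_hits_floor(self):
        # two tight, far-apart clusters of 9 and 7 samples
        rng = np.random.default_rng(3)
        n1, n2 = 9, 7
        pts = np.vstack([rng.normal(0, 0.01, (n1, 2)), rng.normal(100, 0.01, (n2, 2))])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(axis=2))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n1 + n2)])
        groups = ["a"] * n1 + ["b"] * n2
        f, p = permanova(dm, groups, n_perm=99, seed=4)
        assert f > 100
        assert p == pytest.approx(1 / 100)

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(5)
        dm = _random_dm(rng, 5)
        with pytest.raises(ValueError, match="singleton"):
            permanova(dm, ["a", "a", "a", "a", "b"])

    def test_accepts_series_grouping(self):
        rng = np.random.default_rng(6)
        dm = _random_dm(rng, 8)
        groups = pd.Series(["a", "b"] * 4, index=dm.ids)
        f, p = permanova(dm, groups, n_perm=99, seed=7)
        assert np.isfinite(f) and 0 < p <= 1


class TestCorrelationNetwork:
    def _matrix(self, X):
        return CommunityMatrix(
            pd.DataFrame(
                X, index=[f"s{i}" for i in range(X.shape[0])],
                columns=[f"t{j}" for j in range(X.shape[1])],
            )
        )

    def test_perfectly_correlated_and_anticorrelated_taxa(self):
        up = np.arange(1, 9)
        X = np.column_stack([up * 10, up * 3 + 1, up[::-1] * 5])
        net = correlation_network(self._matrix(X), min_reads=0)
        assert net.has_edge("t0", "t1")
        assert net["t0"]["t1"]["r"] == pytest.approx(1.0)
        assert net["t0"]["t2"]["sign"] == "negative"
        assert net["t0"]["t2"]["r"] == pytest.approx(-1.0)

    def test_every_edge_satisfies_both_thresholds(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 40, size=(20, 25))
        env = pd.DataFrame(
            {"temperature": rng.normal(25, 2, 20), "salinity": rng.normal(34, 1, 20)},
            index=[f"s{i}" for i in range(20)],
        )
        net = correlation_network(self._matrix(X), env, r_threshold=0.4, p_threshold=0.1, min_reads=5)
        for _, _, d in net.edges(data=True):
            assert abs(d["r"]) > 0.4
            assert d["p"] < 0.1

    def test_low_count_taxa_excluded(self):
        rng = np.random.default_rng(9)
        X = rng.integers(2, 10, size=(10, 4))
        X[:, 3] = 0
        X[0, 3] = 1  # total 1 <= min_reads
        net = correlation_network(self._matrix(X), min_reads=10)
        assert "t3" not in net.nodes

    def test_env_nodes_typed(self):
        rng = np.random.default_rng(10)
        X = rng.integers(1, 50, size=(12, 6))
        env = pd.DataFrame({"temperature": rng.normal(size=12)}, index=[f"s{i}" for i in range(12)])
        net = correlation_network(self._matrix(X), env, min_reads=0)
        assert net.nodes["temperature"]["kind"] == "env"
        assert net.nodes["t0"]["kind"] == "taxon"


class TestTopology:
    def test_path_graph_betweenness(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        t = node_topology(g)
        assert t.loc["B", "degree"] == 2
        assert t.loc["B", "betweenness"] == pytest.approx(1.0)
        assert t.loc["A", "degree"] == 1

    def test_complete_graph_symmetry(self):
        g = nx.complete_graph(4)
        t = node_topology(g)
        assert (t["betweenness"] == 0).all()
        assert (t["degree"] == 3).all()

    def test_star_centre_has_maximal_eigenvector(self):
        g = nx.star_graph(4)  # node 0 is the centre
        t = node_topology(g)
        assert t.loc[0, "eigenvector"] == t["eigenvector"].max()

    def test_relabelling_invariance(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        t1 = node_topology(g)
        mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        t2 = node_topology(nx.relabel_nodes(g, mapping))
        for old, new in mapping.items():
            for col in ("degree", "betweenness", "closeness"):
                assert t1.loc[old, col] == pytest.approx(t2.loc[new, col])


class TestSubnetwork:
    def test_identity_induced_and_empty(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "A")])
        assert set(subnetwork(g, ["A", "B", "C"]).edges) == set(g.edges)
        sub = subnetwork(g, ["A", "B"])
        assert list(sub.edges) == [("A", "B")]
        assert subnetwork(g, []).number_of_nodes() == 0

    def test_unknown_nodes_rejected(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(ValueError, match="unknown node"):
            subnetwork(g, ["A", "Q"])
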