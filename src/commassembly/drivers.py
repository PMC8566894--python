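"""Deterministic-driver statistics: Mantel, PERMANOVA, co-occurrence network.

The Mantel test correlates community dissimilarity with environmental
distance; PERMANOVA partitions distance-matrix variance between sample
groups.  Both are permutation tests delegated to scikit-bio and honour the
permutation-p floor 1/(n_perm + 1).

The co-occurrence network connects taxa (total count above ``min_reads``)
and environmental variables by Spearman rank correlation, keeping only
robust (|r| > 0.5) and significant (p < 0.05) edges by default; node-level
topology (degree, betweenness, closeness, eigenvector centrality) is
computed on the resulting undirected, unweighted graph.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.distance import permanova as _skbio_permanova

from .io import CommunityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "mantel",
    "permanova",
    "correlation_network",
    "node_topology",
    "subnetwork",
]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed=None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Returns (r, p).  The null permutes rows/columns of one matrix
    simultaneously; significance is two-sided on |r| with
    ``p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_perm)``.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices cover different samples")
    d2 = d2.filter(d1.ids)
    for d, name in ((d1, "d1"), (d2, "d2")):
        if np.ptp(d.condensed_form()) == 0:
            raise ValueError(f"{name} has zero variance; Mantel r undefined")
    r, p, _ = _skbio_mantel(
        d1, d2, method=method, permutations=n_perm, alternative="two-sided",
        seed=_to_seed(seed),
    )
    return float(r), float(p)


def permanova(
    d: DistanceMatrix, groups, n_perm: int = 9999, seed=None
) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F and permutation p for a grouping.

    ``groups`` is a sequence aligned with ``d.ids`` or a mapping/Series
    from sample id to label.  Each group needs at least 2 samples.
    """
    if isinstance(groups, (dict, pd.Series)):
        grouping = [groups[i] for i in d.ids]
    else:
        grouping = list(groups)
    if len(grouping) != len(d.ids):
        raise ValueError("grouping length does not match distance matrix")
    sizes = pd.Series(grouping).value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        raise ValueError(f"singleton group(s): {sizes[sizes < 2].index.tolist()}")
    res = _skbio_permanova(d, grouping, permutations=n_perm, seed=_to_seed(seed))
    return float(res["test statistic"]), float(res["p-value"])


def _to_seed(seed):
    if seed is None or isinstance(seed, (int, np.integer)):
        return seed
    return np.random.default_rng(seed)


def correlation_network(
    m: CommunityMatrix,
    env: pd.DataFrame | None = None,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
    min_reads: int = 10,
    use_relative: bool = False,
    fdr: bool = False,
) -> nx.Graph:
    """Thresholded Spearman co-occurrence network of taxa and environment.

    Taxa with total count <= ``min_reads`` are excluded.  All taxon-taxon
    and taxon-environment pairs are tested; an edge is kept when
    |r| > ``r_threshold`` and p < ``p_threshold`` (two-sided
    t-approximation; raw p-values by default, Benjamini-Hochberg adjusted
    when ``fdr`` is on — note the raw rule inflates the spurious-edge rate
    over many pairs).  Constant profiles are skipped with a warning.
    """
    if m.shape[0] < 5:
        raise ValueError("need at least 5 samples for a correlation network")
    totals = m.counts.sum(axis=0)
    keep = totals > min_reads
    taxa = [t for t, k in zip(m.taxon_ids, keep) if k]
    X = m.relative_abundance()[:, keep] if use_relative else m.counts[:, keep].astype(float)
    cols = list(taxa)
    kinds = {t: "taxon" for t in taxa}
    blocks = [X]
    if env is not None:
        env = env.reindex(m.sample_ids)
        num = env.select_dtypes(include=[np.number])
        blocks.append(num.to_numpy(dtype=float))
        cols += list(num.columns)
        kinds.update({c: "env" for c in num.columns})
    data = np.column_stack(blocks)

    const = np.nanstd(data, axis=0) == 0
    if const.any():
        skipped = [c for c, f in zip(cols, const) if f]
        logger.warning("skipping %d constant profile(s): %s", len(skipped), skipped[:5])
    ok = ~const
    data, cols = data[:, ok], [c for c, f in zip(cols, ok) if f]

    rho, pval = stats.spearmanr(data, nan_policy="omit")
    rho, pval = np.atleast_2d(rho), np.atleast_2d(pval)
    iu = np.triu_indices(len(cols), k=1)
    if fdr:
        flat = pval[iu]
        adj = stats.false_discovery_control(flat, method="bh")
        pval = pval.copy()
        pval[iu] = adj
        pval.T[iu] = adj

    g = nx.Graph(r_threshold=r_threshold, p_threshold=p_threshold, fdr=fdr)
    for c in cols:
        g.add_node(c, kind=kinds[c])
    for i, j in zip(*iu):
        r, p = rho[i, j], pval[i, j]
        if np.isfinite(r) and abs(r) > r_threshold and p < p_threshold:
            g.add_edge(
                cols[i], cols[j], r=float(r), p=float(p),
                sign="positive" if r > 0 else "negative",
            )
    return g


def node_topology(net: nx.Graph, normalized_betweenness: bool = False) -> pd.DataFrame:
    """Node-level topology of a (sub)network.

    Degree, shortest-path betweenness (unnormalized by default), closeness
    and eigenvector centrality; the latter two are computed within
    connected components.  Isolated nodes get zero centralities.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    betw = nx.betweenness_centrality(net, normalized=normalized_betweenness)
    close = nx.closeness_centrality(net)
    eig: dict = {}
    for comp in nx.connected_components(net):
        if len(comp) == 1:
            eig[next(iter(comp))] = 0.0
        elif len(comp) == 2:
            # principal eigenvector of a single edge: equal weight
            eig.update({n: 1.0 / np.sqrt(2.0) for n in comp})
        else:
            eig.update(nx.eigenvector_centrality_numpy(net.subgraph(comp)))
    rows = {
        n: {
            "degree": net.degree(n),
            "betweenness": betw[n],
            "closeness": close[n],
            "eigenvector": abs(eig[n]),
            "kind": net.nodes[n].get("kind", "taxon"),
        }
        for n in net.nodes
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "node"
    return df


def subnetwork(net: nx.Graph, node_subset) -> nx.Graph:
    """Induced subgraph on ``node_subset`` (edges with both ends inside)."""
    node_subset = list(node_subset)
    unknown = [n for n in node_subset if n not in net]
    if unknown:
        raise ValueError(f"unknown node ids: {unknown[:5]}")
    sub = net.subgraph(node_subset).copy()
    sub.graph.update(net.graph)
    return sub
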