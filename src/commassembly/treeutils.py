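"""Small phylogeny helpers shared by the null-model and signal modules."""

from __future__ import annotations

import logging

import numpy as np
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = ["patristic_matrix", "vcv_matrix", "check_taxa_on_tree"]


def check_taxa_on_tree(tree: TreeNode, taxa) -> list[str]:
    """Return the subset of ``taxa`` present as tips; raise if none are."""
    tips = {t.name for t in tree.tips()}
    present = [t for t in taxa if t in tips]
    missing = [t for t in taxa if t not in tips]
    if missing:
        logger.warning("%d taxa absent from the tree (e.g. %r)", len(missing), missing[0])
    if not present:
        raise ValueError("no taxa map to tree tips")
    return present


def patristic_matrix(tree: TreeNode, taxa) -> np.ndarray:
    """Pairwise patristic (sum of branch lengths) distances for ``taxa``.

    Every taxon must be a tip of the tree.
    """
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:5]}")
    dm = tree.tip_tip_distances(endpoints=list(taxa))
    # reorder to the requested taxon order
    idx = [dm.index(t) for t in taxa]
    return dm.data[np.ix_(idx, idx)]


def vcv_matrix(tree: TreeNode, taxa) -> np.ndarray:
    """Brownian-motion tip covariance matrix.

    ``V[i, j]`` is the shared root-to-tip branch length of tips i and j;
    the diagonal holds each tip's total root-to-tip depth.
    """
    taxa = list(taxa)
    depth = {}
    for tip in tree.tips():
        d = 0.0
        node = tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depth[tip.name] = d
    missing = [t for t in taxa if t not in depth]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:5]}")
    D = patristic_matrix(tree, taxa)
    root_depth = np.array([depth[t] for t in taxa])
    V = 0.5 * (root_depth[:, None] + root_depth[None, :] - D)
    # guard tiny negative round-off on distant pairs
    return np.maximum(V, 0.0)
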