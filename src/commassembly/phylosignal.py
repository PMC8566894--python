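"""Phylogenetic signal of taxon environmental responses (Blomberg's K).

A taxon's "environmental response" is summarised as its abundance-weighted
mean environment (niche value).  Blomberg's K compares the trait variance
across tips with the variance expected under Brownian motion on the given
tree: K = 1 matches Brownian evolution, K -> 0 no signal, K > 1 stronger
clustering than Brownian.  Significance is assessed by the variance of
phylogenetically independent contrasts (PIC) against a null that reshuffles
trait values across tips: signal makes contrasts *less* variable than the
null (one-sided test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import CommunityMatrix
from .synth import NicheTraits
from .treeutils import vcv_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SignalResult",
    "taxon_niche_values",
    "blomberg_k",
    "pic_variance",
    "k_significance",
]


def taxon_niche_values(
    m: CommunityMatrix, env: pd.DataFrame, variable: str
) -> NicheTraits:
    """Abundance-weighted mean environment per taxon.

    ``t_i = sum_s (x_is / sum_s' x_is') * env_s`` — the taxon's read
    distribution across samples weights the samples' environmental values.
    Samples with missing values are dropped; taxa with zero total count
    over the remaining samples are excluded.
    """
    if variable not in env.columns:
        raise ValueError(f"variable {variable!r} not in environment table")
    vals = pd.to_numeric(env[variable], errors="coerce")
    vals = vals.reindex(m.sample_ids)
    ok = vals.notna().to_numpy()
    if ok.sum() < 3:
        raise ValueError(f"variable {variable!r} has fewer than 3 non-missing samples")
    x = m.counts[ok].astype(float)
    e = vals.to_numpy()[ok]
    totals = x.sum(axis=0)
    keep = totals > 0
    if (~keep).any():
        logger.info("excluding %d taxa with zero total count", int((~keep).sum()))
    w = x[:, keep] / totals[keep]
    t = w.T @ e
    taxa = [tid for tid, k in zip(m.taxon_ids, keep) if k]
    return NicheTraits(taxa, t)


def _match_tree(tree: TreeNode, traits: NicheTraits):
    tips = {t.name for t in tree.tips()}
    keep = [i for i, t in enumerate(traits.taxon_ids) if t in tips]
    dropped = len(traits.taxon_ids) - len(keep)
    if dropped:
        logger.warning("dropping %d taxa absent from the tree", dropped)
    taxa = [traits.taxon_ids[i] for i in keep]
    y = traits.values[keep]
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa on the tree")
    sub = tree.shear(taxa)
    return sub, taxa, y


def blomberg_k(tree: TreeNode, traits: NicheTraits) -> float:
    """Blomberg's K for a continuous trait on a rooted tree.

    With V the Brownian tip covariance matrix and a-hat the GLS root state,
    K is the ratio of the observed MSE0/MSE to its Brownian expectation
    ``(tr(V) - n / sum(V^-1)) / (n - 1)``.  A constant trait returns 0
    with a warning.
    """
    sub, taxa, y = _match_tree(tree, traits)
    n = len(taxa)
    if np.ptp(y) == 0:
        logger.warning("constant trait: K set to 0")
        return 0.0
    V = vcv_matrix(sub, taxa)
    ones = np.ones(n)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, ones)
    denom_1V1 = ones @ Vinv_1
    a_hat = (ones @ Vinv_y) / denom_1V1
    resid = y - a_hat
    mse0 = (resid @ resid) / (n - 1)
    if mse0 == 0.0:
        logger.warning("constant trait: K set to 0")
        return 0.0
    mse = (resid @ np.linalg.solve(V, resid)) / (n - 1)
    expected = (np.trace(V) - n / denom_1V1) / (n - 1)
    return float((mse0 / mse) / expected)


def pic_variance(tree: TreeNode, taxa: list[str], Y: np.ndarray) -> np.ndarray:
    """Variance of phylogenetically independent contrasts.

    ``Y`` is (n_tips, n_sets); a variance is returned per column, so many
    permuted trait vectors can be pruned in one pass.  Requires a fully
    bifurcating tree.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != len(taxa):
        Y = Y.T
    order = {t: i for i, t in enumerate(taxa)}
    vals: dict[int, np.ndarray] = {}
    lens: dict[int, float] = {}
    contrasts = []
    for node in tree.postorder():
        if node.is_tip():
            vals[id(node)] = Y[order[node.name]]
            lens[id(node)] = max(node.length or 0.0, 1e-12)
            continue
        children = node.children
        if len(children) != 2:
            raise ValueError("PIC requires a fully bifurcating tree")
        c1, c2 = children
        x1, x2 = vals.pop(id(c1)), vals.pop(id(c2))
        b1, b2 = lens.pop(id(c1)), lens.pop(id(c2))
        contrasts.append((x1 - x2) / np.sqrt(b1 + b2))
        vals[id(node)] = (x1 / b1 + x2 / b2) / (1.0 / b1 + 1.0 / b2)
        lens[id(node)] = max(node.length or 0.0, 0.0) + b1 * b2 / (b1 + b2)
    C = np.asarray(contrasts)  # (n-1, n_sets)
    return C.var(axis=0, ddof=1)


@dataclass
class SignalResult:
    """Blomberg's K with its permutation p-value."""

    k: float
    p_value: float
    n_perm: int
    trait: str
    n_tips: int
    pic_var_obs: float


def k_significance(
    tree: TreeNode,
    traits: NicheTraits,
    n_perm: int = 999,
    seed=None,
    trait_name: str = "trait",
) -> SignalResult:
    """Tip-reshuffling significance test for phylogenetic signal.

    The statistic is the PIC variance; the p-value is the fraction of
    reshuffles whose PIC variance is at most the observed one,
    ``p = (1 + #{null <= obs}) / (1 + n_perm)``.
    """
    sub, taxa, y = _match_tree(tree, traits)
    k = blomberg_k(tree, traits)
    rng = np.random.default_rng(seed)
    n = len(taxa)
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = y[rng.permutation(n)]
    obs = float(pic_variance(sub, taxa, y[:, None])[0])
    null = pic_variance(sub, taxa, perms)
    p = (1 + int((null <= obs).sum())) / (1 + n_perm)
    return SignalResult(
        k=k, p_value=float(p), n_perm=n_perm, trait=trait_name, n_tips=n,
        pic_var_obs=obs,
    )
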