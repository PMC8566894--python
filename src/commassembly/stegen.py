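"""Phylogenetic and taxonomic null models for assembly-process inference.

βMNTD (between-sample mean nearest-taxon distance) measures phylogenetic
turnover; βNTI standardizes it against a null that shuffles taxon labels
across the tips of the regional phylogeny (999 randomizations by default).
|βNTI| > 2 indicates selection — variable selection when observed turnover
exceeds the null (βNTI > +2), homogeneous selection when it falls short
(βNTI < -2).  For pairs without strong selection, the abundance-based
Raup-Crick metric RC_Bray compares the observed Bray-Curtis dissimilarity
with a distribution of probabilistically assembled null communities,
rescaled to [-1, +1]: RC > +0.95 indicates dispersal limitation, RC < -0.95
homogenizing dispersal, and the remainder "undominated" processes (weak
selection, weak dispersal, drift, diversification).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .io import CommunityMatrix
from .nst import _null_matrices
from .treeutils import patristic_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "BetaNTIResult",
    "RCResult",
    "ProcessSummary",
    "beta_mntd",
    "beta_nti",
    "rc_bray",
    "classify_processes",
    "PROCESS_LABELS",
]

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


def _weights_and_presence(counts: np.ndarray, abundance_weighted: bool):
    present = counts > 0
    if not present.any(axis=1).all():
        empty = np.flatnonzero(~present.any(axis=1))
        raise ValueError(f"sample(s) with no taxa on the tree: rows {empty.tolist()}")
    if abundance_weighted:
        W = counts / counts.sum(axis=1, keepdims=True)
    else:
        W = present / present.sum(axis=1, keepdims=True)
    return W.astype(float), present


def _bmntd_matrix(W: np.ndarray, present: np.ndarray, D: np.ndarray) -> np.ndarray:
    """βMNTD for all sample pairs given a tip-distance matrix D.

    dmin[l, i] is the distance from taxon i to its nearest taxon present in
    sample l (zero if i itself is present in l, matching the
    nearest-taxon-in-the-other-community convention).
    """
    S, T = W.shape
    dmin = np.empty((S, T))
    for l in range(S):
        dmin[l] = D[:, present[l]].min(axis=1)
    M = W @ dmin.T  # M[k, l] = sum_i W[k, i] * dmin[l, i]
    B = 0.5 * (M + M.T)
    np.fill_diagonal(B, 0.0)
    return B


def _prepare(m: CommunityMatrix, tree: TreeNode, abundance_weighted: bool):
    sub = m.drop_empty_taxa()
    D = patristic_matrix(tree, sub.taxon_ids)
    W, present = _weights_and_presence(sub.counts, abundance_weighted)
    return sub, D, W, present


def beta_mntd(
    m: CommunityMatrix, tree: TreeNode, abundance_weighted: bool = True
) -> DistanceMatrix:
    """Between-sample mean nearest-taxon phylogenetic distance.

    For samples k, l:
    ``0.5 * [sum_i f_ik min_j d_ij + sum_j f_jl min_i d_ij]`` with f the
    within-sample relative abundance (uniform weights over present taxa
    when ``abundance_weighted`` is off) and d the patristic distance.
    Taxa with zero total count are dropped; remaining taxa must be tree
    tips.
    """
    sub, D, W, present = _prepare(m, tree, abundance_weighted)
    return DistanceMatrix(_bmntd_matrix(W, present, D), ids=sub.sample_ids)


@dataclass
class BetaNTIResult:
    """Observed βMNTD and its standardized effect size βNTI."""

    sample_ids: list[str]
    observed: np.ndarray = field(repr=False)
    bnti: np.ndarray = field(repr=False)  # NaN where the null sd is 0
    n_null: int = 999
    seed: object = None
    n_undefined_pairs: int = 0

    def pair_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        ids = np.asarray(self.sample_ids)
        return pd.DataFrame(
            {
                "sample_i": ids[iu[0]],
                "sample_j": ids[iu[1]],
                "bmntd": self.observed[iu],
                "bnti": self.bnti[iu],
            }
        )


def beta_nti(
    m: CommunityMatrix,
    tree: TreeNode,
    n_null: int = 999,
    seed=None,
    abundance_weighted: bool = True,
) -> BetaNTIResult:
    """βNTI: standardized deviation of βMNTD from a tip-shuffling null.

    The null permutes taxon labels across the whole regional pool's tip
    distance matrix and recomputes βMNTD; βNTI = (obs - mean) / sd over the
    ``n_null`` randomizations.  Pairs whose null has zero variance are
    reported as NaN.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    rng = np.random.default_rng(seed)
    sub, D, W, present = _prepare(m, tree, abundance_weighted)
    obs = _bmntd_matrix(W, present, D)
    s1 = np.zeros_like(obs)
    s2 = np.zeros_like(obs)
    T = D.shape[0]
    for _ in range(n_null):
        perm = rng.permutation(T)
        B = _bmntd_matrix(W, present, D[np.ix_(perm, perm)])
        s1 += B
        s2 += B * B
    mean = s1 / n_null
    var = np.maximum(s2 / n_null - mean**2, 0.0)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        bnti = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    np.fill_diagonal(bnti, np.nan)
    iu = np.triu_indices(obs.shape[0], k=1)
    n_undef = int(np.isnan(bnti[iu]).sum())
    if n_undef:
        logger.warning("%d sample pair(s) with zero-variance βMNTD null", n_undef)
    return BetaNTIResult(
        sample_ids=sub.sample_ids,
        observed=obs,
        bnti=bnti,
        n_null=n_null,
        seed=seed,
        n_undefined_pairs=n_undef,
    )


@dataclass
class RCResult:
    """Abundance-based Raup-Crick (Bray-Curtis) deviations in [-1, +1]."""

    sample_ids: list[str]
    rc: np.ndarray = field(repr=False)
    n_null: int = 999
    seed: object = None


def rc_bray(m: CommunityMatrix, n_null: int = 999, seed=None) -> RCResult:
    """Raup-Crick on Bray-Curtis against probabilistic null communities.

    Null communities preserve each sample's observed richness and total
    count: taxa are drawn without replacement with probability proportional
    to regional occurrence frequency, then reads are allocated with
    probability proportional to regional relative abundance.  For each pair,
    ``RC = 2 * [(#null < obs) + 0.5 * (#null = obs)] / n_null - 1``.
    """
    rng = np.random.default_rng(seed)
    sub = m.drop_empty_taxa()
    counts = sub.counts
    S = counts.shape[0]
    nulls = _null_matrices(counts, "abundance_prop_prop", n_null, rng).astype(float)
    rc = np.zeros((S, S))
    x = counts.astype(float)
    for k in range(S):
        for l in range(k + 1, S):
            obs = np.abs(x[k] - x[l]).sum() / (x[k] + x[l]).sum()
            a, b = nulls[k], nulls[l]
            null_vals = np.abs(a - b).sum(axis=1) / (a + b).sum(axis=1)
            less = (null_vals < obs - 1e-12).sum()
            equal = (np.abs(null_vals - obs) <= 1e-12).sum()
            rc[k, l] = rc[l, k] = 2.0 * (less + 0.5 * equal) / n_null - 1.0
    return RCResult(sample_ids=sub.sample_ids, rc=rc, n_null=n_null, seed=seed)


@dataclass
class ProcessSummary:
    """Per-pair assembly-process labels and their fractions."""

    pairs: pd.DataFrame = field(repr=False)  # sample_i, sample_j, bnti, rc, label
    fractions: dict = None
    n_pairs: int = 0
    n_undefined: int = 0

    def __repr__(self) -> str:  # pragma: no cover
        parts = ", ".join(f"{k}={v:.3f}" for k, v in self.fractions.items())
        return f"ProcessSummary({self.n_pairs} pairs: {parts})"


def classify_processes(
    bnti: BetaNTIResult,
    rc: RCResult,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> ProcessSummary:
    """Five-way assembly-process classification per sample pair.

    βNTI > +2 → variable selection; βNTI < -2 → homogeneous selection;
    otherwise RC > +0.95 → dispersal limitation, RC < -0.95 → homogenizing
    dispersal, else undominated.  Pairs with undefined βNTI are excluded
    from the fractions and counted separately.
    """
    if bnti.sample_ids != rc.sample_ids:
        raise ValueError("βNTI and RC results cover different samples")
    ids = np.asarray(bnti.sample_ids)
    iu = np.triu_indices(len(ids), k=1)
    b = bnti.bnti[iu]
    r = rc.rc[iu]
    labels = np.full(b.shape, "undominated", dtype=object)
    labels[r > rc_threshold] = "dispersal_limitation"
    labels[r < -rc_threshold] = "homogenizing_dispersal"
    labels[b > bnti_threshold] = "variable_selection"
    labels[b < -bnti_threshold] = "homogeneous_selection"
    defined = ~np.isnan(b)
    labels[~defined] = "undefined"
    pairs = pd.DataFrame(
        {
            "sample_i": ids[iu[0]],
            "sample_j": ids[iu[1]],
            "bnti": b,
            "rc": r,
            "label": labels,
        }
    )
    n_def = int(defined.sum())
    fractions = {
        lab: (float((labels[defined] == lab).sum()) / n_def if n_def else np.nan)
        for lab in PROCESS_LABELS
    }
    return ProcessSummary(
        pairs=pairs,
        fractions=fractions,
        n_pairs=n_def,
        n_undefined=int((~defined).sum()),
    )
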