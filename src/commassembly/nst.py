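"""Normalized stochasticity ratio (NST) under probabilistic null models.

The null expectation of between-sample dissimilarity is obtained by
randomizing communities while preserving per-sample constraints:

* ``incidence_prop_fixed`` — each sample keeps its observed richness; the
  taxa present are drawn without replacement with probability proportional
  to their regional occurrence frequency.
* ``abundance_prop_prop`` — additionally each sample keeps its observed
  total count; one read is seated per drawn taxon (so realized richness is
  preserved) and the remainder is allocated multinomially with probability
  proportional to regional relative abundance over the drawn taxa.

For each sample pair the observed dissimilarity ``D`` is compared with its
null expectation ``E``; the normalized selection strength is

    NSS = (D - E) / (1 - E)   if D >= E      (more dissimilar than null)
    NSS = (E - D) / E         otherwise       (more similar than null)

and ``NST = 1 - mean(NSS)`` over within-group pairs, so 1 is fully
stochastic (observed indistinguishable from null) and 0 fully deterministic
(observed at a bound).  Fifty percent is the conventional boundary between
deterministic- and stochastic-dominated assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import pairwise_dissimilarity
from .io import CommunityMatrix

logger = logging.getLogger(__name__)

__all__ = ["NSTResult", "null_communities", "nst", "nst_panova", "ALGORITHMS"]

ALGORITHMS = ("incidence_prop_fixed", "abundance_prop_prop")


def _null_sample_batch(
    richness: int,
    total: int,
    log_occ: np.ndarray,
    gamma: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
    abundance: bool,
) -> np.ndarray:
    """``n_null`` randomizations of one sample (rows are realizations)."""
    T = log_occ.size
    out = np.zeros((n_null, T), dtype=np.int64)
    # weighted sampling without replacement via Gumbel top-k
    keys = log_occ[None, :] + rng.gumbel(size=(n_null, T))
    sel = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    rows = np.arange(n_null)[:, None]
    if not abundance:
        out[rows, sel] = 1
        return out
    pv = gamma[sel]
    pv = pv / pv.sum(axis=1, keepdims=True)
    extra = rng.multinomial(total - richness, pv)  # broadcast over rows
    out[rows, sel] = extra + 1
    return out


def _null_matrices(
    counts: np.ndarray, algorithm: str, n_null: int, rng: np.random.Generator
) -> np.ndarray:
    """Array of shape (n_samples, n_null, n_taxa) of null communities."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    abundance = algorithm == "abundance_prop_prop"
    occ = (counts > 0).mean(axis=0)
    with np.errstate(divide="ignore"):
        log_occ = np.log(occ)
    tot = counts.sum(axis=0).astype(float)
    gamma = tot / tot.sum()
    S, T = counts.shape
    out = np.zeros((S, n_null, T), dtype=np.int64)
    for i in range(S):
        r = int((counts[i] > 0).sum())
        if r == 0:
            continue
        out[i] = _null_sample_batch(
            r, int(counts[i].sum()), log_occ, gamma, n_null, rng, abundance
        )
    return out


def null_communities(
    m: CommunityMatrix, algorithm: str = "abundance_prop_prop", seed=None
) -> CommunityMatrix:
    """One randomized community matrix under the chosen null algorithm."""
    rng = np.random.default_rng(seed)
    nulls = _null_matrices(m.counts, algorithm, 1, rng)
    return CommunityMatrix(
        pd.DataFrame(nulls[:, 0, :], index=m.sample_ids, columns=m.taxon_ids)
    )


def _nss(D: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Per-pair normalized selection strength, clamped to [0, 1]."""
    above = D >= E
    with np.errstate(invalid="ignore", divide="ignore"):
        hi = np.where(E < 1.0, (D - E) / np.where(E < 1.0, 1.0 - E, 1.0), 0.0)
        lo = np.where(E > 0.0, (E - D) / np.where(E > 0.0, E, 1.0), 0.0)
    return np.clip(np.where(above, hi, lo), 0.0, 1.0)


@dataclass
class NSTResult:
    """Stochasticity-ratio estimate for one group of samples."""

    nst: float
    metric: str
    variant: str
    algorithm: str
    group: list[str]
    n_null: int
    seed: object
    perm_mean: float
    perm_sd: float
    perm_values: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)  # per-pair D_ij (condensed)
    expected: np.ndarray = field(repr=False)  # per-pair mean null E_ij
    nss: np.ndarray = field(repr=False)


def _upper(x: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(x.shape[0], k=1)
    return x[iu]


def nst(
    m: CommunityMatrix,
    metric: str = "bray",
    variant: str = "abundance",
    algorithm: str | None = None,
    n_null: int = 999,
    group=None,
    seed=None,
) -> NSTResult:
    """Normalized stochasticity ratio for one sample group.

    ``algorithm=None`` pairs the null with the metric variant:
    incidence metrics with ``incidence_prop_fixed``, abundance metrics with
    ``abundance_prop_prop``.

    The permutation distribution contains one NST value per randomization,
    obtained by using that single randomization's dissimilarities as the
    null expectation; its mean and standard deviation summarise null-model
    uncertainty.
    """
    if algorithm is None:
        algorithm = "incidence_prop_fixed" if variant == "incidence" else "abundance_prop_prop"
    sub = m if group is None else m.select_samples(group)
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 samples for NST")
    rng = np.random.default_rng(seed)
    counts = sub.counts
    D = _upper(pairwise_dissimilarity(counts, metric, variant))
    nulls = _null_matrices(counts, algorithm, n_null, rng)
    null_D = np.empty((n_null, D.size))
    for k in range(n_null):
        null_D[k] = _upper(pairwise_dissimilarity(nulls[:, k, :], metric, variant))
    E = null_D.mean(axis=0)
    bad = (E <= 0.0) | (E >= 1.0)
    if bad.any():
        logger.warning("%d pair(s) with degenerate null expectation", int(bad.sum()))
    nss = _nss(D, E)
    nst_value = float(np.clip(1.0 - nss.mean(), 0.0, 1.0))
    perm = np.clip(1.0 - _nss(D[None, :], null_D).mean(axis=1), 0.0, 1.0)
    return NSTResult(
        nst=nst_value,
        metric=metric,
        variant=variant,
        algorithm=algorithm,
        group=sub.sample_ids,
        n_null=n_null,
        seed=seed,
        perm_mean=float(perm.mean()),
        perm_sd=float(perm.std(ddof=1)),
        perm_values=perm,
        observed=D,
        expected=E,
        nss=nss,
    )


def nst_panova(
    m: CommunityMatrix,
    group_a,
    group_b,
    metric: str = "bray",
    variant: str = "abundance",
    algorithm: str | None = None,
    n_null: int = 999,
    n_perm: int = 999,
    seed=None,
) -> dict:
    """Permutational ANOVA on the NST difference between two groups.

    The statistic is ``|NST_A - NST_B|``; the null permutes group labels
    across samples while the per-pair observed and expected dissimilarities
    are held fixed (only the pair-to-group assignment changes), giving
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 samples")
    if algorithm is None:
        algorithm = "incidence_prop_fixed" if variant == "incidence" else "abundance_prop_prop"
    samples = group_a + group_b
    sub = m.select_samples(samples)
    rng = np.random.default_rng(seed)
    counts = sub.counts
    S = len(samples)
    D = pairwise_dissimilarity(counts, metric, variant)
    nulls = _null_matrices(counts, algorithm, n_null, rng)
    Esum = np.zeros_like(D)
    for k in range(n_null):
        Esum += pairwise_dissimilarity(nulls[:, k, :], metric, variant)
    E = Esum / n_null
    NSS = _nss(D, E)

    labels = np.array([0] * len(group_a) + [1] * len(group_b))
    iu = np.triu_indices(S, k=1)

    def stat(lab: np.ndarray) -> float:
        li, lj = lab[iu[0]], lab[iu[1]]
        within_a = (li == 0) & (lj == 0)
        within_b = (li == 1) & (lj == 1)
        vals = NSS[iu]
        return abs((1.0 - vals[within_a].mean()) - (1.0 - vals[within_b].mean()))

    obs = stat(labels)
    count = 0
    for _ in range(n_perm):
        count += stat(rng.permutation(labels)) >= obs
    p = (1 + count) / (1 + n_perm)
    nst_a = float(np.clip(1.0 - NSS[iu][(labels[iu[0]] == 0) & (labels[iu[1]] == 0)].mean(), 0, 1))
    nst_b = float(np.clip(1.0 - NSS[iu][(labels[iu[0]] == 1) & (labels[iu[1]] == 1)].mean(), 0, 1))
    return {
        "statistic": float(obs),
        "p_value": float(p),
        "nst_a": nst_a,
        "nst_b": nst_b,
        "n_perm": n_perm,
        "metric": metric,
        "variant": variant,
        "algorithm": algorithm,
    }
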