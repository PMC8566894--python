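"""Alpha-diversity indices and bounded community dissimilarities.

Alpha indices are the classical estimators (richness, Chao1, ACE, Shannon,
Pielou evenness, Gini-Simpson) computed per sample via scikit-bio.  The
dissimilarity function provides the family of [0, 1]-bounded metrics the
stochasticity-ratio machinery needs: Bray-Curtis, Jaccard, Kulczynski,
Canberra, range-standardised Gower and maximum-standardised Manhattan, each
in an abundance and an incidence (presence/absence) variant.

Notes on conventions
--------------------
* Shannon uses natural log so that Pielou J = H / ln S.
* "Simpson" is the Gini-Simpson index 1 - sum(p^2).
* The abundance variant of Jaccard is the Ruzicka coefficient
  ``2B / (1 + B)`` with B the Bray-Curtis dissimilarity (the quantitative
  Jaccard of vegan); the incidence variant is the classical
  ``(b + c) / (a + b + c)``.
* Gower divides by per-taxon across-sample ranges and Manhattan by
  per-taxon across-sample maxima, so both are bounded by 1; taxa with zero
  range/maximum contribute zero.
* Canberra averages over taxa present in at least one of the two samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.diversity.alpha import ace, chao1, pielou_e, shannon, simpson

from .io import CommunityMatrix

logger = logging.getLogger(__name__)

__all__ = ["alpha_diversity", "dissimilarity", "pairwise_dissimilarity", "METRICS"]

METRICS = ("bray", "jaccard", "kulczynski", "gower", "manhattan", "canberra")


def alpha_diversity(m: CommunityMatrix) -> pd.DataFrame:
    """Per-sample alpha-diversity table.

    Columns: ``richness``, ``chao1``, ``ace``, ``shannon`` (nats),
    ``pielou`` and ``gini_simpson``.  Chao1 uses the bias-corrected
    estimator ``S + F1(F1-1) / (2(F2+1))``; ACE uses the standard
    abundance-based coverage estimator with rare cutoff 10.
    """
    rows = []
    for sid, counts in zip(m.sample_ids, m.counts):
        if counts.sum() == 0:
            raise ValueError(f"sample {sid!r} is empty")
        s = int((counts > 0).sum())
        h = shannon(counts, base=np.e)
        c1 = chao1(counts, bias_corrected=True)
        try:
            a = ace(counts, rare_threshold=10)
        except ValueError:
            # ACE is undefined when every rare taxon is a singleton;
            # EstimateS recommends bias-corrected Chao1 in that case.
            logger.info("ACE undefined for sample %r; using Chao1", sid)
            a = c1
        rows.append(
            {
                "richness": s,
                "chao1": c1,
                "ace": a,
                "shannon": h,
                "pielou": pielou_e(counts, base=np.e) if s > 1 else np.nan,
                "gini_simpson": simpson(counts, finite=False),
            }
        )
    return pd.DataFrame(rows, index=pd.Index(m.sample_ids, name="sample_id"))


def _pair_values(X: np.ndarray, metric: str) -> np.ndarray:
    """All-pairs dissimilarity on rows of X (already binarised if incidence).

    Broadcasts to an (S, S, T) difference tensor; community matrices here
    are small enough that this is faster than a python pair loop.
    """
    Xf = X.astype(float)
    A = Xf[:, None, :]
    B = Xf[None, :, :]
    if metric == "bray":
        num = np.abs(A - B).sum(axis=2)
        den = (A + B).sum(axis=2)
        return _safe_div(num, den)
    if metric == "jaccard":
        bray = _pair_values(X, "bray")
        return 2.0 * bray / (1.0 + bray)
    if metric == "kulczynski":
        mins = np.minimum(A, B).sum(axis=2)
        sa = Xf.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = 0.5 * (mins / sa[:, None] + mins / sa[None, :])
        return np.where(np.isfinite(sim), 1.0 - sim, 0.0)
    if metric == "canberra":
        num = np.abs(A - B)
        den = A + B
        present = den > 0
        terms = np.where(present, num / np.where(present, den, 1.0), 0.0)
        nprime = present.sum(axis=2)
        return _safe_div(terms.sum(axis=2), nprime)
    if metric == "gower":
        rng = Xf.max(axis=0) - Xf.min(axis=0)
        ok = rng > 0
        terms = np.where(ok, np.abs(A - B) / np.where(ok, rng, 1.0), 0.0)
        return terms.sum(axis=2) / X.shape[1]
    if metric == "manhattan":
        mx = Xf.max(axis=0)
        ok = mx > 0
        terms = np.where(ok, np.abs(A - B) / np.where(ok, mx, 1.0), 0.0)
        return terms.sum(axis=2) / X.shape[1]
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def _incidence_jaccard(X: np.ndarray) -> np.ndarray:
    P = (X > 0).astype(float)
    a = P @ P.T
    pres = P.sum(axis=1)
    union = pres[:, None] + pres[None, :] - a
    return _safe_div(union - a, union)


def pairwise_dissimilarity(
    X: np.ndarray, metric: str = "bray", variant: str = "abundance"
) -> np.ndarray:
    """Square dissimilarity array for a raw counts array (rows = samples)."""
    if variant not in ("abundance", "incidence"):
        raise ValueError(f"unknown variant {variant!r}")
    X = np.asarray(X)
    if variant == "incidence":
        if metric == "jaccard":
            D = _incidence_jaccard(X)
        else:
            D = _pair_values((X > 0).astype(float), metric)
    else:
        if metric == "jaccard":
            # quantitative (Ruzicka) form
            D = _pair_values(X, "jaccard")
        else:
            D = _pair_values(X, metric)
    if (X.sum(axis=1) == 0).any():
        logger.warning("all-zero sample(s) present; their dissimilarities are 0")
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)  # enforce exact symmetry against round-off


def dissimilarity(
    m: CommunityMatrix, metric: str = "bray", variant: str = "abundance"
) -> DistanceMatrix:
    """Pairwise sample dissimilarity under a bounded metric.

    Parameters
    ----------
    metric : one of ``bray``, ``jaccard``, ``kulczynski``, ``gower``,
        ``manhattan``, ``canberra``.
    variant : ``abundance`` (counts) or ``incidence`` (presence/absence).
    """
    if m.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    D = pairwise_dissimilarity(m.counts, metric, variant)
    return DistanceMatrix(D, ids=m.sample_ids)
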