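"""Synthetic communities with known assembly regimes.

Every downstream inference stage (neutral-model fit, phylogenetic null
models, stochasticity ratios, phylogenetic signal) is validated against
communities generated here, where the assembly process is known exactly:

* a *metacommunity* with a lognormal (skewed) abundance distribution on a
  simulated pure-birth phylogeny;
* *neutral* local communities assembled by immigration-limited drift — a
  Moran death/replacement process in which each random death is replaced by
  an immigrant drawn from the metacommunity with probability ``m`` and by a
  local birth otherwise;
* *selected* local communities assembled by Gaussian environmental
  filtering on a niche optimum trait evolved by Brownian motion along the
  tree, so that selection leaves a phylogenetic imprint;
* sequencing simulated as multinomial subsampling of each community to a
  fixed read depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import CommunityMatrix, write_env_table, write_otu_table, write_tree

__all__ = [
    "Metacommunity",
    "NicheTraits",
    "SyntheticDataset",
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_bm_trait",
    "build_metacommunity",
    "simulate_neutral_community",
    "simulate_selected_community",
    "simulate_dataset",
]

REGIMES = ("neutral", "homogeneous_selection", "variable_selection", "mixed")


@dataclass
class Metacommunity:
    """Regional species pool: taxon ids and their relative abundances."""

    taxon_ids: list[str]
    abundances: np.ndarray

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.taxon_ids) != self.abundances.size:
            raise ValueError("taxon_ids and abundances length mismatch")
        if (self.abundances <= 0).any():
            raise ValueError("metacommunity abundances must be positive")
        if abs(self.abundances.sum() - 1.0) > 1e-12:
            raise ValueError("metacommunity abundances must sum to 1")


@dataclass
class NicheTraits:
    """Per-taxon niche optima (same units as the environmental axis)."""

    taxon_ids: list[str]
    values: np.ndarray
    sigma2: float | None = None
    root_value: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.taxon_ids) != self.values.size:
            raise ValueError("taxon_ids and values length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite trait value")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.taxon_ids)


def simulate_yule_tree(n_tips: int, seed, birth_rate: float = 1.0) -> TreeNode:
    """Simulate a rooted binary pure-birth (Yule) tree.

    Lineages split at rate ``birth_rate`` each; after the n-th tip appears
    the process runs one final exponential waiting time so terminal branches
    are strictly positive.  Tips are labelled ``OTU_1 .. OTU_n``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    active: list[tuple[TreeNode, float]] = [(root, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        node, birth = active.pop(i)
        node.length = t - birth if node.parent is not None else None
        left, right = TreeNode(), TreeNode()
        node.append(left)
        node.append(right)
        active.append((left, t))
        active.append((right, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node, birth in active:
        node.length = t - birth
    for k, tip in enumerate(root.tips(), start=1):
        tip.name = f"OTU_{k}"
    return root


def simulate_bm_trait(
    tree: TreeNode, sigma2: float, root: float = 0.0, seed=None
) -> NicheTraits:
    """Evolve a continuous trait by Brownian motion along the tree.

    Each branch adds an independent Gaussian increment with variance
    ``sigma2 * branch_length``; the tip value is the sum of increments along
    its root path plus the root value.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): float(root)}
    tips, tip_values = [], []
    for node in tree.preorder(include_self=False):
        b = node.length or 0.0
        v = values[id(node.parent)] + rng.normal(0.0, np.sqrt(sigma2 * b))
        values[id(node)] = v
        if node.is_tip():
            tips.append(node.name)
            tip_values.append(v)
    return NicheTraits(tips, np.array(tip_values), sigma2=sigma2, root_value=root)


def build_metacommunity(n_taxa: int, lognormal_sigma: float = 1.5, seed=None) -> Metacommunity:
    """Lognormal metacommunity relative abundances (skewed species pool)."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, lognormal_sigma, size=n_taxa))
    gamma = raw / raw.sum()
    return Metacommunity([f"OTU_{k}" for k in range(1, n_taxa + 1)], gamma)


def simulate_neutral_community(
    meta: Metacommunity,
    N: int,
    m: float,
    generations: int = 50,
    seed=None,
) -> np.ndarray:
    """Immigration-limited neutral drift (Moran scheme).

    The community of fixed size ``N`` is initialised as a multinomial draw
    from the metacommunity.  Each of ``generations * N`` steps removes one
    uniformly chosen individual and replaces it, with probability ``m``, by
    an immigrant drawn from the metacommunity (prob. proportional to gamma)
    and otherwise by the offspring of a uniformly chosen surviving local
    individual.

    Returns the final counts vector (sums to ``N``).
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"migration probability m must be in [0, 1], got {m}")
    if N < 10:
        raise ValueError("community size N must be >= 10")
    rng = np.random.default_rng(seed)
    gamma = meta.abundances
    n_taxa = gamma.size
    cum = np.cumsum(gamma)
    cum[-1] = 1.0
    community = np.searchsorted(cum, rng.random(N)).astype(np.int64)
    steps = generations * N
    # draw all randomness up front; the loop itself is then branch + assign
    death = rng.integers(0, N, size=steps)
    migrate = rng.random(steps) < m
    immigrant = np.searchsorted(cum, rng.random(steps))
    # parent chosen uniformly among the N-1 survivors
    parent = (death + 1 + rng.integers(0, N - 1, size=steps)) % N
    for s in range(steps):
        if migrate[s]:
            community[death[s]] = immigrant[s]
        else:
            community[death[s]] = community[parent[s]]
    return np.bincount(community, minlength=n_taxa)


def simulate_selected_community(
    meta: Metacommunity,
    traits: NicheTraits,
    env: float,
    sigma_w: float,
    N: int,
    seed=None,
) -> np.ndarray:
    """Gaussian environmental filtering of the metacommunity.

    Sampling weight of taxon i is ``gamma_i * exp(-(t_i - env)^2 / (2 sigma_w^2))``
    (niche optimum ``t_i``, niche breadth ``sigma_w``); the community is a
    multinomial draw of ``N`` individuals from the normalised weights.
    """
    if sigma_w <= 0:
        raise ValueError("niche breadth sigma_w must be positive")
    if list(traits.taxon_ids) != list(meta.taxon_ids):
        trait_map = traits.as_series()
        t = trait_map.reindex(meta.taxon_ids).to_numpy()
        if np.isnan(t).any():
            raise ValueError("traits missing for some metacommunity taxa")
    else:
        t = traits.values
    rng = np.random.default_rng(seed)
    w = meta.abundances * np.exp(-((t - env) ** 2) / (2.0 * sigma_w**2))
    if w.sum() <= 0 or not np.isfinite(w.sum()):
        raise ValueError(
            "all selection weights underflowed to zero; increase sigma_w"
        )
    return rng.multinomial(N, w / w.sum())


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset."""

    regime: str = "neutral"
    n_samples: int = 30
    n_taxa: int = 100
    m: float = 0.5
    sigma_w: float = 1.0
    N: int = 1000
    depth: int = 1000
    generations: int = 50
    lognormal_sigma: float = 2.0
    sigma2_bm: float = 1.0
    background_m: float = 0.05
    env_range: tuple[float, float] = (20.0, 30.0)
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["env_range"] = list(self.env_range)
        return d


@dataclass
class SyntheticDataset:
    """A community matrix, its phylogeny, environment and ground truth."""

    matrix: CommunityMatrix
    tree: TreeNode
    env: pd.DataFrame
    traits: NicheTraits
    regime: str
    sample_regime: pd.Series
    config: SimulationConfig = field(repr=False)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_otu_table(self.matrix, outdir / "otu_table.tsv")
        write_tree(self.tree, outdir / "tree.nwk")
        env = self.env.copy()
        env["regime"] = self.sample_regime
        write_env_table(env, outdir / "metadata.csv")
        truth = {
            "regime": self.regime,
            "config": self.config.to_dict(),
            "niche_optima": {t: float(v) for t, v in zip(self.traits.taxon_ids, self.traits.values)},
        }
        with open(outdir / "ground_truth.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Assemble a full synthetic dataset under one assembly regime.

    Regimes
    -------
    neutral
        Every sample is an independent Moran community with immigration
        ``m`` from the shared metacommunity; the environment is a gradient
        with no effect on composition.
    homogeneous_selection
        One environmental optimum (the trait mean) for all samples:
        each sample is a Moran community drifting on the Gaussian-filtered
        metacommunity (immigration ``m`` from the filtered pool), so
        samples are dominated by different but closely related members of
        the selected clade — selection plus local drift.
    variable_selection
        Two equal sample groups deterministically filtered toward optima
        placed at the trait mean +/- 2 trait standard deviations.
    mixed
        First half neutral, second half homogeneous selection.

    Selection regimes additionally receive a fraction ``background_m`` of
    individuals straight from the unfiltered metacommunity (weak mass
    effects), which keeps the regional taxon pool representative of the
    whole phylogeny.

    Sequencing is multinomial subsampling of each community to ``depth``
    reads.  Deterministic for a fixed config seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_yule_tree(cfg.n_taxa, rng.integers(2**31))
    meta = build_metacommunity(cfg.n_taxa, cfg.lognormal_sigma, rng.integers(2**31))
    traits = simulate_bm_trait(tree, cfg.sigma2_bm, root=float(np.mean(cfg.env_range)), seed=rng.integers(2**31))
    trait_by_taxon = traits.as_series().reindex(meta.taxon_ids).to_numpy()
    t_mean, t_sd = trait_by_taxon.mean(), trait_by_taxon.std()

    n = cfg.n_samples
    sample_ids = [f"S{k:03d}" for k in range(1, n + 1)]
    env_values = np.empty(n)
    regimes = []
    counts = np.zeros((n, cfg.n_taxa), dtype=np.int64)

    def neutral(i):
        counts[i] = simulate_neutral_community(
            meta, cfg.N, cfg.m, cfg.generations, rng.integers(2**31)
        )

    def selected(i, optimum):
        # selection is strong but not absolute: a small fraction of
        # individuals are background immigrants from the unfiltered pool,
        # so the regional taxon pool keeps its full metacommunity footprint
        n_bg = rng.binomial(cfg.N, cfg.background_m)
        sel = simulate_selected_community(
            meta, traits, optimum, cfg.sigma_w, cfg.N - n_bg, rng.integers(2**31)
        )
        bg = rng.multinomial(n_bg, meta.abundances)
        counts[i] = sel + bg

    def selected_with_drift(i, optimum):
        # homogeneous selection: drift within the filtered pool, so each
        # sample fixes on different (but related) members of the selected
        # clade; plus background immigrants as above
        w = meta.abundances * np.exp(
            -((trait_by_taxon - optimum) ** 2) / (2.0 * cfg.sigma_w**2)
        )
        keep = np.flatnonzero(w > 0)
        if keep.size < 2:
            raise ValueError("selection too strong: filtered pool has < 2 taxa")
        filtered = Metacommunity(
            [meta.taxon_ids[j] for j in keep], w[keep] / w[keep].sum()
        )
        n_bg = rng.binomial(cfg.N, cfg.background_m)
        local = simulate_neutral_community(
            filtered, cfg.N - n_bg, cfg.m, cfg.generations, rng.integers(2**31)
        )
        counts[i, keep] = local
        counts[i] += rng.multinomial(n_bg, meta.abundances)

    if cfg.regime == "neutral":
        gradient = np.linspace(*cfg.env_range, n)
        for i in range(n):
            env_values[i] = gradient[i]
            neutral(i)
            regimes.append("neutral")
    elif cfg.regime == "homogeneous_selection":
        for i in range(n):
            env_values[i] = t_mean
            selected_with_drift(i, t_mean)
            regimes.append("homogeneous_selection")
    elif cfg.regime == "variable_selection":
        if n < 4:
            raise ValueError("variable_selection needs >= 4 samples (two groups)")
        optima = (t_mean - 2.0 * t_sd, t_mean + 2.0 * t_sd)
        for i in range(n):
            opt = optima[0] if i < n // 2 else optima[1]
            env_values[i] = opt
            selected(i, opt)
            regimes.append("variable_selection")
    elif cfg.regime == "mixed":
        gradient = np.linspace(*cfg.env_range, n)
        for i in range(n):
            if i < n // 2:
                env_values[i] = gradient[i]
                neutral(i)
                regimes.append("neutral")
            else:
                env_values[i] = t_mean
                selected_with_drift(i, t_mean)
                regimes.append("homogeneous_selection")

    # sequencing: multinomial read sampling to fixed depth
    reads = np.empty_like(counts)
    for i in range(n):
        reads[i] = rng.multinomial(cfg.depth, counts[i] / counts[i].sum())

    matrix = CommunityMatrix(
        pd.DataFrame(reads, index=sample_ids, columns=meta.taxon_ids)
    )
    half = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    env = pd.DataFrame(
        {
            "temperature": env_values,
            "salinity": rng.normal(34.0, 0.5, size=n).round(3),
            "depth_to_bottom": np.exp(rng.normal(6.0, 1.0, size=n)).round(1),
            "group": half,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticDataset(
        matrix=matrix,
        tree=tree,
        env=env,
        traits=traits,
        regime=cfg.regime,
        sample_regime=pd.Series(regimes, index=sample_ids, name="regime"),
        config=cfg,
    )
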