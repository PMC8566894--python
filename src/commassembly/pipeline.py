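"""End-to-end orchestration: load or simulate, then run every stage.

A :class:`RunConfig` (YAML/JSON-friendly, schema-validated, unknown keys
rejected) either points at an OTU table / tree / metadata triplet or embeds
a simulation block.  ``run`` executes diversity -> NCM -> phylogenetic null
models -> NST -> phylogenetic signal -> driver statistics, derives every
stage's random seed deterministically from the single global seed, writes
tidy TSV/JSON outputs, and returns a machine-readable report.  Identical
config + seed gives byte-identical table outputs.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import diversity as _diversity
from . import drivers as _drivers
from . import ncm as _ncm
from . import nst as _nst
from . import phylosignal as _signal
from . import stegen as _stegen
from .io import (
    CommunityMatrix,
    rarefy,
    read_env_table,
    read_otu_table,
    read_tree,
    write_otu_table,
)
from .synth import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "stage_seed"]


class InputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    otu_table: str
    tree: str | None = None
    metadata: str | None = None
    orientation: str = "taxa-rows"


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
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


class StegenBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_null: int = 999
    abundance_weighted: bool = True
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95


class NSTBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    metrics: list[str] = Field(default_factory=lambda: ["jaccard", "bray"])
    variants: list[str] = Field(default_factory=lambda: ["incidence", "abundance"])
    n_null: int = 999
    group_column: str | None = "group"


class SignalBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    variables: list[str] = Field(default_factory=lambda: ["temperature"])
    n_perm: int = 999


class DriversBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r_threshold: float = 0.5
    p_threshold: float = 0.05
    min_reads: int = 10
    mantel_permutations: int = 999
    permanova_permutations: int = 9999
    group_column: str | None = "group"
    variables: list[str] | None = None


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "results/run"
    input: InputBlock | None = None
    simulate: SimulateBlock | None = None
    rarefy_depth: int | None = None
    ncm_detection_limit: float | str = "auto"
    stegen: StegenBlock = Field(default_factory=StegenBlock)
    nst: NSTBlock = Field(default_factory=NSTBlock)
    signal: SignalBlock = Field(default_factory=SignalBlock)
    drivers: DriversBlock = Field(default_factory=DriversBlock)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls.model_validate(payload)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, from the global seed."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, t0: float, outputs: list[str], **extra):
        report["stages"][stage] = {
            "status": "succeeded",
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": outputs,
            **extra,
        }

    def skip(stage: str, reason: str):
        logger.info("skipping stage %s: %s", stage, reason)
        report["stages"][stage] = {"status": "skipped", "reason": reason}

    # ---- load or simulate -------------------------------------------------
    t0 = time.perf_counter()
    tree = None
    env = None
    if (config.input is None) == (config.simulate is None):
        raise ValueError("config must set exactly one of 'input' or 'simulate'")
    if config.simulate is not None:
        sim_cfg = SimulationConfig(
            seed=stage_seed(config.seed, "simulate"), **config.simulate.model_dump()
        )
        ds = simulate_dataset(sim_cfg)
        ds.write(outdir / "simulated")
        matrix, tree, env = ds.matrix, ds.tree, ds.env
        record("load", t0, ["simulated/"], regime=ds.regime)
    else:
        matrix = read_otu_table(config.input.otu_table, config.input.orientation)
        if config.input.tree:
            tree = read_tree(config.input.tree)
        if config.input.metadata:
            env = read_env_table(config.input.metadata)
        record("load", t0, [config.input.otu_table])

    if config.rarefy_depth:
        t0 = time.perf_counter()
        matrix = rarefy(matrix, config.rarefy_depth, stage_seed(config.seed, "rarefy"))
        write_otu_table(matrix, outdir / "rarefied_otu_table.tsv")
        record("rarefy", t0, ["rarefied_otu_table.tsv"], depth=config.rarefy_depth)

    # ---- alpha + beta diversity ------------------------------------------
    t0 = time.perf_counter()
    alpha = _diversity.alpha_diversity(matrix)
    _write_tsv(alpha, outdir / "alpha_diversity.tsv")
    bray = _diversity.dissimilarity(matrix, "bray", "abundance")
    _write_tsv(
        pd.DataFrame(bray.data, index=bray.ids, columns=bray.ids),
        outdir / "bray_curtis.tsv",
    )
    record("diversity", t0, ["alpha_diversity.tsv", "bray_curtis.tsv"])

    # ---- neutral community model -----------------------------------------
    t0 = time.perf_counter()
    fit = _ncm.fit_ncm(matrix, d=config.ncm_detection_limit)
    _write_tsv(fit.taxa, outdir / "ncm_taxa.tsv")
    _write_json(fit.summary(), outdir / "ncm_fit.json")
    record("ncm", t0, ["ncm_taxa.tsv", "ncm_fit.json"], m=fit.m, r_squared=fit.r_squared)

    # ---- Stegen null models ----------------------------------------------
    if tree is None:
        skip("stegen", "no phylogeny provided")
    else:
        t0 = time.perf_counter()
        sg = config.stegen
        bnti = _stegen.beta_nti(
            matrix,
            tree,
            n_null=sg.n_null,
            seed=stage_seed(config.seed, "beta_nti"),
            abundance_weighted=sg.abundance_weighted,
        )
        rc = _stegen.rc_bray(matrix, n_null=sg.n_null, seed=stage_seed(config.seed, "rc_bray"))
        summary = _stegen.classify_processes(
            bnti, rc, bnti_threshold=sg.bnti_threshold, rc_threshold=sg.rc_threshold
        )
        _write_tsv(summary.pairs, outdir / "assembly_pairs.tsv", index=False)
        _write_json(
            {
                "fractions": summary.fractions,
                "n_pairs": summary.n_pairs,
                "n_undefined": summary.n_undefined,
                "n_null": sg.n_null,
            },
            outdir / "assembly_fractions.json",
        )
        record(
            "stegen", t0, ["assembly_pairs.tsv", "assembly_fractions.json"],
            fractions=summary.fractions,
        )

    # ---- normalized stochasticity ratio ----------------------------------
    t0 = time.perf_counter()
    nb = config.nst
    groups = {"all": None}
    if env is not None and nb.group_column and nb.group_column in env.columns:
        groups = {
            str(g): env.index[env[nb.group_column] == g].tolist()
            for g in env[nb.group_column].unique()
        }
    rows = []
    for metric in nb.metrics:
        for variant in nb.variants:
            for gname, gsamples in groups.items():
                res = _nst.nst(
                    matrix,
                    metric=metric,
                    variant=variant,
                    n_null=nb.n_null,
                    group=gsamples,
                    seed=stage_seed(config.seed, f"nst:{metric}:{variant}:{gname}"),
                )
                rows.append(
                    {
                        "metric": metric,
                        "variant": variant,
                        "group": gname,
                        "nst": res.nst,
                        "perm_mean": res.perm_mean,
                        "perm_sd": res.perm_sd,
                        "n_null": res.n_null,
                    }
                )
    nst_table = pd.DataFrame(rows)
    _write_tsv(nst_table, outdir / "nst.tsv", index=False)
    record("nst", t0, ["nst.tsv"])

    # ---- phylogenetic signal ---------------------------------------------
    if tree is None or env is None:
        skip("signal", "needs phylogeny and metadata")
    else:
        t0 = time.perf_counter()
        rows = []
        for var in config.signal.variables:
            if var not in env.columns:
                logger.warning("signal variable %r missing; skipped", var)
                continue
            traits = _signal.taxon_niche_values(matrix, env, var)
            res = _signal.k_significance(
                tree,
                traits,
                n_perm=config.signal.n_perm,
                seed=stage_seed(config.seed, f"signal:{var}"),
                trait_name=var,
            )
            rows.append(
                {"variable": var, "K": res.k, "p_value": res.p_value, "n_tips": res.n_tips}
            )
        _write_tsv(pd.DataFrame(rows), outdir / "phylosignal.tsv", index=False)
        record("signal", t0, ["phylosignal.tsv"])

    # ---- driver statistics ------------------------------------------------
    if env is None:
        skip("drivers", "no metadata provided")
    else:
        t0 = time.perf_counter()
        db = config.drivers
        outputs = []
        num_env = env.select_dtypes(include=[np.number])
        variables = db.variables or list(num_env.columns)
        mrows = []
        for var in variables:
            if var not in num_env.columns:
                continue
            vals = num_env[var].reindex(matrix.sample_ids).to_numpy(dtype=float)
            if np.ptp(vals[np.isfinite(vals)]) == 0:
                logger.warning("mantel: %r constant; skipped", var)
                continue
            from skbio import DistanceMatrix as _DM

            dvar = _DM(np.abs(vals[:, None] - vals[None, :]), ids=matrix.sample_ids)
            r, p = _drivers.mantel(
                bray, dvar, method="spearman", n_perm=db.mantel_permutations,
                seed=stage_seed(config.seed, f"mantel:{var}"),
            )
            mrows.append({"variable": var, "mantel_r": r, "p_value": p})
        _write_tsv(pd.DataFrame(mrows), outdir / "mantel.tsv", index=False)
        outputs.append("mantel.tsv")

        if db.group_column and db.group_column in env.columns:
            labels = env[db.group_column].reindex(matrix.sample_ids)
            if labels.nunique() >= 2 and labels.value_counts().min() >= 2:
                f, p = _drivers.permanova(
                    bray, labels, n_perm=db.permanova_permutations,
                    seed=stage_seed(config.seed, "permanova"),
                )
                _write_json(
                    {"pseudo_F": f, "p_value": p, "n_perm": db.permanova_permutations},
                    outdir / "permanova.json",
                )
                outputs.append("permanova.json")

        net = _drivers.correlation_network(
            matrix, env, r_threshold=db.r_threshold, p_threshold=db.p_threshold,
            min_reads=db.min_reads,
        )
        edges = pd.DataFrame(
            [
                {"source": u, "target": v, "r": d["r"], "p": d["p"], "sign": d["sign"]}
                for u, v, d in sorted(net.edges(data=True))
            ]
        )
        _write_tsv(edges, outdir / "network_edges.tsv", index=False)
        topo = _drivers.node_topology(net) if net.number_of_nodes() else pd.DataFrame()
        _write_tsv(topo, outdir / "network_topology.tsv")
        import networkx as nx

        nx.write_graphml(net, outdir / "network.graphml")
        outputs += ["network_edges.tsv", "network_topology.tsv", "network.graphml"]
        record("drivers", t0, outputs, n_edges=net.number_of_edges())

    _write_json(report, outdir / "report.json")
    return report
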