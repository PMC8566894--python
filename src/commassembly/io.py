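"""Reading, writing and rarefying the pipeline's tabular and tree inputs.

The central in-memory objects are deliberately thin wrappers around the
containers practitioners already use: a :class:`CommunityMatrix` holds a
samples x taxa pandas DataFrame of integer counts, environmental metadata is
a pandas DataFrame indexed by sample id, and phylogenies are scikit-bio
``TreeNode`` objects read from newick.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "write_tree",
    "read_env_table",
    "write_env_table",
    "rarefy",
]


class CommunityMatrix:
    """Samples x taxa table of non-negative integer counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns are taxa.  Values must be non-negative
        integers (floats that are whole numbers are accepted and cast).

    Raises
    ------
    ValueError
        On duplicate sample/taxon ids, negative, non-finite or non-integer
        counts, or an empty table.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise ValueError("community matrix is empty")
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dup}")
        values = counts.to_numpy()
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in community matrix: {exc}") from None
        if not np.isfinite(values).all():
            raise ValueError("non-finite count in community matrix")
        if (values < 0).any():
            raise ValueError("negative count in community matrix")
        if not np.array_equal(values, np.round(values)):
            bad = values[values != np.round(values)][0]
            raise ValueError(f"non-integer count in community matrix: {bad}")
        self._df = pd.DataFrame(
            values.astype(np.int64),
            index=counts.index.astype(str),
            columns=counts.columns.astype(str),
        )
        self._df.index.name = None
        self._df.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an int array of shape (n_samples, n_taxa)."""
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised counts; all-zero rows map to all-zero rows."""
        x = self.counts.astype(float)
        totals = x.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(totals > 0, x / np.maximum(totals, 1e-300), 0.0)
        return f

    def select_samples(self, sample_ids) -> "CommunityMatrix":
        return CommunityMatrix(self._df.loc[list(sample_ids)])

    def select_taxa(self, taxon_ids) -> "CommunityMatrix":
        return CommunityMatrix(self._df.loc[:, list(taxon_ids)])

    def drop_empty_taxa(self) -> "CommunityMatrix":
        """Drop taxa with zero total count (e.g. after rarefaction)."""
        keep = self._df.columns[self._df.sum(axis=0) > 0]
        dropped = self.shape[1] - len(keep)
        if dropped:
            logger.info("dropping %d empty taxa", dropped)
        return CommunityMatrix(self._df.loc[:, keep])

    def __repr__(self) -> str:  # pragma: no cover
        s, t = self.shape
        return f"CommunityMatrix({s} samples x {t} taxa)"


def read_otu_table(path, orientation: str = "taxa-rows") -> CommunityMatrix:
    """Read a tab-separated OTU table.

    Parameters
    ----------
    path : str or Path
        TSV file with a header row and an id column first.
    orientation : {"taxa-rows", "samples-rows"}
        ``taxa-rows`` is the QIIME-classic layout (one row per taxon); the
        table is transposed into canonical samples x taxa orientation.
    """
    if orientation not in ("taxa-rows", "samples-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty OTU table: {path}")
    if orientation == "taxa-rows":
        df = df.T
    return CommunityMatrix(df)


def write_otu_table(m: CommunityMatrix, path, orientation: str = "taxa-rows") -> None:
    df = m.to_dataframe()
    if orientation == "taxa-rows":
        df = df.T
        df.index.name = "otu_id"
    else:
        df.index.name = "sample_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t")


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; every non-root branch must have a length."""
    tree = TreeNode.read(str(path), format="newick")
    missing = [
        n.name for n in tree.traverse(include_self=False) if n.length is None
    ]
    if missing:
        raise ValueError(
            f"tree has {len(missing)} branches without lengths (e.g. {missing[0]!r})"
        )
    neg = [n.length for n in tree.traverse(include_self=False) if n.length < 0]
    if neg:
        raise ValueError(f"negative branch length: {neg[0]}")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(str(tree).strip() + "\n")


def read_env_table(path) -> pd.DataFrame:
    """Read sample metadata CSV with a ``sample_id`` column."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("metadata CSV must contain a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return df.set_index("sample_id")


def write_env_table(env: pd.DataFrame, path) -> None:
    out = env.copy()
    out.index.name = "sample_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh)


def rarefy(
    m: CommunityMatrix,
    depth: int,
    seed: int | np.random.Generator = 0,
    with_replacement: bool = False,
) -> CommunityMatrix:
    """Subsample every sample to an even sequencing depth.

    Samples whose total count is below ``depth`` are dropped with a logged
    warning.  Default draws are without replacement (multivariate
    hypergeometric); ``with_replacement=True`` switches to multinomial
    resampling of reads.

    Deterministic for a fixed integer seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    counts = m.counts
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = [s for s, k in zip(m.sample_ids, keep) if not k]
        logger.warning(
            "dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    if not keep.any():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    rows = []
    for i in np.flatnonzero(keep):
        row = counts[i]
        if with_replacement:
            rows.append(rng.multinomial(depth, row / row.sum()))
        elif totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = pd.DataFrame(
        np.asarray(rows),
        index=[s for s, k in zip(m.sample_ids, keep) if k],
        columns=m.taxon_ids,
    )
    return CommunityMatrix(out)
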