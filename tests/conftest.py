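import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from commassembly.io import CommunityMatrix


@pytest.fixture
def toy_matrix() -> CommunityMatrix:
    """The documented 3-sample / 4-taxon worked example."""
    return CommunityMatrix(
        pd.DataFrame(
            [[5, 1, 1, 2], [3, 0, 0, 1], [0, 2, 1, 0]],
            index=["S1", "S2", "S3"],
            columns=["A", "B", "C", "D"],
        )
    )


@pytest.fixture
def toy_tree() -> TreeNode:
    """Three-tip tree with hand-computable patristic distances."""
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def five_tip_tree() -> TreeNode:
    """Five-tip tree used for cross-checked phylogenetic oracles."""
    return TreeNode.read(["((A:1,B:1):1,(C:1.5,(D:0.5,E:0.5):1):0.5);"])


@pytest.fixture
def five_tip_matrix() -> CommunityMatrix:
    return CommunityMatrix(
        pd.DataFrame(
            [[5, 1, 0, 2, 0], [0, 3, 1, 0, 1], [2, 0, 4, 1, 0]],
            index=["S1", "S2", "S3"],
            columns=list("ABCDE"),
        )
    )
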