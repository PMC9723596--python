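import numpy as np
import pandas as pd
import pytest

from assemblytrace import CommunityTable, read_newick


@pytest.fixture
def balanced_tree():
    """Four-tip balanced tree: two cherries of unit branches."""
    return read_newick("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def toy_table():
    return CommunityTable(
        pd.DataFrame(
            [[5, 0, 2], [1, 1, 1]],
            index=["s1", "s2"],
            columns=["A", "B", "C"],
        )
    )


def random_count_table(rng, n_samples, n_taxa, depth=100, sparsity=0.3):
    """Random integer community table with guaranteed non-empty samples."""
    counts = rng.integers(0, depth, size=(n_samples, n_taxa)).astype(float)
    counts[rng.random((n_samples, n_taxa)) < sparsity] = 0
    empty = counts.sum(axis=1) == 0
    counts[empty, 0] = 1
    return CommunityTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j:03d}" for j in range(n_taxa)],
        ),
        keep_empty_taxa=True,
    )
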