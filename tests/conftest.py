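import numpy as np
import pandas as pd
import pytest

from phylocomm import CommunityMatrix, EnvTable, PhyloTree


@pytest.fixture
def toy_tree() -> PhyloTree:
    """Three tips with printed lengths: PD(all)=5, d(A,B)=2, d(A,C)=4."""
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_cm() -> CommunityMatrix:
    return CommunityMatrix(
        pd.DataFrame(
            [[3, 0], [1, 2]],
            index=pd.Index(["A", "B"], name="taxon_id"),
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def small_env() -> EnvTable:
    return EnvTable(
        pd.DataFrame(
            {
                "area": ["north", "north", "south", "south"],
                "TOC": [0.3, 0.35, 0.6, 0.65],
                "CPE": [0.2, 0.25, 0.8, 0.75],
                "Mud": [55.0, 60.0, 62.0, 58.0],
            },
            index=pd.Index(["n1", "n2", "s1", "s2"], name="sample_id"),
        )
    )


def make_cm(matrix, taxa=None, samples=None, taxonomy=None) -> CommunityMatrix:
    m = np.asarray(matrix)
    taxa = taxa or [f"t{i}" for i in range(m.shape[0])]
    samples = samples or [f"s{j}" for j in range(m.shape[1])]
    return CommunityMatrix(
        pd.DataFrame(m, index=pd.Index(taxa, name="taxon_id"), columns=samples),
        taxonomy=taxonomy,
    )
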