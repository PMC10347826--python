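import io

import numpy as np
import pytest
import skbio

from rarescape.io_formats import EnvTable, OtuTable, PhyloTree
from rarescape.phylo import DistanceMatrix


@pytest.fixture
def tiny_table():
    """3 samples x 4 OTUs, hand-checkable totals (sum = 100)."""
    counts = np.array([
        [10, 0, 5, 1],
        [20, 3, 0, 0],
        [40, 0, 20, 1],
    ])
    return OtuTable(
        sample_ids=["s1", "s2", "s3"],
        otu_ids=["otuA", "otuB", "otuC", "otuD"],
        counts=counts,
        fraction=["nano", "nano", "nano"],
        taxonomy={"otuA": "Alveolata;Dinoflagellata;X;Y",
                  "otuB": "Alveolata;Ciliophora;Z;W",
                  "otuC": "unclassified",
                  "otuD": "Stramenopiles;Ochrophyta;Q;R"},
    )


@pytest.fixture
def star_tree3():
    """Star tree: 3 tips A, B, C all at branch length 1 from the root."""
    return PhyloTree(skbio.TreeNode.read(io.StringIO("(A:1,B:1,C:1);")))


@pytest.fixture
def caterpillar_tree():
    """((A:1,B:1):1,C:2); d(A,B)=2, d(A,C)=d(B,C)=4."""
    return PhyloTree(skbio.TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);")))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_table(rng, n_samples, n_otus, depth=200, fraction="nano"):
    """Random non-degenerate OtuTable for oracle comparisons."""
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_otus)),
                             size=n_samples)
    # guarantee no empty sample
    counts[:, 0] += 1
    return OtuTable(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        otu_ids=[f"o{j}" for j in range(n_otus)],
        counts=counts,
        fraction=[fraction] * n_samples,
    )


def random_distance_matrix(rng, ids, scale=1.0, metric="cophenetic"):
    n = len(ids)
    x = rng.random((n, 3)) * scale
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix(list(ids), d, metric)


@pytest.fixture
def env4():
    import pandas as pd
    return EnvTable(
        ["s1", "s2", "s3", "s4"],
        pd.DataFrame({
            "temperature": [10.0, 12.0, 14.0, 16.0],
            "salinity": [33.0, 34.0, 35.0, 33.5],
        }, index=["s1", "s2", "s3", "s4"]),
    )
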