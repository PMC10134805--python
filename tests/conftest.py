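import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from genecat.catalog_io import AbundanceMatrix, PresenceMatrix, SampleTable


def presence_from_sets(memberships: dict) -> PresenceMatrix:
    """Build a PresenceMatrix from {sample_id: iterable of gene_ids}."""
    samples = sorted(memberships)
    genes = sorted({g for gs in memberships.values() for g in gs})
    gidx = {g: j for j, g in enumerate(genes)}
    mat = sp.lil_matrix((len(samples), len(genes)), dtype=np.int8)
    for i, s in enumerate(samples):
        for g in memberships[s]:
            mat[i, gidx[g]] = 1
    return PresenceMatrix(mat.tocsr(), samples, genes)


def sample_table(ecology_of: dict, group_of: dict | None = None) -> SampleTable:
    """Build a SampleTable from {sample_id: ecology} (+ optional ecology->group)."""
    group_of = group_of or {}
    df = pd.DataFrame(
        {
            "sample_id": list(ecology_of),
            "ecology": list(ecology_of.values()),
            "ecology_group": [group_of.get(e, e) for e in ecology_of.values()],
        }
    )
    return SampleTable(df)


def random_presence(rng, n_samples=20, n_genes=60, density=0.2) -> PresenceMatrix:
    """Random sparse binary matrix with every row and column nonempty."""
    mat = (rng.random((n_samples, n_genes)) < density).astype(np.int8)
    for j in np.flatnonzero(mat.sum(axis=0) == 0):
        mat[rng.integers(n_samples), j] = 1
    for i in np.flatnonzero(mat.sum(axis=1) == 0):
        mat[i, rng.integers(n_genes)] = 1
    return PresenceMatrix(
        sp.csr_matrix(mat),
        [f"s{i:03d}" for i in range(n_samples)],
        [f"g{j:03d}" for j in range(n_genes)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_pm():
    return presence_from_sets({"s1": {"g1", "g2"}, "s2": {"g1"}})
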