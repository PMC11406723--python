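import numpy as np
import pytest
import scipy.sparse as sp

from schictype.contacts import CellContactSet, ContactMatrix, GenomeSpec


@pytest.fixture
def toy_genome():
    """Two short chromosomes at 1 Mbp: 10 and 8 bins."""
    return GenomeSpec(("chrA", "chrB"), (10_000_000, 8_000_000), 1_000_000)


def make_cell(cell_id, genome, triplets):
    """Build a CellContactSet from {chrom: [(i, j, count), ...]} (upper triangle)."""
    matrices = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        rows, cols, vals = [], [], []
        for i, j, v in triplets.get(chrom, []):
            if i == j:
                rows.append(i); cols.append(j); vals.append(v)
            else:
                rows.extend((i, j)); cols.extend((j, i)); vals.extend((v, v))
        mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n), dtype=np.int64).tocsr()
        matrices[chrom] = ContactMatrix(chrom, n, mat)
    return CellContactSet(cell_id, matrices)


@pytest.fixture
def separable_embedding():
    """200 cells in two well-separated Gaussian blobs; linearly separable."""
    rng = np.random.default_rng(0)
    X = np.vstack([
        rng.normal(loc=-3.0, scale=0.5, size=(100, 5)),
        rng.normal(loc=+3.0, scale=0.5, size=(100, 5)),
    ])
    labels = ["alpha"] * 100 + ["beta"] * 100
    perm = rng.permutation(200)
    return X[perm], [labels[i] for i in perm]
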