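"""Synthetic single-cell Hi-C generator with type-specific contact structure.

The generator emulates the statistical features the pipeline relies on:

* genomic distance decay — the base contact probability between bins i and j
  falls off as (1 + |i - j|) ** (-decay_alpha);
* cell-type signal — each type multiplies a few seeded random contiguous
  blocks of the map by ``block_strength``, mimicking compartment-scale
  differences between cell types at coarse (Mb) resolution;
* sparsity — per-cell contact depths are drawn from a negative binomial
  whose mean sits near the QC threshold, and each cell's contacts are a
  multinomial sample from its type's map, so individual matrices are very
  sparse;
* type imbalance — ``cells_per_type`` can be skewed.

``generate_dataset`` serializes cells in the pairs dialect consumed by
:mod:`schictype.contacts` together with a chrom.sizes table and a labels
table, bit-reproducibly for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .contacts import CellContactSet, ContactMatrix, GenomeSpec

__all__ = ["SimParams", "make_population_maps", "sample_cell", "generate_cells", "generate_dataset"]


def _default_genome() -> GenomeSpec:
    # two toy chromosomes of 50 bins at 1 Mbp
    return GenomeSpec(("chr1", "chr2"), (50_000_000, 50_000_000), 1_000_000)


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults give a 4-type dataset with clear signal."""

    n_types: int = 4
    cells_per_type: tuple[int, ...] = (50, 50, 50, 50)
    genome: GenomeSpec = field(default_factory=_default_genome)
    decay_alpha: float = 1.0
    block_strength: float = 2.0
    blocks_per_type: int = 3
    depth_mean: float = 10_000.0
    depth_dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 1 or len(self.cells_per_type) != self.n_types:
            raise ValueError("cells_per_type must have n_types entries")
        if any(c < 1 for c in self.cells_per_type):
            raise ValueError("cells_per_type entries must be positive")
        if self.decay_alpha < 0 or self.block_strength <= 0 or self.blocks_per_type < 0:
            raise ValueError("decay_alpha >= 0, block_strength > 0, blocks_per_type >= 0 required")
        if self.depth_mean <= 0 or self.depth_dispersion < 0:
            raise ValueError("depth_mean > 0 and depth_dispersion >= 0 required")
        object.__setattr__(self, "cells_per_type", tuple(self.cells_per_type))

    @property
    def type_names(self) -> tuple[str, ...]:
        return tuple(f"type{t}" for t in range(self.n_types))


def make_population_maps(params: SimParams) -> dict[str, dict[str, np.ndarray]]:
    """Per-type, per-chromosome contact probability maps.

    Base matrix B_ij ~ (1 + |i-j|) ** (-decay_alpha); each type multiplies
    ``blocks_per_type`` seeded random contiguous diagonal blocks by
    ``block_strength``.  Each map is symmetric and its upper triangle
    (including the diagonal) sums to 1.
    """
    rng = np.random.default_rng(params.seed)
    maps: dict[str, dict[str, np.ndarray]] = {}
    for type_name in params.type_names:
        per_chrom = {}
        for chrom in params.genome.chrom_names:
            n = params.genome.n_bins(chrom)
            idx = np.arange(n)
            base = (1.0 + np.abs(idx[:, None] - idx[None, :])) ** (-params.decay_alpha)
            for _ in range(params.blocks_per_type):
                width = int(rng.integers(max(2, n // 10), max(3, n // 4) + 1))
                start = int(rng.integers(0, n - width + 1))
                sl = slice(start, start + width)
                base[sl, sl] *= params.block_strength
            base = (base + base.T) / 2.0
            base /= np.triu(base).sum()
            per_chrom[chrom] = base
        maps[type_name] = per_chrom
    return maps


def sample_cell(
    cell_id: str,
    type_map: dict[str, np.ndarray],
    depth: int,
    genome: GenomeSpec,
    rng: np.random.Generator,
) -> CellContactSet:
    """Draw ``depth`` contacts multinomially from the map's upper triangles.

    Chromosomes are weighted by their upper-triangle element counts, so each
    map is treated as one joint distribution over all intra-chromosomal bin
    pairs.  The result is a symmetric integer matrix per chromosome and
    ``total_contacts == depth`` exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    chroms = list(genome.chrom_names)
    # joint probability vector over all chromosomes' upper triangles
    triu_probs, triu_index = [], []
    for chrom in chroms:
        P = type_map[chrom]
        n = P.shape[0]
        iu = np.triu_indices(n)
        p = P[iu]
        triu_probs.append(p * len(p))  # weight by element count
        triu_index.append((chrom, iu))
    joint = np.concatenate(triu_probs)
    joint = joint / joint.sum()
    draws = rng.multinomial(depth, joint)

    matrices = {}
    offset = 0
    for chrom, iu in triu_index:
        n = genome.n_bins(chrom)
        m = len(iu[0])
        counts = draws[offset : offset + m]
        offset += m
        nz = counts > 0
        rows, cols, vals = iu[0][nz], iu[1][nz], counts[nz]
        upper = sp.coo_matrix((vals, (rows, cols)), shape=(n, n), dtype=np.int64)
        off_diag = rows != cols
        lower = sp.coo_matrix(
            (vals[off_diag], (cols[off_diag], rows[off_diag])), shape=(n, n), dtype=np.int64
        )
        matrices[chrom] = ContactMatrix(chrom, n, (upper + lower).tocsr())
    return CellContactSet(cell_id, matrices)


def _draw_depths(params: SimParams, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial-like depths: mean depth_mean, var = mu + phi * mu^2."""
    mu, phi = params.depth_mean, params.depth_dispersion
    if phi == 0:
        depths = rng.poisson(mu, size=n_cells)
    else:
        r = 1.0 / phi
        p = r / (r + mu)
        depths = rng.negative_binomial(r, p, size=n_cells)
    return np.maximum(depths, 1)


def generate_cells(params: SimParams) -> tuple[list[CellContactSet], dict[str, str], dict[str, int]]:
    """Sample all cells in memory; returns (cells, cell_id -> type, cell_id -> depth)."""
    rng = np.random.default_rng(params.seed + 1)
    maps = make_population_maps(params)
    cells, labels, depths_out = [], {}, {}
    counter = 0
    for type_name, n_cells in zip(params.type_names, params.cells_per_type):
        depths = _draw_depths(params, n_cells, rng)
        for d in depths:
            cell_id = f"cell{counter:05d}"
            counter += 1
            cells.append(sample_cell(cell_id, maps[type_name], int(d), params.genome, rng))
            labels[cell_id] = type_name
            depths_out[cell_id] = int(d)
    return cells, labels, depths_out


def _write_pairs(cells: list[CellContactSet], genome: GenomeSpec, path: Path, rng: np.random.Generator) -> None:
    R = genome.resolution
    lengths = genome.lengths
    with open(path, "w") as fh:
        fh.write("#cell_id\tchrom_a\tpos_a\tchrom_b\tpos_b\tcount\n")
        for cell in cells:
            for chrom, cm in cell.matrices.items():
                upper = sp.triu(cm.entries, k=0).tocoo()
                for i, j, v in zip(upper.row, upper.col, upper.data):
                    # one line per binned contact with a random position inside each bin
                    pos_a = int(i) * R + 1 + int(rng.integers(0, min(R, lengths[chrom] - int(i) * R)))
                    pos_b = int(j) * R + 1 + int(rng.integers(0, min(R, lengths[chrom] - int(j) * R)))
                    fh.write(f"{cell.cell_id}\t{chrom}\t{pos_a}\t{chrom}\t{pos_b}\t{int(v)}\n")


def generate_dataset(params: SimParams, out_dir: str | Path) -> dict[str, Path]:
    """Write pairs.tsv, chrom.sizes, and labels.tsv for a seeded synthetic dataset.

    Byte-identical for identical parameters.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells, labels, depths = generate_cells(params)
    rng = np.random.default_rng(params.seed + 2)

    pairs_path = out_dir / "pairs.tsv"
    _write_pairs(cells, params.genome, pairs_path, rng)

    sizes_path = out_dir / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for chrom, length in zip(params.genome.chrom_names, params.genome.chrom_lengths):
            fh.write(f"{chrom}\t{length}\n")

    labels_path = out_dir / "labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("cell_id\tcell_type\n")
        for cell in cells:
            fh.write(f"{cell.cell_id}\t{labels[cell.cell_id]}\n")

    depths_path = out_dir / "true_depths.tsv"
    with open(depths_path, "w") as fh:
        fh.write("cell_id\tdepth\n")
        for cell in cells:
            fh.write(f"{cell.cell_id}\t{depths[cell.cell_id]}\n")

    return {"pairs": pairs_path, "chrom_sizes": sizes_path, "labels": labels_path, "depths": depths_path}
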