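"""HDF5 container for per-cell, per-chromosome sparse contact matrices.

Layout::

    /genome                 attrs: resolution; datasets: chrom_names, chrom_lengths
    /<group>/<cell>/<chrom> datasets: row, col, count (triplets)

``group`` is ``raw`` for binned counts and ``imputed`` for dense imputation
output (stored as triplets of its nonzero entries, with shape and the
imputation parameters recorded as attributes).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp

from .contacts import CellContactSet, ContactMatrix, GenomeSpec
from .imputation import ImputationParams

__all__ = ["save_cells", "load_cells", "save_imputed", "load_imputed", "load_genome"]


def _write_genome(f: h5py.File, genome: GenomeSpec) -> None:
    if "genome" in f:
        return
    g = f.create_group("genome")
    g.attrs["resolution"] = genome.resolution
    g.create_dataset("chrom_names", data=np.array(genome.chrom_names, dtype="S"))
    g.create_dataset("chrom_lengths", data=np.array(genome.chrom_lengths, dtype=np.int64))


def load_genome(path: str | Path) -> GenomeSpec:
    with h5py.File(path, "r") as f:
        g = f["genome"]
        names = tuple(x.decode() for x in g["chrom_names"][:])
        lengths = tuple(int(x) for x in g["chrom_lengths"][:])
        return GenomeSpec(names, lengths, int(g.attrs["resolution"]))


def save_cells(path: str | Path, cells: list[CellContactSet], genome: GenomeSpec, group: str = "raw") -> None:
    with h5py.File(path, "a") as f:
        _write_genome(f, genome)
        if group in f:
            del f[group]
        root = f.create_group(group)
        for cell in cells:
            cg = root.create_group(cell.cell_id)
            for chrom, cm in cell.matrices.items():
                coo = sp.triu(cm.entries, k=0).tocoo()
                sub = cg.create_group(chrom)
                sub.create_dataset("row", data=coo.row.astype(np.int32))
                sub.create_dataset("col", data=coo.col.astype(np.int32))
                sub.create_dataset("count", data=coo.data.astype(np.float64))


def load_cells(path: str | Path, group: str = "raw") -> tuple[list[CellContactSet], GenomeSpec]:
    genome = load_genome(path)
    cells = []
    with h5py.File(path, "r") as f:
        root = f[group]
        for cell_id in root:
            matrices = {}
            for chrom in genome.chrom_names:
                n = genome.n_bins(chrom)
                sub = root[cell_id][chrom]
                rows, cols, vals = sub["row"][:], sub["col"][:], sub["count"][:]
                upper = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
                off = rows != cols
                lower = sp.coo_matrix((vals[off], (cols[off], rows[off])), shape=(n, n))
                matrices[chrom] = ContactMatrix(chrom, n, (upper + lower).tocsr().astype(np.int64))
            cells.append(CellContactSet(cell_id, matrices))
    cells.sort(key=lambda c: c.cell_id)
    return cells, genome


def save_imputed(
    path: str | Path,
    imputed: dict[str, dict[str, np.ndarray]],
    genome: GenomeSpec,
    params: ImputationParams,
    group: str = "imputed",
) -> None:
    with h5py.File(path, "a") as f:
        _write_genome(f, genome)
        if group in f:
            del f[group]
        root = f.create_group(group)
        for key, value in asdict(params).items():
            root.attrs[key] = value
        for cell_id, per_chrom in imputed.items():
            cg = root.create_group(cell_id)
            for chrom, M in per_chrom.items():
                coo = sp.coo_matrix(M)
                sub = cg.create_group(chrom)
                sub.attrs["n_bins"] = M.shape[0]
                sub.create_dataset("row", data=coo.row.astype(np.int32))
                sub.create_dataset("col", data=coo.col.astype(np.int32))
                sub.create_dataset("count", data=coo.data.astype(np.float64))


def load_imputed(path: str | Path, group: str = "imputed") -> dict[str, dict[str, np.ndarray]]:
    genome = load_genome(path)
    out: dict[str, dict[str, np.ndarray]] = {}
    with h5py.File(path, "r") as f:
        root = f[group]
        for cell_id in sorted(root):
            per_chrom = {}
            for chrom in genome.chrom_names:  # genome order, not hdf5 key order
                sub = root[cell_id][chrom]
                n = int(sub.attrs["n_bins"])
                M = np.zeros((n, n))
                M[sub["row"][:], sub["col"][:]] = sub["count"][:]
                per_chrom[chrom] = M
            out[cell_id] = per_chrom
    return out
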