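"""Read-pair ingestion, intra-chromosomal binning, and cell-level quality control.

Single-cell Hi-C yields one very sparse contact map per cell.  This module
turns a tab-delimited read-pairs table (cell id, chrom A, pos A, chrom B,
pos B [, count]) into per-cell, per-chromosome binned contact matrices at a
fixed resolution, and filters out low-quality cells: those with fewer than
``min_contacts`` total intra-chromosomal contacts, and those with at least
one chromosome carrying no read pair at all.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomeSpec",
    "PairRecord",
    "ContactMatrix",
    "CellContactSet",
    "PairsParseError",
    "read_chrom_sizes",
    "read_pairs",
    "bin_pairs",
    "total_contacts",
    "passes_qc",
    "filter_cells",
    "QCResult",
]

#: default bin width in base pairs (1 Mbp)
DEFAULT_RESOLUTION = 1_000_000

#: default minimum total contacts for a cell to pass QC
DEFAULT_MIN_CONTACTS = 5000


class PairsParseError(ValueError):
    """A malformed line in a pairs file, annotated with its line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names, lengths (bp), and the binning resolution.

    The number of bins per chromosome is ``n = ceil(L / R)`` so that the
    chromosome tail shorter than one full bin is retained; every valid
    position then falls inside some bin.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(self.chrom_names) == 0:
            raise ValueError("at least one chromosome required")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def n_bins(self, chrom: str) -> int:
        """Number of non-overlapping bins for ``chrom``: ceil(L / R)."""
        return math.ceil(self.lengths[chrom] / self.resolution)

    def bin_index(self, chrom: str, pos: int) -> int:
        """0-based bin for a 1-based position: floor((pos - 1) / R)."""
        return (pos - 1) // self.resolution

    @classmethod
    def from_chrom_sizes(cls, path: str | Path, resolution: int = DEFAULT_RESOLUTION) -> "GenomeSpec":
        names, lengths = read_chrom_sizes(path)
        return cls(tuple(names), tuple(lengths), resolution)


def read_chrom_sizes(path: str | Path) -> tuple[list[str], list[int]]:
    """Parse a standard two-column chrom.sizes table (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"], dtype={"chrom": str})
    return df["chrom"].tolist(), df["length"].astype(int).tolist()


@dataclass(frozen=True)
class PairRecord:
    """One read pair: two genomic positions observed in contact in one cell."""

    cell_id: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    count: int = 1

    @property
    def is_intra(self) -> bool:
        return self.chrom_a == self.chrom_b


@dataclass
class ContactMatrix:
    """Symmetric sparse contact-count matrix for one chromosome of one cell."""

    chrom: str
    n_bins: int
    entries: sp.csr_matrix

    def __post_init__(self):
        if self.entries.shape != (self.n_bins, self.n_bins):
            raise ValueError(
                f"matrix shape {self.entries.shape} does not match n_bins={self.n_bins}"
            )

    @property
    def is_symmetric(self) -> bool:
        diff = self.entries - self.entries.T
        return diff.nnz == 0 or np.abs(diff.data).max() == 0

    def upper_triangle_sum(self) -> int:
        """Total unique contact mass: upper triangle including the diagonal."""
        return int(sp.triu(self.entries, k=0).sum())

    def toarray(self) -> np.ndarray:
        return self.entries.toarray()


@dataclass
class CellContactSet:
    """All per-chromosome contact matrices of one cell."""

    cell_id: str
    matrices: dict[str, ContactMatrix]

    @property
    def total_contacts(self) -> int:
        return total_contacts(self)

    def chrom_is_empty(self, chrom: str) -> bool:
        return self.matrices[chrom].entries.nnz == 0


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_pairs(
    path: str | Path,
    genome: GenomeSpec,
    on_error: str = "raise",
) -> Iterator[PairRecord]:
    """Stream validated :class:`PairRecord` rows from a tab-delimited pairs file.

    Expected columns: cell_id, chrom_a, pos_a, chrom_b, pos_b and an optional
    sixth count column.  Lines starting with ``#`` are comments.  Positions are
    1-based.  ``on_error`` is ``"raise"`` (abort on the first bad record) or
    ``"skip"`` (warn with the line number and continue).
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    lengths = genome.lengths

    def _fail(msg: str, lineno: int):
        err = PairsParseError(msg, lineno)
        if on_error == "raise":
            raise err
        warnings.warn(f"skipping {err}", stacklevel=2)

    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                _fail(f"expected >=5 tab-separated columns, got {len(fields)}", lineno)
                continue
            cell_id, chrom_a, pos_a_s, chrom_b, pos_b_s = fields[:5]
            try:
                pos_a, pos_b = int(pos_a_s), int(pos_b_s)
                count = int(fields[5]) if len(fields) > 5 and fields[5] != "" else 1
            except ValueError:
                _fail(f"non-integer coordinate or count: {line!r}", lineno)
                continue
            ok = True
            for chrom, pos in ((chrom_a, pos_a), (chrom_b, pos_b)):
                if chrom not in lengths:
                    _fail(f"unknown chromosome {chrom!r}", lineno)
                    ok = False
                    break
                if not (1 <= pos <= lengths[chrom]):
                    _fail(f"position {pos} outside [1, {lengths[chrom]}] on {chrom}", lineno)
                    ok = False
                    break
            if not ok:
                continue
            if count < 1:
                _fail(f"count must be >= 1, got {count}", lineno)
                continue
            yield PairRecord(cell_id, chrom_a, pos_a, chrom_b, pos_b, count)


def bin_pairs(pairs: Iterable[PairRecord], genome: GenomeSpec) -> dict[str, CellContactSet]:
    """Accumulate intra-chromosomal read pairs into binned contact matrices.

    Inter-chromosomal records are discarded.  Each count is added symmetrically
    at (i, j) and (j, i); diagonal contacts are counted once.  Returns one
    :class:`CellContactSet` per distinct cell id, keyed by cell id, in first-seen
    order.
    """
    # per cell, per chrom: triplet lists
    acc: dict[str, dict[str, tuple[list[int], list[int], list[int]]]] = {}
    for rec in pairs:
        if not rec.is_intra:
            continue
        chrom = rec.chrom_a
        i = genome.bin_index(chrom, rec.pos_a)
        j = genome.bin_index(chrom, rec.pos_b)
        cell = acc.setdefault(rec.cell_id, {})
        rows, cols, vals = cell.setdefault(chrom, ([], [], []))
        if i == j:
            rows.append(i)
            cols.append(j)
            vals.append(rec.count)
        else:
            rows.extend((i, j))
            cols.extend((j, i))
            vals.extend((rec.count, rec.count))

    out: dict[str, CellContactSet] = {}
    for cell_id, per_chrom in acc.items():
        matrices = {}
        for chrom in genome.chrom_names:
            n = genome.n_bins(chrom)
            if chrom in per_chrom:
                rows, cols, vals = per_chrom[chrom]
                mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n), dtype=np.int64).tocsr()
                mat.sum_duplicates()
            else:
                mat = sp.csr_matrix((n, n), dtype=np.int64)
            matrices[chrom] = ContactMatrix(chrom, n, mat)
        out[cell_id] = CellContactSet(cell_id, matrices)
    return out


def total_contacts(cell: CellContactSet) -> int:
    """Unique contact mass of a cell: upper triangle + diagonal, summed over chromosomes."""
    return sum(m.upper_triangle_sum() for m in cell.matrices.values())


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


def passes_qc(cell: CellContactSet, min_contacts: int = DEFAULT_MIN_CONTACTS) -> QCResult:
    """Cell-level quality control.

    A cell passes iff it has at least ``min_contacts`` total contacts
    (LOW_DEPTH otherwise) and every chromosome matrix holds at least one
    read pair (EMPTY_CHROM otherwise).
    """
    reasons = []
    if total_contacts(cell) < min_contacts:
        reasons.append("LOW_DEPTH")
    if any(cell.chrom_is_empty(c) for c in cell.matrices):
        reasons.append("EMPTY_CHROM")
    return QCResult(passed=not reasons, reasons=tuple(reasons))


def filter_cells(
    cells: Iterable[CellContactSet],
    min_contacts: int = DEFAULT_MIN_CONTACTS,
) -> tuple[list[CellContactSet], list[tuple[CellContactSet, QCResult]]]:
    """Partition cells into (kept, removed-with-reasons), preserving order."""
    kept: list[CellContactSet] = []
    removed: list[tuple[CellContactSet, QCResult]] = []
    for cell in cells:
        res = passes_qc(cell, min_contacts)
        if res.passed:
            kept.append(cell)
        else:
            removed.append((cell, res))
    return kept, removed
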