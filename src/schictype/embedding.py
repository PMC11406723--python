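"""Two-stage PCA cell embedding.

Each chromosome's imputed matrices are vectorized (upper triangle including
the diagonal) across cells and reduced by PCA; the per-chromosome score
blocks are concatenated in genome order and a second PCA produces the final
per-cell embedding that feeds the classifier.

Fitted transforms are stored so held-out cells can be projected without
refitting (inductive use); fitting on all cells jointly (transductive) is
simply a matter of which cells are passed to :meth:`CellEmbedder.fit`.

PCA signs are pinned by forcing the largest-magnitude loading of every
component to be positive, making the whole pipeline bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "EmbedParams",
    "EmbeddingMatrix",
    "flatten_chrom",
    "unflatten_chrom",
    "pca_embed",
    "combine_embeddings",
    "CellEmbedder",
    "embed_cells",
]

Stage = Literal["per-chromosome", "concatenated", "final"]


@dataclass(frozen=True)
class EmbedParams:
    """k_chrom: components per chromosome; k_cell: final components."""

    k_chrom: int = 10
    k_cell: int = 20
    scale: bool = False

    def __post_init__(self):
        if self.k_chrom < 1 or self.k_cell < 1:
            raise ValueError("component counts must be >= 1")


@dataclass
class EmbeddingMatrix:
    """M cells x N features with an ordered cell index and a stage tag."""

    cell_ids: tuple[str, ...]
    features: np.ndarray
    stage: str

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.cell_ids):
            raise ValueError("features must be 2-D with one row per cell")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        self.cell_ids = tuple(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def flatten_chrom(
    matrices: Sequence[np.ndarray], cell_ids: Sequence[str]
) -> EmbeddingMatrix:
    """Vectorize one chromosome across cells.

    Each cell's symmetric matrix contributes its upper triangle (including
    the diagonal) flattened row-wise, giving n(n+1)/2 features in a fixed
    order.
    """
    if len(matrices) != len(cell_ids):
        raise ValueError("one matrix per cell id required")
    if len(matrices) == 0:
        raise ValueError("at least one cell required")
    n = matrices[0].shape[0]
    iu = np.triu_indices(n)
    rows = []
    for m in matrices:
        m = np.asarray(m)
        if m.shape != (n, n):
            raise ValueError(f"inconsistent matrix shape {m.shape}, expected ({n}, {n})")
        rows.append(m[iu])
    return EmbeddingMatrix(tuple(cell_ids), np.vstack(rows), stage="per-chromosome")


def unflatten_chrom(row: np.ndarray, n_bins: int) -> np.ndarray:
    """Rebuild the symmetric n x n matrix from one flattened feature row."""
    iu = np.triu_indices(n_bins)
    M = np.zeros((n_bins, n_bins))
    M[iu] = row
    M = M + M.T - np.diag(np.diag(M))
    return M


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Force the largest-magnitude loading of each component to be positive."""
    for c in range(components.shape[0]):
        j = np.argmax(np.abs(components[c]))
        if components[c, j] < 0:
            components[c] *= -1.0
            scores[:, c] *= -1.0
    return components, scores


@dataclass
class PCATransform:
    """A fitted, sign-pinned PCA usable for out-of-sample projection."""

    mean: np.ndarray
    components: np.ndarray  # k x N
    explained_variance_ratio: np.ndarray
    scale: np.ndarray | None = None

    def project(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xc = X - self.mean
        if self.scale is not None:
            Xc = Xc / self.scale
        return Xc @ self.components.T


def _fit_pca(X: np.ndarray, k: int, scale: bool = False) -> tuple[PCATransform, np.ndarray]:
    M, N = X.shape
    if not (1 <= k <= min(M, N)):
        raise ValueError(f"k={k} must satisfy 1 <= k <= min(M={M}, N={N})")
    if M < 2:
        raise ValueError("PCA requires at least 2 cells")
    mean = X.mean(axis=0)
    Xw = X - mean
    scale_vec = None
    if scale:
        scale_vec = X.std(axis=0, ddof=0)
        scale_vec = np.where(scale_vec > 0, scale_vec, 1.0)
        Xw = Xw / scale_vec
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xw)
    components, scores = _fix_signs(pca.components_.copy(), scores)
    transform = PCATransform(
        mean=mean,
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scale=scale_vec,
    )
    return transform, scores


def pca_embed(X: EmbeddingMatrix, k: int, scale: bool = False) -> EmbeddingMatrix:
    """Leading-k principal-component scores of the column-centered features.

    Deterministic: per-component sign is pinned by the largest-magnitude
    loading.
    """
    _, scores = _fit_pca(X.features, k, scale=scale)
    return EmbeddingMatrix(X.cell_ids, scores, stage="pca")


def combine_embeddings(per_chrom: Sequence[EmbeddingMatrix]) -> EmbeddingMatrix:
    """Horizontally concatenate per-chromosome embeddings (same cell order)."""
    if len(per_chrom) == 0:
        raise ValueError("nothing to combine")
    ids = per_chrom[0].cell_ids
    for e in per_chrom[1:]:
        if e.cell_ids != ids:
            raise ValueError("cell order mismatch between chromosome embeddings")
    return EmbeddingMatrix(ids, np.hstack([e.features for e in per_chrom]), stage="concatenated")


class CellEmbedder:
    """Fits the two-stage PCA and projects new cells through the stored maps.

    ``fit`` consumes ``{cell_id: {chrom: imputed matrix}}``; chromosome order
    is taken from the order supplied (pass ``chrom_order`` to pin it).
    """

    def __init__(self, params: EmbedParams | None = None, chrom_order: Sequence[str] | None = None):
        self.params = params or EmbedParams()
        self.chrom_order = list(chrom_order) if chrom_order is not None else None
        self.chrom_transforms: dict[str, PCATransform] = {}
        self.final_transform: PCATransform | None = None
        self._n_bins: dict[str, int] = {}

    @property
    def is_fitted(self) -> bool:
        return self.final_transform is not None

    def _resolve_chroms(self, cells: Mapping[str, Mapping[str, np.ndarray]]) -> list[str]:
        if self.chrom_order is not None:
            return self.chrom_order
        first = next(iter(cells.values()))
        return list(first.keys())

    def _chrom_feature_blocks(
        self, cells: Mapping[str, Mapping[str, np.ndarray]], chroms: list[str]
    ) -> tuple[tuple[str, ...], dict[str, EmbeddingMatrix]]:
        cell_ids = tuple(cells.keys())
        blocks = {}
        for chrom in chroms:
            mats = [cells[cid][chrom] for cid in cell_ids]
            blocks[chrom] = flatten_chrom(mats, cell_ids)
        return cell_ids, blocks

    def fit(self, cells: Mapping[str, Mapping[str, np.ndarray]]) -> EmbeddingMatrix:
        """Fit both PCA stages on these cells and return their final embedding."""
        if len(cells) < 2:
            raise ValueError("embedding requires at least 2 cells")
        chroms = self._resolve_chroms(cells)
        self.chrom_order = chroms
        cell_ids, blocks = self._chrom_feature_blocks(cells, chroms)
        per_chrom_scores = []
        for chrom in chroms:
            block = blocks[chrom]
            self._n_bins[chrom] = int((np.sqrt(8 * block.n_features + 1) - 1) / 2)
            k = min(self.params.k_chrom, min(block.n_cells, block.n_features))
            transform, scores = _fit_pca(block.features, k, scale=self.params.scale)
            self.chrom_transforms[chrom] = transform
            per_chrom_scores.append(EmbeddingMatrix(cell_ids, scores, stage="per-chromosome"))
        concat = combine_embeddings(per_chrom_scores)
        k_cell = min(self.params.k_cell, min(concat.n_cells, concat.n_features))
        self.final_transform, final_scores = _fit_pca(concat.features, k_cell, scale=False)
        return EmbeddingMatrix(cell_ids, final_scores, stage="final")

    def transform(self, cells: Mapping[str, Mapping[str, np.ndarray]]) -> EmbeddingMatrix:
        """Project (held-out) cells through the fitted transforms."""
        if not self.is_fitted:
            raise RuntimeError("CellEmbedder must be fitted first")
        cell_ids, blocks = self._chrom_feature_blocks(cells, self.chrom_order)
        parts = []
        for chrom in self.chrom_order:
            parts.append(self.chrom_transforms[chrom].project(blocks[chrom].features))
        concat = np.hstack(parts)
        return EmbeddingMatrix(cell_ids, self.final_transform.project(concat), stage="final")


def embed_cells(
    cells: Mapping[str, Mapping[str, np.ndarray]],
    params: EmbedParams | None = None,
    chrom_order: Sequence[str] | None = None,
) -> tuple[EmbeddingMatrix, CellEmbedder]:
    """Fit the two-stage PCA on all given cells; returns (embedding, fitted embedder)."""
    embedder = CellEmbedder(params, chrom_order)
    emb = embedder.fit(cells)
    return emb, embedder
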