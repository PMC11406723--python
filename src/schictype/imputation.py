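"""Contact-matrix imputation: mean-filter convolution, then random walk with restart.

A single cell's binned contact matrix is extremely sparse; direct embedding
of raw counts is dominated by sampling noise.  Two deterministic smoothing
steps densify each chromosome's matrix before PCA:

1. a (2*pad+1)^2 mean-filter convolution with zero padding, which shares
   counts between neighbouring bins, and
2. a random walk with restart (RWR) over the row-normalized contact graph,
   whose stationary matrix ``Q`` mixes local and global connectivity:

       Q_{t+1} = p * Q_t * P + (1 - p) * I,      Q_0 = I,

   with restart probability ``1 - p`` and ``P`` the row-stochastic transition
   matrix.  Rows of ``Q_t`` remain stochastic at every step, and the fixed
   point is symmetrized as (Q + Q^T) / 2.

An optional final step keeps the top fraction of entries as a 0/1 matrix,
which discards the diffusion magnitudes and retains only topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .contacts import CellContactSet, ContactMatrix

__all__ = ["ImputationParams", "convolve", "rwr", "binarize_top", "impute_cell"]


@dataclass(frozen=True)
class ImputationParams:
    """Parameters of the convolution + RWR imputation.

    window_pad
        mean-filter half-width; 1 gives a 3x3 window.
    restart_prob
        the walk continuation weight ``p`` in (0, 1); each step restarts with
        probability ``1 - p``.
    tol, max_iter
        convergence threshold on the maximum row-wise L1 change, and the
        iteration cap.
    top_fraction, binarize
        keep the top fraction of entries as ones when ``binarize`` is set.
    """

    window_pad: int = 1
    restart_prob: float = 0.5
    tol: float = 1e-6
    max_iter: int = 30
    top_fraction: float = 0.2
    binarize: bool = True

    def __post_init__(self):
        if self.window_pad < 0:
            raise ValueError("window_pad must be >= 0")
        if not (0.0 < self.restart_prob < 1.0):
            raise ValueError("restart_prob must be in (0, 1)")
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


def convolve(matrix: np.ndarray | ContactMatrix, pad: int = 1) -> np.ndarray:
    """Mean-filter smoothing: each cell becomes the mean of its (2*pad+1)^2 window.

    Borders are zero-padded and the divisor stays the full window size, so
    edge values shrink.  ``pad=0`` is the identity.  Symmetric input gives
    symmetric output.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    X = matrix.toarray() if isinstance(matrix, ContactMatrix) else np.asarray(matrix)
    X = X.astype(float)
    if pad == 0:
        return X.copy()
    w = 2 * pad + 1
    kernel = np.full((w, w), 1.0 / (w * w))
    return convolve2d(X, kernel, mode="same", boundary="fill", fillvalue=0.0)


def _row_normalize(A: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrix; all-zero rows become identity rows."""
    A = np.asarray(A, dtype=float)
    row_sums = A.sum(axis=1)
    P = np.zeros_like(A)
    nonzero = row_sums > 0
    P[nonzero] = A[nonzero] / row_sums[nonzero, None]
    zero_idx = np.flatnonzero(~nonzero)
    P[zero_idx, zero_idx] = 1.0
    return P


def rwr(
    matrix: np.ndarray,
    restart_prob: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 30,
    return_iterations: bool = False,
    symmetrize: bool = True,
) -> np.ndarray | tuple[np.ndarray, int]:
    """Random walk with restart to a fixed point, symmetrized.

    Iterates ``Q <- p Q P + (1-p) I`` from ``Q = I`` until the maximum
    row-wise L1 change drops below ``tol`` or ``max_iter`` is hit, then
    returns ``(Q + Q^T) / 2`` (or the raw row-stochastic ``Q`` with
    ``symmetrize=False``).
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("rwr requires a square matrix")
    if np.any(A < 0):
        raise ValueError("rwr requires a nonnegative matrix")
    p = restart_prob
    n = A.shape[0]
    P = _row_normalize(A)
    I = np.eye(n)
    Q = I.copy()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        Q_next = p * (Q @ P) + (1.0 - p) * I
        delta = np.abs(Q_next - Q).sum(axis=1).max()
        Q = Q_next
        if delta < tol:
            break
    if symmetrize:
        Q = (Q + Q.T) / 2.0
    if return_iterations:
        return Q, iterations
    return Q


def binarize_top(matrix: np.ndarray, top_fraction: float = 0.2) -> np.ndarray:
    """Keep the top ``ceil(fraction * n^2)`` entries as 1, the rest as 0.

    Ties at the cutoff are broken by (row, col) order so the result is
    deterministic.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    X = np.asarray(matrix, dtype=float)
    n_keep = int(np.ceil(top_fraction * X.size))
    flat = X.ravel()  # C order == (row, col) order
    # stable sort by descending value; stability gives (row, col) tie-breaking
    order = np.argsort(-flat, kind="stable")
    out = np.zeros(X.size)
    out[order[:n_keep]] = 1.0
    return out.reshape(X.shape)


def impute_cell(cell: CellContactSet, params: ImputationParams | None = None) -> dict[str, np.ndarray]:
    """Convolve -> RWR -> (optionally) binarize every chromosome of a cell.

    Fully deterministic given ``params``; returns dense real matrices keyed
    by chromosome.
    """
    params = params or ImputationParams()
    out: dict[str, np.ndarray] = {}
    for chrom, mat in cell.matrices.items():
        smoothed = convolve(mat, params.window_pad)
        walked = rwr(smoothed, params.restart_prob, params.tol, params.max_iter)
        if params.binarize:
            walked = binarize_top(walked, params.top_fraction)
        out[chrom] = walked
    return out
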