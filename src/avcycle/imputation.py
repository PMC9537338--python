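"""Diffusion-based expression smoothing by powering a cell-cell Markov operator.

Dropout-heavy single-cell matrices are smoothed by sharing information along
the cell-cell affinity graph: distances are measured in a truncated PCA
embedding of the log-normalized matrix, an adaptive Gaussian kernel with
bandwidth set by each cell's ka-th neighbor is symmetrized and
row-normalized into a Markov operator M, and expression is replaced by
M^t x (default t = 4).  Row-stochasticity makes imputed values convex
combinations of observed ones: constants are preserved exactly and
per-gene variance never increases with t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

__all__ = ["DiffusionOperator", "build_operator", "operator_from_distances", "impute"]


@dataclass
class DiffusionOperator:
    """Row-stochastic cell-cell Markov matrix with its construction parameters."""

    markov: np.ndarray
    k: int
    ka: int
    t: int = 4
    embedding_dims: int = 20

    def validate(self) -> None:
        M = self.markov
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("markov must be square")
        if np.any(M < 0):
            raise ValueError("markov entries must be nonnegative")
        if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("markov rows must sum to 1 within 1e-9")
        if self.t < 0 or int(self.t) != self.t:
            raise ValueError("t must be a nonnegative integer")


def operator_from_distances(dist: np.ndarray, k: int = 15, ka: int = 4) -> np.ndarray:
    """Markov operator from a precomputed cell-cell distance matrix.

    Affinity A_ij = exp(-(d_ij / sigma_i)^2) for j in {i} ∪ kNN(i), with the
    adaptive bandwidth sigma_i equal to the distance to i's ka-th nearest
    other cell; A is symmetrized as (A + A^T)/2 and row-normalized.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if k <= ka:
        raise ValueError(f"k ({k}) must exceed ka ({ka})")
    if n <= k:
        raise ValueError(f"need more cells ({n}) than neighbors k ({k})")

    order = np.argsort(d, axis=1, kind="stable")
    # drop self (distance 0 sorts first; ties broken stably by index)
    neigh = np.empty((n, k), dtype=int)
    sigma = np.empty(n)
    for i in range(n):
        others = order[i][order[i] != i][:k]
        neigh[i] = others
        sigma[i] = d[i, others[ka - 1]]
    tiny = np.finfo(float).tiny ** 0.25
    if np.any(sigma <= 0):
        warnings.warn("duplicate cells produced zero bandwidth; flooring sigma")
        sigma = np.maximum(sigma, tiny)

    A = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    cols = neigh.ravel()
    A[rows, cols] = np.exp(-((d[rows, cols] / sigma[rows]) ** 2))
    A[np.arange(n), np.arange(n)] = 1.0  # self-affinity, d = 0
    A = 0.5 * (A + A.T)
    return A / A.sum(axis=1, keepdims=True)


def build_operator(
    expr_lognorm,
    k: int = 15,
    ka: int = 4,
    embedding_dims: int = 20,
    t: int = 4,
) -> DiffusionOperator:
    """Build the diffusion operator from a cells x genes log-normalized matrix.

    Distances are Euclidean in a truncated principal-component embedding
    (at most ``embedding_dims`` components; deterministic full SVD).
    """
    X = np.asarray(expr_lognorm, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix must be finite")
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more cells ({n}) than neighbors k ({k})")
    dims = min(embedding_dims, n - 1, X.shape[1])
    emb = PCA(n_components=dims, svd_solver="full").fit_transform(X)
    dist = squareform(pdist(emb))
    M = operator_from_distances(dist, k=k, ka=ka)
    op = DiffusionOperator(markov=M, k=k, ka=ka, t=t, embedding_dims=dims)
    op.validate()
    return op


def impute(expr, op: DiffusionOperator, t: int = None):
    """Smooth expression as M^t x (t = 0 returns the input unchanged).

    Powers are applied by repeated multiplication — t is small in practice.
    Preserves the input's container: a DataFrame comes back as a DataFrame.
    """
    steps = op.t if t is None else int(t)
    if steps < 0:
        raise ValueError("t must be >= 0")
    values = np.asarray(expr, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
        squeeze = True
    else:
        squeeze = False
    if op.markov.shape[0] != values.shape[0]:
        raise ValueError(
            f"operator is for {op.markov.shape[0]} cells but matrix has {values.shape[0]} rows"
        )
    out = values.copy()
    for _ in range(steps):
        out = op.markov @ out
    if squeeze:
        out = out[:, 0]
    if hasattr(expr, "index") and hasattr(expr, "columns"):
        import pandas as pd

        return pd.DataFrame(out, index=expr.index, columns=expr.columns)
    return out
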