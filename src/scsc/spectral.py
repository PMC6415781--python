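"""Graph Laplacian construction and the dissimilarity-maximizing eigenproblem.

The coloring merit of a scalar assignment ``x`` over states is

    z = 1/2 * sum_ij (x_i - x_j)^2 a_ij,

the dissimilarity-weighted squared spread of the assignment.  Maximizing z
subject to a finite-norm constraint leads to the generalized eigenproblem

    L X = lambda D X,

with ``D`` the diagonal of row sums of the dissimilarity matrix ``A`` and
``L = D - A`` the graph Laplacian.  Because ``A`` stores *dissimilarities*,
the informative solutions are those with the **largest** eigenvalues; the
constant vector is always an eigenvector with eigenvalue zero.

Under the normalization ``X_k^T D X_k = 1`` used here, the merit of the
k-th eigenvector equals its eigenvalue: ``z(X_k) = X_k^T L X_k = lambda_k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .dissimilarity import AdjacencyMatrix
from .errors import ConvergenceError, InputError, ZeroDegreeError

__all__ = [
    "SpectralSolution",
    "degree_and_laplacian",
    "solve_coloring",
    "coloring_merit",
]


@dataclass
class SpectralSolution:
    """All generalized eigenpairs of ``(L, D)``, sorted by descending eigenvalue.

    Attributes
    ----------
    eigenvalues
        ``lambda_1 >= ... >= lambda_n >= 0``; the last is zero (constant mode).
    eigenvectors
        Column ``k`` is ``X_k``, normalized to ``X_k^T D X_k = 1`` and
        D-orthogonal to the other columns.  The sign is fixed so that the
        largest-magnitude entry of each column is positive (the sign of an
        eigenvector is otherwise arbitrary; downstream logic is sign-blind).
    degrees
        Row sums of the dissimilarity matrix (diagonal of ``D``).
    merit_values
        Coloring merit ``z(X_k)``; equals ``eigenvalues`` up to round-off.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    degrees: np.ndarray
    merit_values: np.ndarray

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]


def degree_and_laplacian(A: AdjacencyMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Return the degree vector (row sums of ``A``) and ``L = D - A``.

    Every row of ``L`` sums to zero.  A zero-degree row means a state with
    no measurable dissimilarity to any other state and is rejected.
    """
    degrees = A.values.sum(axis=1)
    if np.any(degrees <= 0):
        bad = np.flatnonzero(degrees <= 0)
        raise ZeroDegreeError(
            f"state(s) {bad.tolist()} have zero total dissimilarity; "
            "remove or merge duplicate states before solving"
        )
    L = np.diag(degrees) - A.values
    return degrees, L


def solve_coloring(A: AdjacencyMatrix, tol: float = 1e-8) -> SpectralSolution:
    """Solve ``L X = lambda D X`` for all ``n`` eigenpairs.

    The problem is symmetrized as ``D^{-1/2} L D^{-1/2}`` and solved densely
    (problem sizes of interest are a few thousand states), which yields
    D-orthonormal eigenvectors directly.  Residuals
    ``||L X_k - lambda_k D X_k||`` are checked against ``tol * ||D X_k||``.
    """
    if tol <= 0:
        raise InputError("tol must be positive")
    degrees, L = degree_and_laplacian(A)
    s = 1.0 / np.sqrt(degrees)
    M = L * s[:, None] * s[None, :]
    M = 0.5 * (M + M.T)
    w, V = scipy.linalg.eigh(M)
    X = V * s[:, None]  # X^T D X = I
    order = np.argsort(w)[::-1]
    w = w[order]
    X = X[:, order]
    # round-off can leave tiny negative eigenvalues near the constant mode
    w[(w < 0) & (w > -1e-10 * max(1.0, abs(w[0])))] = 0.0
    # canonical sign: largest-magnitude entry positive
    idx = np.argmax(np.abs(X), axis=0)
    signs = np.sign(X[idx, np.arange(X.shape[1])])
    signs[signs == 0] = 1.0
    X *= signs[None, :]

    DX = X * degrees[:, None]
    R = L @ X - DX * w[None, :]
    res = np.linalg.norm(R, axis=0)
    bound = tol * np.linalg.norm(DX, axis=0)
    if np.any(res > bound):
        worst = float(np.max(res / np.maximum(bound, np.finfo(float).tiny)))
        raise ConvergenceError(
            f"eigensolve residual exceeds tolerance {tol:g} "
            f"(worst relative residual {worst:.3g} x tol)",
            worst_residual=float(res.max()),
        )
    merits = np.einsum("ij,ij->j", X, L @ X)
    return SpectralSolution(
        eigenvalues=w, eigenvectors=X, degrees=degrees, merit_values=merits
    )


def coloring_merit(
    X, A: AdjacencyMatrix, subset=None
) -> float:
    """Coloring merit ``1/2 sum_ij (x_i - x_j)^2 a_ij`` over a state subset.

    With no subset the sum runs over all states; for a normalized
    eigenvector this equals its eigenvalue.  Empty and singleton subsets
    have zero merit.  ``X`` is always the *globally* defined assignment;
    only the summation range is restricted.
    """
    x = np.asarray(X, dtype=float)
    n = A.n
    if x.shape != (n,):
        raise InputError(f"X must have length n={n}; got shape {x.shape}")
    if subset is None:
        a = A.values
        xs = x
    else:
        idx = np.asarray(subset, dtype=int)
        if idx.ndim != 1:
            raise InputError("subset must be a 1-D collection of state indices")
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise InputError(f"subset indices out of range for n={n}")
        if np.unique(idx).size != idx.size:
            raise InputError("subset contains repeated indices")
        if idx.size <= 1:
            return 0.0
        a = A.values[np.ix_(idx, idx)]
        xs = x[idx]
    # 1/2 sum (xi-xj)^2 a_ij = sum_i d_i x_i^2 - x^T A x  with subset row sums d
    d = a.sum(axis=1)
    return float(np.dot(xs * xs, d) - np.dot(xs, a @ xs))
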