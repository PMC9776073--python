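"""Graph Laplacians and Chebyshev-polynomial graph convolution.

The spectral graph filter g_theta acting on node features X is
approximated by a K-order Chebyshev expansion in the rescaled Laplacian
L~ = 2 L / lambda_max - I, computed by the three-term recursion
T_0 = I, T_1 = L~, T_k = 2 L~ T_{k-1} - T_{k-2} with no
eigendecomposition.  The recursion applies verbatim to the asymmetric
Laplacians arising from directed (Granger) adjacencies; lambda_max is
then taken from the symmetrized part, and an optional symmetrization of
the adjacency is available for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: lambda_max floor guarding against division by zero on empty graphs.
LAMBDA_MAX_FLOOR = 1e-6


class GraphError(ValueError):
    pass


@dataclass
class LaplacianBundle:
    """L = D - A with D = diag(row sums of A), plus its rescaled form."""

    L: np.ndarray
    L_tilde: np.ndarray
    lambda_max: float


def symmetrize(A: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Symmetrize a directed adjacency: ``mean`` -> (A + A^T)/2,
    ``binary`` -> 1 wherever either direction is nonzero."""
    A = np.asarray(A, dtype=float)
    if mode == "mean":
        return (A + A.T) / 2.0
    if mode == "binary":
        return ((A + A.T) > 0).astype(float)
    raise GraphError(f"unknown symmetrize mode '{mode}'")


def laplacian(A: np.ndarray, lambda_max: float | str = "auto") -> LaplacianBundle:
    """Graph Laplacian of a (possibly asymmetric, weighted) adjacency.

    Degrees are row sums, i.e. incoming mass under the convention that
    A[i, j] carries the influence j -> i.  With ``lambda_max="auto"``
    the rescaling constant is the largest eigenvalue of the symmetrized
    Laplacian (L + L^T)/2, floored at a small positive value.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise GraphError("adjacency must be square")
    if np.any(A < 0):
        raise GraphError("adjacency entries must be non-negative")
    n = A.shape[0]
    L = np.diag(A.sum(axis=1)) - A
    if lambda_max == "auto":
        lam = float(np.linalg.eigvalsh((L + L.T) / 2.0).max())
    else:
        lam = float(lambda_max)
        if lam <= 0:
            raise GraphError("lambda_max must be positive")
    lam = max(lam, LAMBDA_MAX_FLOOR)
    L_tilde = 2.0 * L / lam - np.eye(n)
    return LaplacianBundle(L=L, L_tilde=L_tilde, lambda_max=lam)


def cheb_basis(L_tilde: np.ndarray, K: int) -> np.ndarray:
    """Stacked Chebyshev matrices T_0(L~) ... T_K(L~), shape (K+1, N, N)."""
    if K < 0:
        raise GraphError("Chebyshev order K must be >= 0")
    n = L_tilde.shape[0]
    T = np.empty((K + 1, n, n))
    T[0] = np.eye(n)
    if K >= 1:
        T[1] = L_tilde
    for k in range(2, K + 1):
        T[k] = 2.0 * L_tilde @ T[k - 1] - T[k - 2]
    return T


def cheb_conv(
    X: np.ndarray,
    bundle: LaplacianBundle | np.ndarray,
    theta: np.ndarray,
    W: np.ndarray | None = None,
) -> np.ndarray:
    """Chebyshev graph convolution sum_k theta_k T_k(L~) X W.

    Parameters
    ----------
    X : ndarray, shape (N, F)
        Node feature matrix.
    bundle : LaplacianBundle or adjacency matrix
        An adjacency is converted with auto lambda_max.
    theta : ndarray, shape (K+1,)
        Polynomial coefficients; K is inferred from its length.
    W : ndarray, shape (F, F'), optional
        Output feature map; identity if omitted.
    """
    if isinstance(bundle, np.ndarray):
        bundle = laplacian(bundle)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != bundle.L_tilde.shape[0]:
        raise GraphError(
            f"feature rows ({X.shape[0]}) must match node count ({bundle.L_tilde.shape[0]})"
        )
    theta = np.asarray(theta, dtype=float).ravel()
    T = cheb_basis(bundle.L_tilde, len(theta) - 1)
    out = np.einsum("k,kij,jf->if", theta, T, X)
    if W is not None:
        W = np.asarray(W, dtype=float)
        if W.shape[0] != X.shape[1]:
            raise GraphError(f"W rows ({W.shape[0]}) must match feature width ({X.shape[1]})")
        out = out @ W
    return out


def spectral_filter(
    X: np.ndarray,
    A: np.ndarray,
    theta: np.ndarray,
    W: np.ndarray | None = None,
    lambda_max: float | str = "auto",
) -> np.ndarray:
    """Dense spectral form U g_theta(Lambda) U^T X W (symmetric graphs only).

    Evaluates the same Chebyshev polynomial on the eigenvalues of the
    rescaled Laplacian via its eigendecomposition.  Exists as the exact
    reference the recursion is checked against; O(N^3) and limited to
    symmetric adjacencies (real orthogonal eigenvectors).
    """
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T):
        raise GraphError("spectral form requires a symmetric adjacency")
    bundle = laplacian(A, lambda_max)
    lam, U = np.linalg.eigh(bundle.L)
    lam_tilde = 2.0 * lam / bundle.lambda_max - 1.0
    theta = np.asarray(theta, dtype=float).ravel()
    K = len(theta) - 1
    # Chebyshev polynomials evaluated on the eigenvalues
    Tvals = np.empty((K + 1, len(lam)))
    Tvals[0] = 1.0
    if K >= 1:
        Tvals[1] = lam_tilde
    for k in range(2, K + 1):
        Tvals[k] = 2.0 * lam_tilde * Tvals[k - 1] - Tvals[k - 2]
    g = theta @ Tvals
    out = U @ np.diag(g) @ U.T @ np.atleast_2d(np.asarray(X, dtype=float))
    if W is not None:
        out = out @ np.asarray(W, dtype=float)
    return out
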