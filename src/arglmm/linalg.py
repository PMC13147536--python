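"""Matrix-free randomized linear algebra.

Everything operates on a minimal symmetric-operator contract: an object
with ``dim`` and a batched ``matmat`` (a ``(dim, k)`` block of column
vectors in, the same shape out).  The three tools are

* a preconditioned conjugate gradient that solves many right-hand sides
  in one pass of batched products,
* a randomized Nystrom preconditioner for ill-conditioned SPD operators,
* the XTrace stochastic trace estimator (exchangeable leave-one-out
  deflation; variance decays ~1/k^2 in the number of test vectors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceError",
    "LinearOperator",
    "CallableOperator",
    "DenseOperator",
    "DiagonalShiftOperator",
    "TraceEstimate",
    "conjugate_gradient",
    "NystromSketch",
    "nystrom_preconditioner",
    "xtrace",
    "operator_to_dense",
]


class ConvergenceError(RuntimeError):
    """An iterative solve failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class LinearOperator:
    """Base contract: square, symmetric, with batched apply."""

    dim: int

    def matmat(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def matvec(self, x: np.ndarray) -> np.ndarray:
        return self.matmat(x)

    __call__ = matvec


class CallableOperator(LinearOperator):
    def __init__(self, dim: int, apply: Callable[[np.ndarray], np.ndarray]):
        self.dim = dim
        self._apply = apply

    def matmat(self, X: np.ndarray) -> np.ndarray:
        return self._apply(np.asarray(X, dtype=float))


class DenseOperator(LinearOperator):
    def __init__(self, A: np.ndarray):
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("DenseOperator needs a square matrix")
        self.A = A
        self.dim = A.shape[0]

    def matmat(self, X: np.ndarray) -> np.ndarray:
        return self.A @ X


class DiagonalShiftOperator(LinearOperator):
    """``alpha * A + beta * I`` — the LMM covariance V = tau2*B + sige2*I."""

    def __init__(self, base: LinearOperator, alpha: float, beta: float):
        self.base = base
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.dim = base.dim

    def matmat(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = self.beta * X
        if self.alpha != 0.0:
            out = out + self.alpha * self.base.matmat(X)
        return out


def operator_to_dense(A: LinearOperator) -> np.ndarray:
    """Materialize a small operator column-by-column (tests/oracles)."""
    return A.matmat(np.eye(A.dim))


# ----------------------------------------------------------------------
# conjugate gradient
# ----------------------------------------------------------------------


def conjugate_gradient(
    A: LinearOperator,
    b: np.ndarray,
    tol: float = 1e-5,
    precond: LinearOperator | None = None,
    max_iter: int | None = None,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Solve ``A x = b`` for an SPD operator, many right-hand sides at once.

    ``b`` may be a vector or a ``(dim, k)`` block; per column, iteration
    stops when the relative residual ``||A x - b|| / ||b||`` drops below
    ``tol``.  Converged columns are frozen so the batched product shrinks
    as the block converges.  Raises :class:`ConvergenceError` (carrying
    the worst final residual) on failure.
    """
    b = np.asarray(b, dtype=float)
    single = b.ndim == 1
    B = b[:, None] if single else b
    n, k = B.shape
    if n != A.dim:
        raise ValueError(f"rhs dimension {n} does not match operator dim {A.dim}")
    if max_iter is None:
        max_iter = max(10 * n, 200)
    bnorm = np.linalg.norm(B, axis=0)
    nonzero = bnorm > 0
    X = np.zeros_like(B) if x0 is None else np.array(x0, dtype=float).reshape(n, k).copy()
    if not np.any(nonzero):
        return X[:, 0] if single else X

    R = B - (A.matmat(X) if x0 is not None else 0.0)
    if x0 is None:
        R = B.copy()
    Z = precond.matmat(R) if precond is not None else R.copy()
    P = Z.copy()
    rz = np.einsum("ij,ij->j", R, Z)
    active = nonzero & (np.linalg.norm(R, axis=0) > tol * np.where(nonzero, bnorm, 1.0))

    it = 0
    while np.any(active) and it < max_iter:
        idx = np.nonzero(active)[0]
        Ap = A.matmat(P[:, idx])
        pAp = np.einsum("ij,ij->j", P[:, idx], Ap)
        # guard against breakdown on semidefinite directions
        safe = pAp > 0
        alpha = np.zeros(len(idx))
        alpha[safe] = rz[idx][safe] / pAp[safe]
        X[:, idx] += P[:, idx] * alpha
        R[:, idx] -= Ap * alpha
        Znew = precond.matmat(R[:, idx]) if precond is not None else R[:, idx]
        rz_new = np.einsum("ij,ij->j", R[:, idx], Znew)
        beta = np.zeros(len(idx))
        beta[safe] = rz_new[safe] / rz[idx][safe]
        P[:, idx] = Znew + P[:, idx] * beta
        rz[idx] = rz_new
        resid = np.linalg.norm(R[:, idx], axis=0) / bnorm[idx]
        still = resid > tol
        active[idx] = still
        it += 1

    logger.debug("cg: %d rhs solved in %d iterations (tol %.1e)", k, it, tol)
    if np.any(active):
        rel = np.linalg.norm(R, axis=0) / np.where(nonzero, bnorm, 1.0)
        worst = float(rel[active].max())
        raise ConvergenceError(
            f"conjugate gradient did not converge: relative residual {worst:.3e} "
            f"after {it} iterations (tol {tol:.1e})",
            residual=worst,
        )
    return X[:, 0] if single else X


# ----------------------------------------------------------------------
# Nystrom preconditioner
# ----------------------------------------------------------------------


class NystromSketch:
    """Rank-``r`` randomized Nystrom approximation ``A ~= U diag(L) U^T``.

    Sketched once from an SPD operator; :meth:`preconditioner` then
    yields an SPD approximate inverse for any positive diagonal shift
    (and positive rescaling of A), which is what lets one sketch of the
    GRM serve every AI-REML iteration of V = tau2*B + sige2*I.
    """

    def __init__(self, A: LinearOperator, rank: int, seed: int):
        if rank < 1:
            raise ValueError("rank must be >= 1")
        n = A.dim
        self.dim = n
        self.exact = rank >= n
        if self.exact:
            # small-problem fallback: dense eigendecomposition is the
            # "rank == dim" limit of the sketch
            dense = operator_to_dense(A)
            L, U = scipy.linalg.eigh(dense)
            self.eigenvalues = np.maximum(L[::-1], 0.0)
            self.U = U[:, ::-1]
            return
        rng = np.random.default_rng(seed)
        Omega = rng.standard_normal((n, rank))
        Omega, _ = np.linalg.qr(Omega)
        Y = A.matmat(Omega)
        # shifted Cholesky for numerical stability (Frangella-Tropp-Udell)
        nu = np.sqrt(n) * np.finfo(float).eps * np.linalg.norm(Y, 2)
        Ynu = Y + nu * Omega
        C = scipy.linalg.cholesky(Omega.T @ Ynu, lower=False)
        Bmat = scipy.linalg.solve_triangular(C, Ynu.T, lower=False, trans="T").T
        U, s, _ = np.linalg.svd(Bmat, full_matrices=False)
        self.U = U
        self.eigenvalues = np.maximum(s**2 - nu, 0.0)

    def preconditioner(self, shift: float, scale: float = 1.0) -> LinearOperator:
        """Approximate inverse of ``scale * A + shift * I``.

        Applies ``U (scale*L + shift)^{-1} U^T x + (1/shift) (x - U U^T x)``.
        """
        if shift <= 0:
            raise ValueError("shift must be positive")
        lam = scale * self.eigenvalues + shift
        U = self.U

        def apply(X):
            UtX = U.T @ X
            return U @ (UtX / lam[:, None]) + (X - U @ UtX) / shift

        return CallableOperator(self.dim, apply)


def nystrom_preconditioner(
    A: LinearOperator, rank: int, shift: float, seed: int
) -> LinearOperator:
    """SPD approximate inverse of ``A + shift*I`` from one randomized sketch.

    With ``rank >= dim`` the sketch degenerates to an exact
    eigendecomposition (test-scale only).
    """
    return NystromSketch(A, rank, seed).preconditioner(shift)


# ----------------------------------------------------------------------
# XTrace
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class TraceEstimate:
    """A stochastic trace estimate with its leave-one-out spread."""

    value: float
    stderr: float
    n_vectors: int
    seed: int

    def __post_init__(self):
        if self.n_vectors < 2:
            raise ValueError("XTrace needs at least 2 test vectors")


def xtrace(A: LinearOperator, n_vectors: int = 50, seed: int = 0) -> TraceEstimate:
    """Unbiased randomized trace estimate (XTrace).

    The estimator averages, over sphere-normalized Gaussian test vectors
    ``w_i``, the exchangeable leave-one-out quantity

        t_i = tr(Q_i^T A Q_i) + w_i^T (I - P_i) A (I - P_i) w_i,

    where ``Q_i`` orthonormalizes the sketch ``A W`` with column ``i``
    deleted and ``P_i = Q_i Q_i^T``.  Deflating by a basis independent of
    ``w_i`` keeps each ``t_i`` unbiased while removing most of the
    variance carried by the dominant eigenspace.  Everything reduces to
    two batched products (``A W`` and ``A Q``) plus O(n k^2) dense work.
    Valid for non-symmetric operators (used for tr(V^{-1} B)).
    """
    if n_vectors < 2:
        raise ValueError("XTrace needs at least 2 test vectors")
    n = A.dim
    m = min(n_vectors, n)
    rng = np.random.default_rng(seed)
    Om = rng.standard_normal((n, m))
    Om *= np.sqrt(n) / np.linalg.norm(Om, axis=0, keepdims=True)

    Y = A.matmat(Om)
    if not np.any(Y):
        return TraceEstimate(0.0, 0.0, n_vectors, seed)
    Q, R = np.linalg.qr(Y)
    Z = A.matmat(Q)
    H = Q.T @ Z  # Q^T A Q
    W = Q.T @ Om
    # unit vectors spanning span(Y)  ∩ span(Y_{-i})^perp: s_i ∝ R^{-T} e_i
    Rinv_T = scipy.linalg.solve_triangular(R, np.eye(m), lower=False).T
    S = Rinv_T / np.linalg.norm(Rinv_T, axis=0, keepdims=True)

    # t_i = tr(H) - s_i' H s_i + quad_i, with the quadratic term expanded
    # in the available products (y_i = A w_i, Z = A Q)
    trH = np.trace(H)
    sHs = np.einsum("ij,ij->j", S, H @ S)
    w_dot_y = np.einsum("ij,ij->j", Om, Y)
    OtZ = Om.T @ Z  # w_i^T A q_j
    QtY = R  # Q^T Y
    alpha = np.einsum("ij,ij->j", S, W)  # (Q s_i)^T om_i
    # scalar pieces, all length m
    t1 = w_dot_y
    t2 = np.einsum("ij,ji->i", OtZ, W)  # om_i^T Z (Q^T om_i)
    t3 = alpha * np.einsum("ij,ji->i", OtZ, S)  # alpha_i * om_i^T Z s_i
    t4 = np.einsum("ij,ij->j", W, QtY)  # w_i^T Q^T y_i
    t5 = np.einsum("ij,ij->j", W, H @ W)
    t6 = alpha * np.einsum("ij,ij->j", W, H @ S)
    t7 = alpha * np.einsum("ij,ij->j", S, QtY)
    t8 = alpha * np.einsum("ij,ij->j", S, H @ W)
    t9 = alpha**2 * sHs
    quad = t1 - t2 + t3 - t4 + t5 - t6 + t7 - t8 + t9
    t = trH - sHs + quad
    value = float(np.mean(t))
    stderr = float(np.std(t, ddof=1) / np.sqrt(m))
    return TraceEstimate(value, stderr, n_vectors, seed)


def hutchinson_trace(A: LinearOperator, n_vectors: int, seed: int) -> TraceEstimate:
    """Plain Hutchinson estimator (Gaussian probes); reference only."""
    rng = np.random.default_rng(seed)
    Om = rng.standard_normal((A.dim, n_vectors))
    t = np.einsum("ij,ij->j", Om, A.matmat(Om))
    return TraceEstimate(
        float(t.mean()), float(t.std(ddof=1) / np.sqrt(n_vectors)), n_vectors, seed
    )
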