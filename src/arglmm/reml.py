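"""Variance-component estimation for the ARG linear mixed model.

Model: ``y ~ N(X b, V)`` with ``V = tau2 * B + sige2 * I``, where ``B``
is the branch GRM (any symmetric PSD operator).  The restricted
log-likelihood objective, up to a constant and a factor of -2, is

    l(tau2, sige2) = log det V + log det(X' V^-1 X) + y' P y,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

minimized by average-information (AI) Newton steps
``theta <- theta - AI^-1 grad`` with

    grad  = [tr(P) - y'PPy,  tr(PB) - y'PBPy]        (sige2, tau2 order)
    AI_ij = y' P Vdot_i P Vdot_j P y,   Vdot = (I, B).

Quadratic forms are exact (conjugate gradient for V^-1); the two large
traces tr(V^-1) and tr(V^-1 B) are XTrace estimates, so the gradient is
stochastic while the AI matrix is not.  Iteration starts from a
randomized Haseman-Elston solve and stops by the relative-change rule,
averaging a trailing window of iterates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.linalg
import scipy.optimize

from .linalg import (
    CallableOperator,
    LinearOperator,
    NystromSketch,
    conjugate_gradient,
    operator_to_dense,
    xtrace,
)

__all__ = [
    "VarianceComponents",
    "RemlConfig",
    "RemlFit",
    "RemlState",
    "project_P",
    "gls_coefficients",
    "reml_gradient",
    "average_information",
    "he_initialize",
    "fit_reml",
    "dense_spectral_reml",
    "estimate_vg",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VarianceComponents:
    """(tau2, sige2): mutational-effect variance per generation per bp
    (on the scale of the GRM supplied) and environmental variance."""

    tau2: float
    sigma_e2: float

    def as_array(self) -> np.ndarray:
        # internal parameter order is (sigma_e2, tau2), matching the
        # gradient/AI layout
        return np.array([self.sigma_e2, self.tau2])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "VarianceComponents":
        return cls(tau2=float(theta[1]), sigma_e2=float(theta[0]))


@dataclass(frozen=True)
class RemlConfig:
    """AI-REML hyperparameters (defaults are the method's standard settings)."""

    cg_tol: float = 1e-5
    n_trace_vectors: int = 50
    nystrom_rank: int = 500
    n_he_vectors: int = 50
    rel_change_threshold: float = 0.05
    min_post_steps: int = 15
    max_iter: int = 100
    seed: int = 0


@dataclass
class IterationRecord:
    theta: VarianceComponents
    gradient: np.ndarray
    ai: np.ndarray


@dataclass
class RemlFit:
    theta: VarianceComponents
    history: list[IterationRecord]
    converged: bool
    n_iter: int
    stderr: VarianceComponents | None = None
    beta: np.ndarray | None = None
    grm_scale: float = 1.0
    config: RemlConfig = field(default_factory=RemlConfig)

    @property
    def tau2(self) -> float:
        return self.theta.tau2

    @property
    def sigma_e2(self) -> float:
        return self.theta.sigma_e2

    def report(self) -> dict:
        """Plain-dict summary (components, SEs, iteration history)."""
        return {
            "tau2": self.theta.tau2,
            "sigma_e2": self.theta.sigma_e2,
            "stderr_tau2": self.stderr.tau2 if self.stderr else None,
            "stderr_sigma_e2": self.stderr.sigma_e2 if self.stderr else None,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grm_scale": self.grm_scale,
            "config": asdict(self.config),
            "history": [
                {
                    "tau2": rec.theta.tau2,
                    "sigma_e2": rec.theta.sigma_e2,
                    "gradient": list(map(float, rec.gradient)),
                    "ai": [list(map(float, row)) for row in rec.ai],
                }
                for rec in self.history
            ],
        }


class RemlState:
    """Caches for one parameter value: V^-1 X, GLS coefficients, Py.

    ``B`` is a symmetric operator over the observed individuals; V^-1
    products run through (preconditioned) conjugate gradient.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        theta: VarianceComponents,
        B: LinearOperator,
        precond: LinearOperator | None = None,
        cg_tol: float = 1e-5,
    ):
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValueError("y and X have inconsistent shapes")
        if X.shape[1] >= X.shape[0]:
            raise ValueError("more covariates than observations")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix X is rank deficient")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite phenotype values")
        self.y = y
        self.X = X
        self.n, self.k = X.shape
        self.theta = theta
        self.B = B
        self.precond = precond
        self.cg_tol = cg_tol
        self.V = _v_operator(B, theta)
        self._vinv_X = None
        self._xtvx_cho = None
        self._py = None
        self._b_hat = None

    # -- cached pieces -------------------------------------------------

    def vinv(self, M: np.ndarray) -> np.ndarray:
        """V^-1 M by preconditioned conjugate gradient."""
        return conjugate_gradient(
            self.V, M, tol=self.cg_tol, precond=self.precond
        )

    @property
    def vinv_X(self) -> np.ndarray:
        if self._vinv_X is None:
            self._vinv_X = self.vinv(self.X)
        return self._vinv_X

    @property
    def xtvx_cho(self):
        if self._xtvx_cho is None:
            G = self.X.T @ self.vinv_X
            G = (G + G.T) / 2
            try:
                self._xtvx_cho = scipy.linalg.cho_factor(G)
            except scipy.linalg.LinAlgError as err:
                raise ValueError(f"X' V^-1 X is singular: {err}") from err
        return self._xtvx_cho

    @property
    def b_hat(self) -> np.ndarray:
        if self._b_hat is None:
            vy = self.vinv(self.y)
            self._b_hat = scipy.linalg.cho_solve(self.xtvx_cho, self.X.T @ vy)
        return self._b_hat

    @property
    def py(self) -> np.ndarray:
        """P y = V^-1 (y - X b_hat)."""
        if self._py is None:
            self._py = self.vinv(self.y - self.X @ self.b_hat)
        return self._py


def _v_operator(B: LinearOperator, theta: VarianceComponents) -> LinearOperator:
    from .linalg import DiagonalShiftOperator

    return DiagonalShiftOperator(B, alpha=theta.tau2, beta=theta.sigma_e2)


def project_P(state: RemlState, v: np.ndarray) -> np.ndarray:
    """Apply the REML projection: P v = V^-1 v - V^-1 X (X'V^-1X)^-1 X'V^-1 v."""
    v = np.asarray(v, dtype=float)
    vinv_v = state.vinv(v)
    corr = state.vinv_X @ scipy.linalg.cho_solve(state.xtvx_cho, state.vinv_X.T @ v)
    return vinv_v - corr


def gls_coefficients(state: RemlState) -> np.ndarray:
    """Generalized least squares: b_hat = (X'V^-1X)^-1 X'V^-1 y."""
    return state.b_hat


def reml_gradient(
    state: RemlState, seed: int = 0, exact_traces: bool = False
) -> np.ndarray:
    """Gradient (d/d sige2, d/d tau2) of the REML objective.

    Quadratic forms are exact; tr(V^-1) and tr(V^-1 B) come from XTrace
    unless ``exact_traces`` (dense, test scale).  The K x K correction
    terms of tr(P) and tr(PB) are always exact.
    """
    py = state.py
    b_py = state.B.matmat(py)
    quad_sigma = float(py @ py)
    quad_tau = float(py @ b_py)

    M = state.vinv_X  # V^-1 X
    if exact_traces:
        Vd = operator_to_dense(state.V)
        Bd = operator_to_dense(state.B)
        Vinv = np.linalg.inv(Vd)
        tr_vinv = float(np.trace(Vinv))
        tr_vinv_b = float(np.trace(Vinv @ Bd))
    else:
        n_vec = getattr(state, "n_trace_vectors", 50)
        op_vinv = CallableOperator(state.n, state.vinv)
        tr_vinv = xtrace(op_vinv, n_vec, seed).value
        op_vinv_b = CallableOperator(
            state.n, lambda Z: state.vinv(state.B.matmat(Z))
        )
        tr_vinv_b = xtrace(op_vinv_b, n_vec, seed + 1).value
    # exact K x K corrections: tr(P) = tr(V^-1) - tr((X'V^-1X)^-1 X'V^-2 X)
    corr_sigma = float(np.trace(scipy.linalg.cho_solve(state.xtvx_cho, M.T @ M)))
    corr_tau = float(
        np.trace(scipy.linalg.cho_solve(state.xtvx_cho, M.T @ state.B.matmat(M)))
    )
    g_sigma = (tr_vinv - corr_sigma) - quad_sigma
    g_tau = (tr_vinv_b - corr_tau) - quad_tau
    return np.array([g_sigma, g_tau])


def average_information(state: RemlState) -> np.ndarray:
    """AI matrix [[y'PPPy, y'PPBPy], [y'PPBPy, y'PBPBPy]] (PSD, trace-free).

    One batched P application on (Py, B Py); entries are Gram products
    in the P inner product, so the matrix is symmetric PSD by
    construction.
    """
    u = state.py
    v = state.B.matmat(u)
    PU = project_P(state, np.column_stack([u, v]))
    ai_ss = float(u @ PU[:, 0])
    ai_st = float(u @ PU[:, 1])
    ai_tt = float(v @ PU[:, 1])
    return np.array([[ai_ss, ai_st], [ai_st, ai_tt]])


# ----------------------------------------------------------------------
# Haseman-Elston initialization
# ----------------------------------------------------------------------


def he_initialize(
    B: LinearOperator,
    y: np.ndarray,
    X: np.ndarray | None = None,
    n_vectors: int = 50,
    seed: int = 0,
    exact_traces: bool = False,
) -> VarianceComponents:
    """Randomized Haseman-Elston estimator of (tau2, sige2).

    Residualizes ``y`` against ``X`` by OLS and solves the
    method-of-moments system

        [tr(Bt^2)  tr(Bt) ] [tau2 ]   [r' B r]
        [tr(Bt)    N - K  ] [sige2] = [r' r  ]

    where ``Bt = Px B Px`` is the GRM projected onto the residual space
    of ``X`` (so both sides of each equation have the same expectation
    under the model; with ``X = None`` the system uses the raw GRM and
    tr(I) = N).  Traces are XTrace estimates.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    r = y
    k = 0
    project = None
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = X.shape[1]
        Q, _ = np.linalg.qr(X)

        def project(V):
            return V - Q @ (Q.T @ V)

        r = project(y)
    if not np.any(r):
        return VarianceComponents(0.0, 0.0)

    def bt_matmat(V):
        if project is None:
            return B.matmat(V)
        return project(B.matmat(project(V)))

    if exact_traces:
        Bt = bt_matmat(np.eye(n))
        tr_b = float(np.trace(Bt))
        tr_b2 = float(np.sum(Bt * Bt))
    else:
        op_bt = CallableOperator(B.dim, bt_matmat)
        tr_b = xtrace(op_bt, n_vectors, seed).value
        op_b2 = CallableOperator(B.dim, lambda Z: bt_matmat(bt_matmat(Z)))
        tr_b2 = xtrace(op_b2, n_vectors, seed + 1).value
    A = np.array([[tr_b2, tr_b], [tr_b, float(n - k)]])
    rhs = np.array([float(r @ B.matmat(r)), float(r @ r)])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) <= 1e-12 * max(abs(A).max() ** 2, 1.0):
        raise ValueError(
            "Haseman-Elston system is singular (is the GRM proportional to I?)"
        )
    tau2, sige2 = np.linalg.solve(A, rhs)
    return VarianceComponents(tau2=float(tau2), sigma_e2=float(sige2))


# ----------------------------------------------------------------------
# AI-REML driver
# ----------------------------------------------------------------------


def fit_reml_operator(
    B: LinearOperator,
    y: np.ndarray,
    X: np.ndarray,
    config: RemlConfig | None = None,
) -> RemlFit:
    """AI-REML on an arbitrary symmetric PSD GRM operator.

    Initializes by Haseman-Elston, iterates
    ``theta <- theta - AI^-1 grad`` with components clamped to
    ``>= 1e-8 * var(y)``, and, once both components move by less than
    ``rel_change_threshold`` relative to the previous iterate, runs
    ``min_post_steps`` further iterations and returns their mean (the
    trailing average smooths the stochastic-gradient jitter).
    """
    config = config or RemlConfig()
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    vary = float(np.var(y))
    if vary == 0.0:
        raise ValueError("phenotype is constant; variance components undefined")
    floor = 1e-8 * vary

    seed_pool = np.random.SeedSequence(config.seed).generate_state(
        3 * config.max_iter + 10
    ) % (2**31)

    theta = he_initialize(
        B, y, X, n_vectors=config.n_he_vectors, seed=int(seed_pool[0])
    )
    theta = _clamp(theta, floor)
    logger.info("HE initialization: tau2=%.6g sigma_e2=%.6g", theta.tau2, theta.sigma_e2)

    sketch = NystromSketch(B, min(config.nystrom_rank, n), seed=int(seed_pool[1]))

    history: list[IterationRecord] = []
    post_steps_left = None
    converged = False
    for it in range(config.max_iter):
        precond = sketch.preconditioner(shift=theta.sigma_e2, scale=theta.tau2)
        state = RemlState(y, X, theta, B, precond=precond, cg_tol=config.cg_tol)
        state.n_trace_vectors = config.n_trace_vectors
        grad = reml_gradient(state, seed=int(seed_pool[2 + 2 * it]))
        ai = average_information(state)
        history.append(IterationRecord(theta, grad.copy(), ai.copy()))
        step = _solve_psd(ai, grad)
        theta_new = _clamp(
            VarianceComponents.from_array(theta.as_array() - step), floor
        )
        rel = np.max(
            np.abs(theta_new.as_array() - theta.as_array())
            / np.maximum(np.abs(theta.as_array()), floor)
        )
        logger.info(
            "iter %d: tau2=%.6g sigma_e2=%.6g |grad|=%.3g rel_change=%.3g",
            it, theta_new.tau2, theta_new.sigma_e2, np.linalg.norm(grad), rel,
        )
        theta = theta_new
        if post_steps_left is not None:
            post_steps_left -= 1
            if post_steps_left <= 0:
                converged = True
                break
        elif rel < config.rel_change_threshold:
            post_steps_left = config.min_post_steps
    # record the final iterate so the trailing window covers the
    # min_post_steps updates taken after the stopping rule fired
    history.append(IterationRecord(theta, np.full(2, np.nan), history[-1].ai))

    window = min(config.min_post_steps, len(history))
    tail = np.array([rec.theta.as_array() for rec in history[-window:]])
    theta_hat = VarianceComponents.from_array(tail.mean(axis=0))
    theta_hat = _clamp(theta_hat, floor)

    # SEs from the inverse AI at the returned estimate: asymptotic REML
    # covariance is the inverse expected information = 2 * AI^-1 here
    precond = sketch.preconditioner(shift=theta_hat.sigma_e2, scale=theta_hat.tau2)
    state = RemlState(y, X, theta_hat, B, precond=precond, cg_tol=config.cg_tol)
    state.n_trace_vectors = config.n_trace_vectors
    ai_final = average_information(state)
    try:
        cov = 2.0 * np.linalg.inv(ai_final)
        stderr = VarianceComponents(
            tau2=float(np.sqrt(max(cov[1, 1], 0.0))),
            sigma_e2=float(np.sqrt(max(cov[0, 0], 0.0))),
        )
    except np.linalg.LinAlgError:
        stderr = None

    fit = RemlFit(
        theta=theta_hat,
        history=history,
        converged=converged,
        n_iter=len(history) - 1,
        stderr=stderr,
        beta=state.b_hat,
        config=config,
    )
    if not converged:
        logger.warning("AI-REML did not trigger the stopping rule in %d iterations", config.max_iter)
    return fit


def _clamp(theta: VarianceComponents, floor: float) -> VarianceComponents:
    return VarianceComponents(
        tau2=max(theta.tau2, floor), sigma_e2=max(theta.sigma_e2, floor)
    )


def _solve_psd(ai: np.ndarray, grad: np.ndarray) -> np.ndarray:
    ridge = 1e-12 * max(np.trace(ai), 1.0)
    try:
        return np.linalg.solve(ai + ridge * np.eye(2), grad)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(ai) @ grad


# ----------------------------------------------------------------------
# dense spectral-rotation oracle
# ----------------------------------------------------------------------


def dense_spectral_reml(
    B: np.ndarray, y: np.ndarray, X: np.ndarray
) -> VarianceComponents:
    """Deterministic REML by eigen-rotation (small-N oracle).

    Rotating y and X by the eigenvectors of ``B`` diagonalizes V, so the
    restricted likelihood is evaluated exactly in O(N) per objective
    call and minimized by bounded 2-D quasi-Newton optimization.
    """
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    lam, U = scipy.linalg.eigh((B + B.T) / 2)
    if lam.min() < -1e-8 * max(np.trace(B) / n, 1.0):
        raise ValueError(f"GRM is not PSD: min eigenvalue {lam.min():.3e}")
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    Xt = U.T @ X
    vary = float(np.var(y))
    lo = 1e-10 * vary

    def objective(theta):
        tau2, sige2 = theta
        d = tau2 * lam + sige2
        if np.any(d <= 0):
            return np.inf
        Xd = Xt / d[:, None]
        G = Xt.T @ Xd
        sign, logdet_g = np.linalg.slogdet(G)
        if sign <= 0:
            return np.inf
        xty = Xd.T @ yt
        ypy = float(yt @ (yt / d) - xty @ np.linalg.solve(G, xty))
        return float(np.sum(np.log(d)) + logdet_g + ypy)

    he = _dense_he(B, y, X)
    starts = [
        np.array([max(he.tau2, lo), max(he.sigma_e2, lo)]),
        np.array([lo, vary]),
        np.array([vary / (2 * max(np.mean(lam), 1e-300)), vary / 2]),
    ]
    best = None
    for x0 in starts:
        res = scipy.optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, None), (lo, None)],
        )
        if best is None or res.fun < best.fun:
            best = res
    return VarianceComponents(tau2=float(best.x[0]), sigma_e2=float(best.x[1]))


def _dense_he(B, y, X) -> VarianceComponents:
    from .linalg import DenseOperator

    try:
        return he_initialize(DenseOperator(B), y, X, exact_traces=True)
    except ValueError:
        vary = float(np.var(y))
        return VarianceComponents(tau2=0.0, sigma_e2=vary)


# ----------------------------------------------------------------------
# additive genetic variance
# ----------------------------------------------------------------------


def estimate_vg(
    fit: RemlFit,
    B_centered: LinearOperator,
    n_vectors: int = 50,
    seed: int = 0,
) -> tuple[float, float]:
    """Estimate the sample additive genetic variance VG and its SD.

    ``VG = (1/N) sum_i (g_i - gbar)^2`` has expectation
    ``tau2 tr(Bc)/N`` and, for Gaussian sub-edge effects, variance
    ``2 tau4/N^2 sum_nm Bc_nm^2`` (the quadratic-form variance
    ``2 tr((A Sigma)^2)`` with ``A = Pc/N`` and ``Sigma = tau2 B``),
    with ``Bc`` the centered GRM on the same scale as the fit.  Both
    traces are XTrace estimates; ``sum_nm Bc_nm^2 = tr(Bc^2)``.
    """
    n = B_centered.dim
    tau2 = fit.theta.tau2
    if tau2 == 0.0:
        return 0.0, 0.0
    tr_bc = xtrace(B_centered, n_vectors, seed).value
    op_bc2 = CallableOperator(n, lambda Z: B_centered.matmat(B_centered.matmat(Z)))
    tr_bc2 = xtrace(op_bc2, n_vectors, seed + 1).value
    vg = tau2 * tr_bc / n
    var_vg = 2.0 * tau2**2 * max(tr_bc2, 0.0) / n**2
    return float(vg), float(np.sqrt(var_vg))


def fit_reml(arg, y, X, config: RemlConfig | None = None, **kwargs) -> RemlFit:
    """AI-REML on an ARG: thin wrapper building the implicit GRM operator.

    ``kwargs`` pass through to :class:`arglmm.estimators.ARGLMM`
    (``grm_scale``, ``obs_index``, ...).
    """
    from .estimators import ARGLMM

    model = ARGLMM(arg, config=config, **kwargs)
    model.fit(X, y)
    return model.fit_result_
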