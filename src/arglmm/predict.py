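"""Empirical BLUP of genetic values, and general linear-combination
prediction, under the fitted ARG linear mixed model.

For observed phenotypes ``y_o`` and target individuals ``n`` (the sets
may overlap), the conditional mean of the Gaussian model is

    g_hat_n = tau2 B_{n,o} (tau2 B_{o,o} + sige2 I)^{-1} (y_o - X_o b_hat),

computed with one conjugate-gradient solve shared by all predictions
and one submatrix GRM product.  The conditional covariance
``tau2 B_{n,n} - tau2 B_{n,o} Sigma_zz^{-1} tau2 B_{o,n}`` is evaluated
column-by-column on request.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .arg import ArgData
from .grm import BranchGRMOperator
from .linalg import conjugate_gradient, DiagonalShiftOperator
from .reml import RemlFit

__all__ = ["BlupResult", "predict_blup", "predict_linear_combination"]

logger = logging.getLogger(__name__)

#: conditional variances need one CG solve per target; keep the set small
VARIANCE_TARGET_GUARD = 2000


@dataclass
class BlupResult:
    predicted: np.ndarray
    obs_index: np.ndarray
    target_index: np.ndarray
    conditional_variance: np.ndarray | None = None
    converged_fit: bool = True

    def __post_init__(self):
        if len(self.predicted) != len(self.target_index):
            raise ValueError("prediction length does not match target set")


def _shared_solve(arg, fit, y_o, X, obs_index, cg_tol, grm_scale):
    """r = (tau2 B_oo + sige2 I)^{-1} (y_o - X_o b_hat), reused by all BLUPs."""
    y_o = np.asarray(y_o, dtype=float).ravel()
    obs_index = np.asarray(obs_index, dtype=np.intp)
    if len(obs_index) == 0:
        raise ValueError("empty observed set")
    if len(y_o) != len(obs_index):
        raise ValueError("y_o and obs_index have different lengths")
    B_oo = BranchGRMOperator(arg, scale=grm_scale, rows=obs_index, cols=obs_index)
    V_oo = DiagonalShiftOperator(B_oo, alpha=fit.theta.tau2, beta=fit.theta.sigma_e2)
    if X is None:
        X = np.ones((len(y_o), 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    # GLS coefficients on the observed set at the fitted components
    vinv_X = conjugate_gradient(V_oo, X, tol=cg_tol)
    vinv_y = conjugate_gradient(V_oo, y_o, tol=cg_tol)
    G = X.T @ vinv_X
    b_hat = np.linalg.solve((G + G.T) / 2, X.T @ vinv_y)
    resid = y_o - X @ b_hat
    r = conjugate_gradient(V_oo, resid, tol=cg_tol)
    return r, b_hat, V_oo


def predict_blup(
    arg: ArgData,
    fit: RemlFit,
    y_o: np.ndarray,
    X: np.ndarray | None,
    obs_index: np.ndarray,
    target_index: np.ndarray,
    with_variance: bool = False,
    grm_scale: float | None = None,
    cg_tol: float | None = None,
) -> BlupResult:
    """Empirical BLUP of genetic values for ``target_index``.

    ``X`` are the covariates of the observed individuals (intercept
    column expected; ``None`` for intercept only).  ``grm_scale``
    defaults to the scale recorded in ``fit``.
    """
    target_index = np.asarray(target_index, dtype=np.intp)
    obs_index = np.asarray(obs_index, dtype=np.intp)
    if grm_scale is None:
        grm_scale = fit.grm_scale
    if cg_tol is None:
        cg_tol = fit.config.cg_tol
    if not fit.converged:
        warnings.warn(
            "variance-component fit did not converge; BLUPs use the best "
            "available estimates",
            stacklevel=2,
        )
    tau2 = fit.theta.tau2
    if tau2 == 0.0:
        pred = np.zeros(len(target_index))
        var = (
            np.zeros(len(target_index)) if with_variance else None
        )
        return BlupResult(pred, obs_index, target_index, var, fit.converged)
    r, _, V_oo = _shared_solve(arg, fit, y_o, X, obs_index, cg_tol, grm_scale)
    B_no = BranchGRMOperator(arg, scale=grm_scale, rows=target_index, cols=obs_index)
    pred = tau2 * B_no.matmat(r)
    variance = None
    if with_variance:
        m = len(target_index)
        if m > VARIANCE_TARGET_GUARD:
            raise ValueError(
                f"conditional variances guarded to <= {VARIANCE_TARGET_GUARD} targets"
            )
        B_nn = BranchGRMOperator(
            arg, scale=grm_scale, rows=target_index, cols=target_index
        )
        B_on = BranchGRMOperator(arg, scale=grm_scale, rows=obs_index, cols=target_index)
        # Sigma_nn - Sigma_no Sigma_oo^-1 Sigma_on, one CG solve per column
        cross = tau2 * B_on.matmat(np.eye(m))
        sol = conjugate_gradient(V_oo, cross, tol=cg_tol)
        Sigma_nn = tau2 * B_nn.matmat(np.eye(m))
        variance = Sigma_nn - tau2 * B_no.matmat(sol)
        variance = (variance + variance.T) / 2
    return BlupResult(pred, obs_index, target_index, variance, fit.converged)


def predict_linear_combination(
    arg: ArgData,
    fit: RemlFit,
    y_o: np.ndarray,
    X: np.ndarray | None,
    obs_index: np.ndarray,
    cross_cov,
    grm_scale: float | None = None,
    cg_tol: float | None = None,
) -> np.ndarray:
    """Conditional mean of any zero-mean linear combination of sub-edge
    effects: ``cross_cov(r)`` with the shared solve
    ``r = Sigma_zz^{-1}(y_o - X_o b_hat)``.

    ``cross_cov`` maps a vector over observed individuals to the target
    quantity, i.e. applies ``Sigma_xz``; passing
    ``v -> tau2 * B[targets, obs] v`` reproduces :func:`predict_blup`.
    """
    if grm_scale is None:
        grm_scale = fit.grm_scale
    if cg_tol is None:
        cg_tol = fit.config.cg_tol
    r, _, _ = _shared_solve(arg, fit, y_o, X, obs_index, cg_tol, grm_scale)
    out = np.asarray(cross_cov(r), dtype=float)
    return out
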