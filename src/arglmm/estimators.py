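"""Scikit-learn style front end for the ARG linear mixed model.

``ARGLMM`` composes the implicit branch-GRM operator, stochastic
AI-REML variance-component estimation, and BLUP genetic prediction into
a fit/predict estimator.  Covariates play the role of ``X`` in
``fit(X, y)``; the ARG itself is a constructor argument because it
defines the covariance structure, not a feature matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .arg import ArgData, total_root_area
from .grm import BranchGRMOperator
from .linalg import CallableOperator
from .reml import (
    RemlConfig,
    RemlFit,
    VarianceComponents,
    estimate_vg as _estimate_vg,
    fit_reml_operator,
    he_initialize,
)

__all__ = ["ARGLMM"]


class ARGLMM(BaseEstimator):
    """Linear mixed model with a branch-GRM covariance from an ARG.

    Phenotypes of the observed individuals follow
    ``y ~ N(X b, tau2 * B_oo + sige2 * I)`` where ``B`` is the branch
    GRM of the ARG (optionally rescaled).  ``fit`` estimates
    ``(tau2, sige2)`` by stochastic AI-REML (or Haseman-Elston with
    ``method="he"``); ``predict`` returns empirical BLUPs of genetic
    values for arbitrary target individuals.

    Parameters
    ----------
    arg:
        :class:`~arglmm.arg.ArgData` (or a tskit ``TreeSequence``).
    normalize:
        If True, divide the GRM by ``4 * total_root_area`` — the scale
        on which simulated phenotypes are generated — so ``tau2`` is
        O(1) and comparable to ``sige2``.  If a float, use it directly
        as the multiplicative GRM scale.
    obs_index:
        Individuals carrying phenotypes (default: all).
    method:
        ``"reml"`` (default) or ``"he"`` (moment estimator only).
    config:
        :class:`~arglmm.reml.RemlConfig`; individual fields may also be
        overridden by keyword (``cg_tol=...`` etc. via ``set_params``).

    Attributes
    ----------
    tau2_, sigma_e2_ : float
        Estimated variance components (GRM scale / phenotype scale).
    beta_ : ndarray
        GLS covariate coefficients at the estimate.
    fit_result_ : RemlFit
        Full iteration history and convergence state.
    grm_scale_ : float
        Resolved multiplicative GRM scale.
    """

    def __init__(
        self,
        arg=None,
        normalize: bool | float = False,
        obs_index=None,
        method: str = "reml",
        config: RemlConfig | None = None,
    ):
        self.arg = arg
        self.normalize = normalize
        self.obs_index = obs_index
        self.method = method
        self.config = config

    # -- plumbing ------------------------------------------------------

    def _arg_data(self) -> ArgData:
        if self.arg is None:
            raise ValueError("ARGLMM requires an ARG")
        return self.arg if isinstance(self.arg, ArgData) else ArgData(self.arg)

    def _resolve_scale(self, arg: ArgData) -> float:
        if self.normalize is True:
            return 1.0 / (4.0 * total_root_area(arg))
        if self.normalize is False:
            return 1.0
        return float(self.normalize)

    def _operator(self, arg, rows=None, cols=None, centered=False):
        return BranchGRMOperator(
            arg,
            centered=centered,
            scale=self.grm_scale_,
            rows=rows,
            cols=cols,
        )

    # -- estimator API -------------------------------------------------

    def fit(self, X, y):
        """Estimate variance components from observed phenotypes.

        ``X`` is the (N_o, K) covariate matrix for the observed
        individuals (an intercept column is appended when absent, since
        mean mutational effects are absorbed into the intercept);
        ``X=None`` means intercept only.
        """
        arg = self._arg_data()
        y = np.asarray(y, dtype=float).ravel()
        n_obs = y.shape[0]
        obs = (
            np.arange(arg.num_individuals)
            if self.obs_index is None
            else np.asarray(self.obs_index, dtype=np.intp)
        )
        if len(obs) != n_obs:
            raise ValueError(
                f"{n_obs} phenotypes for {len(obs)} observed individuals"
            )
        X = _with_intercept(X, n_obs)
        self.grm_scale_ = self._resolve_scale(arg)
        self.obs_index_ = obs
        B_oo = self._operator(arg, rows=obs, cols=obs)
        config = self.config or RemlConfig()
        if self.method == "he":
            theta = he_initialize(
                B_oo, y, X, n_vectors=config.n_he_vectors, seed=config.seed
            )
            theta = VarianceComponents(max(theta.tau2, 0.0), max(theta.sigma_e2, 0.0))
            self.fit_result_ = RemlFit(
                theta=theta,
                history=[],
                converged=True,
                n_iter=0,
                grm_scale=self.grm_scale_,
                config=config,
            )
        elif self.method == "reml":
            self.fit_result_ = fit_reml_operator(B_oo, y, X, config)
            self.fit_result_.grm_scale = self.grm_scale_
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.tau2_ = self.fit_result_.theta.tau2
        self.sigma_e2_ = self.fit_result_.theta.sigma_e2
        self.beta_ = self.fit_result_.beta
        self._y = y
        self._X = X
        self._arg = arg
        return self

    def predict(self, target_index=None, with_variance: bool = False):
        """Empirical BLUPs of genetic values for target individuals.

        Delegates to :func:`arglmm.predict.predict_blup`; see there for
        the conditional-mean formula.  Returns the predicted vector, or
        a :class:`~arglmm.predict.BlupResult` when ``with_variance``.
        """
        from .predict import predict_blup

        self._check_fitted()
        if target_index is None:
            target_index = np.arange(self._arg.num_individuals)
        result = predict_blup(
            self._arg,
            self.fit_result_,
            self._y,
            self._X,
            obs_index=self.obs_index_,
            target_index=np.asarray(target_index, dtype=np.intp),
            with_variance=with_variance,
            grm_scale=self.grm_scale_,
        )
        return result if with_variance else result.predicted

    def estimate_vg(self, n_vectors: int = 50, seed: int = 0):
        """Additive genetic variance of the sample, tau2 * tr(Bc)/N, with SD."""
        self._check_fitted()
        Bc = self._operator(self._arg, centered=True)
        return _estimate_vg(self.fit_result_, Bc, n_vectors=n_vectors, seed=seed)

    def _check_fitted(self):
        if not hasattr(self, "fit_result_"):
            raise ValueError("this ARGLMM instance is not fitted yet")


def _with_intercept(X, n_obs: int) -> np.ndarray:
    if X is None:
        return np.ones((n_obs, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n_obs:
        raise ValueError("X and y have inconsistent lengths")
    # a column with zero variance acts as the intercept
    if not np.any(np.ptp(X, axis=0) == 0):
        X = np.column_stack([np.ones(n_obs), X])
    return X
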