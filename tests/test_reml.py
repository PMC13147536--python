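"""REML machinery: projections, gradients, AI matrix, HE, and the fits."""

import numpy as np
import pytest

from arglmm import (
    DenseOperator,
    RemlConfig,
    RemlState,
    VarianceComponents,
    average_information,
    dense_branch_grm,
    dense_spectral_reml,
    estimate_vg,
    he_initialize,
    project_P,
    reml_gradient,
    simulate_genetic_values,
)
from arglmm.grm import BranchGRMOperator
from arglmm.linalg import operator_to_dense
from arglmm.reml import fit_reml_operator, gls_coefficients


def dense_P(B, X, theta):
    n = B.shape[0]
    V = theta.tau2 * B + theta.sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    G = X.T @ Vi @ X
    return Vi - Vi @ X @ np.linalg.solve(G, X.T @ Vi)


@pytest.fixture(scope="module")
def arg_instance(medium_diploid_arg):
    """100-individual ARG instance with simulated phenotypes."""
    arg = medium_diploid_arg
    n = arg.num_individuals
    B = dense_branch_grm(arg, engine="tskit")
    scale = n / np.trace(B)  # unit average diagonal, keeps tau2 O(1)
    B = B * scale
    rng = np.random.default_rng(12)
    g = simulate_genetic_values(arg, tau2=1.0, seed=77) * np.sqrt(scale)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ np.array([0.5, -0.2]) + 0.8 * g + rng.normal(0, 1.0, n)
    Bop = BranchGRMOperator(arg, scale=scale)
    return arg, B, Bop, y, X


class TestProjectP:
    def test_null_model_is_centering(self):
        """tau2=0, sige2=1, intercept only: P = I - 11'/N."""
        rng = np.random.default_rng(0)
        n = 40
        y = rng.standard_normal(n)
        state = RemlState(
            y, np.ones((n, 1)), VarianceComponents(0.0, 1.0),
            DenseOperator(np.zeros((n, n))), cg_tol=1e-12,
        )
        v = rng.standard_normal(n)
        assert np.allclose(project_P(state, v), v - v.mean(), atol=1e-9)

    def test_annihilates_covariates(self, arg_instance):
        _, B, Bop, y, X = arg_instance
        theta = VarianceComponents(0.4, 1.0)
        state = RemlState(y, X, theta, Bop, cg_tol=1e-10)
        px = project_P(state, X)
        assert np.linalg.norm(px) <= 1e-6 * np.linalg.norm(np.linalg.pinv(
            theta.tau2 * B + np.eye(len(y))) @ X)

    def test_matches_dense_projection(self, arg_instance):
        _, B, Bop, y, X = arg_instance
        theta = VarianceComponents(0.6, 0.9)
        state = RemlState(y, X, theta, Bop, cg_tol=1e-11)
        rng = np.random.default_rng(1)
        v = rng.standard_normal(len(y))
        ref = dense_P(B, X, theta) @ v
        assert np.linalg.norm(project_P(state, v) - ref) <= 1e-6 * np.linalg.norm(ref)

    def test_py_equals_vinv_residual(self, arg_instance):
        _, B, Bop, y, X = arg_instance
        theta = VarianceComponents(0.6, 0.9)
        state = RemlState(y, X, theta, Bop, cg_tol=1e-11)
        assert np.allclose(state.py, project_P(state, y), atol=1e-6)


class TestGlsCoefficients:
    def test_identity_covariance_reduces_to_ols(self, arg_instance):
        _, _, _, y, X = arg_instance
        n = len(y)
        state = RemlState(
            y, X, VarianceComponents(0.0, 1.0),
            DenseOperator(np.zeros((n, n))), cg_tol=1e-12,
        )
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(gls_coefficients(state), ols, atol=1e-8)

    def test_intercept_only_is_mean(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(30)
        state = RemlState(
            y, np.ones((30, 1)), VarianceComponents(0.0, 2.0),
            DenseOperator(np.zeros((30, 30))), cg_tol=1e-12,
        )
        assert gls_coefficients(state)[0] == pytest.approx(y.mean(), abs=1e-9)

    def test_matches_dense_gls(self, arg_instance):
        _, B, Bop, y, X = arg_instance
        theta = VarianceComponents(0.5, 1.2)
        state = RemlState(y, X, theta, Bop, cg_tol=1e-11)
        V = theta.tau2 * B + theta.sigma_e2 * np.eye(len(y))
        Vi = np.linalg.inv(V)
        ref = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(gls_coefficients(state), ref, atol=1e-7)

    def test_rank_deficient_x_rejected(self):
        y = np.arange(10.0)
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            RemlState(y, X, VarianceComponents(0.0, 1.0),
                      DenseOperator(np.zeros((10, 10))))


class TestRemlGradient:
    def test_exact_traces_match_dense_gradient(self, arg_instance):
        _, B, Bop, y, X = arg_instance
        theta = VarianceComponents(0.7, 1.1)
        state = RemlState(y, X, theta, Bop, cg_tol=1e-11)
        g = reml_gradient(state, exact_traces=True)
        P = dense_P(B, X, theta)
        Py = P @ y
        ref = np.array([np.trace(P) - Py @ Py, np.trace(P @ B) - Py @ (B @ Py)])
        assert np.all(np.abs(g - ref) <= 1e-6 * np.abs(ref))

    def test_null_model_closed_form(self):
        """Intercept-only, tau2=0: d/dsige2 vanishes iff sige2 = s^2."""
        rng = np.random.default_rng(3)
        n = 60
        y = rng.standard_normal(n) * 1.7
        s2 = float(np.sum((y - y.mean()) ** 2) / (n - 1))
        scores = {}
        for sige2 in (0.5 * s2, s2, 2.0 * s2):
            state = RemlState(
                y, np.ones((n, 1)), VarianceComponents(0.0, sige2),
                DenseOperator(np.zeros((n, n))), cg_tol=1e-12,
            )
            g = reml_gradient(state, exact_traces=True)
            ref = (n - 1) * (1.0 - s2 / sige2) / sige2
            assert g[0] == pytest.approx(ref, abs=1e-6 * max(abs(ref), 1.0))
            scores[sige2] = g[0]
        # the score vanishes exactly at the REML solution sige2 = s2
        assert abs(scores[s2]) < 1e-6
        assert scores[0.5 * s2] < 0 < scores[2.0 * s2]

    def test_stochastic_gradient_zero_at_dense_optimum(self, arg_instance):
        """At the dense REML optimum both score components sit within
        4 trace-estimator SEs of zero."""
        _, B, Bop, y, X = arg_instance
        theta = dense_spectral_reml(B, y, X)
        state = RemlState(y, X, theta, Bop, cg_tol=1e-10)
        state.n_trace_vectors = 50
        # exact-trace score at the optimum is ~0; stochastic one deviates
        # only by trace-estimation noise
        from arglmm.linalg import CallableOperator, xtrace

        g = reml_gradient(state, seed=5)
        se_v = xtrace(CallableOperator(state.n, state.vinv), 50, seed=123).stderr
        se_vb = xtrace(
            CallableOperator(state.n, lambda Z: state.vinv(Bop.matmat(Z))),
            50, seed=124,
        ).stderr
        assert abs(g[0]) <= 4 * se_v + 1e-6
        assert abs(g[1]) <= 4 * se_vb + 1e-6


class TestAverageInformation:
    def test_zero_phenotype_gives_zero_matrix(self):
        n = 25
        state = RemlState(
            np.zeros(n), None if False else np.ones((n, 1)),
            VarianceComponents(0.2, 1.0), DenseOperator(np.eye(n)),
            cg_tol=1e-10,
        )
        # y = 0 makes every quadratic form vanish
        assert np.allclose(average_information(state), 0.0, atol=1e-12)

    def test_exactly_symmetric(self, arg_instance):
        _, _, Bop, y, X = arg_instance
        state = RemlState(y, X, VarianceComponents(0.5, 1.0), Bop, cg_tol=1e-8)
        ai = average_information(state)
        assert ai[0, 1] == ai[1, 0]

    def test_matches_half_hessian_plus_fisher(self, arg_instance):
        """AI equals (Hessian + Fisher)/2 of the dense objective."""
        _, B, Bop, y, X = arg_instance
        theta = VarianceComponents(0.5, 1.0)
        state = RemlState(y, X, theta, Bop, cg_tol=1e-11)
        ai = average_information(state)
        P = dense_P(B, X, theta)
        Py = P @ y

        def ell(tau2, sige2):
            n = len(y)
            V = tau2 * B + sige2 * np.eye(n)
            Vi = np.linalg.inv(V)
            G = X.T @ Vi @ X
            Pd = Vi - Vi @ X @ np.linalg.solve(G, X.T @ Vi)
            return (
                np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(G)[1]
                + y @ Pd @ y
            )

        h = 1e-4
        t, s = theta.tau2, theta.sigma_e2
        # Hessian in (sige2, tau2) ordering by central differences
        def grad(t_, s_):
            return np.array([
                (ell(t_, s_ + h) - ell(t_, s_ - h)) / (2 * h),
                (ell(t_ + h, s_) - ell(t_ - h, s_)) / (2 * h),
            ])

        H = np.column_stack([
            (grad(t, s + h) - grad(t, s - h)) / (2 * h),
            (grad(t + h, s) - grad(t - h, s)) / (2 * h),
        ])
        Vdots = [np.eye(len(y)), B]
        F = np.array([
            [np.trace(P @ Vdots[i] @ P @ Vdots[j]) for j in range(2)]
            for i in range(2)
        ])
        avg = (H + F) / 2
        assert np.allclose(ai, avg, rtol=5e-4)

    def test_psd_along_fit_history(self, arg_instance):
        _, _, Bop, y, X = arg_instance
        fit = fit_reml_operator(Bop, y, X, RemlConfig(seed=2, max_iter=40))
        for rec in fit.history:
            eig = np.linalg.eigvalsh(rec.ai)
            assert eig.min() >= -1e-8 * max(eig.max(), 1e-12)


class TestHasemanElston:
    def test_zero_phenotype(self, arg_instance):
        _, _, Bop, y, X = arg_instance
        theta = he_initialize(Bop, np.zeros(len(y)), None)
        assert theta.tau2 == 0.0 and theta.sigma_e2 == 0.0

    def test_exact_traces_match_dense_solve(self, arg_instance):
        _, B, Bop, y, X = arg_instance
        theta = he_initialize(DenseOperator(B), y, X, exact_traces=True)
        n, k = X.shape
        Px = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
        Bt = Px @ B @ Px
        r = Px @ y
        A = np.array([[np.sum(Bt * Bt), np.trace(Bt)], [np.trace(Bt), n - k]])
        ref = np.linalg.solve(A, [r @ B @ r, r @ r])
        assert np.allclose([theta.tau2, theta.sigma_e2], ref, rtol=1e-8)

    def test_stochastic_traces_approach_dense_solve(self, arg_instance):
        _, B, Bop, y, X = arg_instance
        exact = he_initialize(DenseOperator(B), y, X, exact_traces=True)
        stoch = he_initialize(Bop, y, X, n_vectors=50, seed=3)
        assert stoch.tau2 == pytest.approx(exact.tau2, abs=0.3 * max(abs(exact.tau2), 0.1))
        assert stoch.sigma_e2 == pytest.approx(exact.sigma_e2, rel=0.3)

    def test_identity_grm_is_singular(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="singular"):
            he_initialize(
                DenseOperator(np.eye(50)), rng.standard_normal(50),
                exact_traces=True,
            )


class TestDenseSpectralReml:
    def test_null_model_recovers_residual_variance(self):
        """B = 0: REML sige2 is the unbiased residual variance."""
        rng = np.random.default_rng(5)
        n, k = 80, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
        y = X @ rng.standard_normal(k) + rng.normal(0, 1.3, n)
        theta = dense_spectral_reml(np.zeros((n, n)), y, X)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        ref = float(resid @ resid / (n - k))
        assert theta.sigma_e2 == pytest.approx(ref, rel=1e-5)

    def test_optimum_beats_local_grid(self, arg_instance):
        _, B, _, y, X = arg_instance
        theta = dense_spectral_reml(B, y, X)
        n = len(y)

        def ell(tau2, sige2):
            V = tau2 * B + sige2 * np.eye(n)
            Vi = np.linalg.inv(V)
            G = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.solve(G, X.T @ Vi)
            return np.linalg.slogdet(V)[1] + np.linalg.slogdet(G)[1] + y @ P @ y

        best = ell(theta.tau2, theta.sigma_e2)
        for dt in np.linspace(-0.1, 0.1, 5):
            for ds in np.linspace(-0.1, 0.1, 4):
                t = max(theta.tau2 + dt, 0.0)
                s = max(theta.sigma_e2 + ds, 1e-8)
                assert best <= ell(t, s) + 1e-6

    def test_recovers_generating_components(self):
        """Across replicates on one GRM the mean estimate brackets truth."""
        rng = np.random.default_rng(6)
        n = 150
        Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        lam = np.sort(np.abs(rng.standard_normal(n)))[::-1] * 2
        B = (Q * lam) @ Q.T
        L = Q * np.sqrt(lam)
        X = np.ones((n, 1))
        taus, sigs = [], []
        for _ in range(40):
            g = L @ rng.standard_normal(n) * np.sqrt(0.8)
            y = 1.0 + g + rng.normal(0, 1.0, n)
            th = dense_spectral_reml(B, y, X)
            taus.append(th.tau2)
            sigs.append(th.sigma_e2)
        assert abs(np.mean(taus) - 0.8) <= 4 * np.std(taus) / np.sqrt(40)
        assert abs(np.mean(sigs) - 1.0) <= 4 * np.std(sigs) / np.sqrt(40)


class TestFitReml:
    def test_tau2_zero_data(self, medium_diploid_arg):
        """Pure-noise phenotypes: tau2 shrinks to ~0, sige2 to var(y)."""
        arg = medium_diploid_arg
        n = arg.num_individuals
        rng = np.random.default_rng(7)
        y = rng.normal(0.0, 1.5, n)
        B = dense_branch_grm(arg, engine="tskit")
        Bop = BranchGRMOperator(arg, scale=n / np.trace(B))
        fit = fit_reml_operator(Bop, y, np.ones((n, 1)), RemlConfig(seed=1))
        assert fit.converged
        # tau2 small relative to total variance; sige2 near sample variance
        assert fit.tau2 <= 0.5
        assert fit.sigma_e2 == pytest.approx(float(np.var(y, ddof=1)), rel=0.35)

    def test_constant_phenotype_rejected(self, medium_diploid_arg):
        arg = medium_diploid_arg
        n = arg.num_individuals
        Bop = BranchGRMOperator(arg)
        with pytest.raises(ValueError, match="constant"):
            fit_reml_operator(Bop, np.ones(n), np.ones((n, 1)), RemlConfig())

    def test_history_and_window_average(self, arg_instance):
        _, _, Bop, y, X = arg_instance
        cfg = RemlConfig(seed=3)
        fit = fit_reml_operator(Bop, y, X, cfg)
        assert fit.converged
        tail = np.array([r.theta.as_array() for r in fit.history[-cfg.min_post_steps:]])
        assert np.allclose(fit.theta.as_array(), tail.mean(axis=0), atol=1e-12)
        assert len(fit.history) == fit.n_iter + 1

    def test_matches_dense_oracle_within_seed_spread(self, arg_instance):
        """Stochastic fits scatter around the dense REML optimum."""
        _, B, Bop, y, X = arg_instance
        dense = dense_spectral_reml(B, y, X)
        fits = [fit_reml_operator(Bop, y, X, RemlConfig(seed=s)) for s in range(6)]
        taus = np.array([f.tau2 for f in fits])
        sigs = np.array([f.sigma_e2 for f in fits])
        assert abs(taus.mean() - dense.tau2) <= 2 * max(taus.std(), 0.02)
        assert abs(sigs.mean() - dense.sigma_e2) <= 2 * max(sigs.std(), 0.02)


class TestEstimateVg:
    def test_zero_tau2(self, arg_instance):
        _, _, Bop, y, X = arg_instance
        fit = fit_reml_operator(Bop, y, X, RemlConfig(seed=1, max_iter=2))
        fit.theta = VarianceComponents(0.0, 1.0)
        vg, se = estimate_vg(fit, Bop)
        assert vg == 0.0 and se == 0.0

    def test_matches_dense_centered_trace(self, arg_instance):
        arg, _, Bop, y, X = arg_instance
        n = Bop.dim
        fit = fit_reml_operator(Bop, y, X, RemlConfig(seed=4))
        Bc_dense = dense_branch_grm(arg, centered=True, engine="tskit") * Bop.scale
        Bc = BranchGRMOperator(arg, centered=True, scale=Bop.scale)
        vg, se = estimate_vg(fit, Bc, n_vectors=50, seed=9)
        ref = fit.tau2 * np.trace(Bc_dense) / n
        ref_se = fit.tau2 * np.sqrt(2.0 * np.sum(Bc_dense**2)) / n
        assert vg == pytest.approx(ref, rel=0.1)
        assert se == pytest.approx(ref_se, rel=0.25)

    def test_moments_match_generative_draws(self, small_diploid_arg):
        """Mean and SD of VG over many effect draws match the formulas."""
        arg = small_diploid_arg
        n = arg.num_individuals
        tau2 = 1.3
        n_rep = 2000
        g = simulate_genetic_values(arg, tau2, seed=21, n_replicates=n_rep)
        gc = g - g.mean(axis=0, keepdims=True)
        vg_draws = np.einsum("ij,ij->j", gc, gc) / n
        Bc = dense_branch_grm(arg, centered=True)
        evg = tau2 * np.trace(Bc) / n
        sd_vg = tau2 * np.sqrt(2.0 * np.sum(Bc**2)) / n
        mc_se_mean = vg_draws.std(ddof=1) / np.sqrt(n_rep)
        assert abs(vg_draws.mean() - evg) <= 4 * mc_se_mean
        # variance of a quadratic form: compare SDs with a generous MC band
        assert vg_draws.std(ddof=1) == pytest.approx(sd_vg, rel=0.15)
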