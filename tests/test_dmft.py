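import numpy as np
import pytest
from scipy import integrate as sint
from scipy import optimize, stats

from metalv.dmft import (
    DMFTSolution,
    RepresentativeParams,
    equilibrium_theory,
    exponential_kernel,
    generate_colored_noise,
    predicted_nstar_distribution,
    self_consistent_solve,
    simulate_representative,
    _draw_equicorrelated,
)
from metalv.ensemble import DisorderScales


class TestColoredNoise:
    def test_delta_like_kernel_variance(self):
        def ker(lag):
            return np.where(np.asarray(lag) == 0.0, 0.25, 0.0)

        x = generate_colored_noise(ker, T=50.0, dt=0.1, n_paths=300, seed=0)
        assert abs(x.var() - 0.25) < 0.01
        lag1 = (x[:, :-1] * x[:, 1:]).mean()
        assert abs(lag1) < 0.01

    def test_exponential_kernel_autocorrelation(self):
        A, tau0 = 0.4, 2.0
        x = generate_colored_noise(
            exponential_kernel(A, tau0), T=200.0, dt=0.05, n_paths=600, seed=1
        )
        assert abs(x.var() - A) / A < 0.03
        k = int(tau0 / 0.05)
        ac = (x[:, :-k] * x[:, k:]).mean()
        assert abs(ac - A / np.e) / (A / np.e) < 0.05

    def test_zero_kernel_gives_zero_paths(self):
        x = generate_colored_noise(lambda lag: 0.0 * np.asarray(lag),
                                   T=10.0, dt=0.1, n_paths=4, seed=2)
        assert (x == 0).all()

    def test_non_psd_kernel_clipped_with_warning(self):
        lags = np.arange(0, 10.0, 0.5)
        vals = np.cos(2.0 * lags) * np.exp(-0.01 * lags)  # nearly undamped
        with pytest.warns(UserWarning, match="not PSD"):
            x = generate_colored_noise((lags, vals), T=5.0, dt=0.5,
                                       n_paths=10, seed=3)
        assert np.isfinite(x).all()


class TestRepresentative:
    def test_noiseless_relaxation_to_characteristic_abundance(self):
        rep = RepresentativeParams(M=1, N_star=np.array([0.7]))
        run = simulate_representative(rep, 60.0, 0.01, 2, seed=0,
                                      N0=np.array([0.05]))
        assert np.allclose(run.final, 0.7, atol=1e-6)

    def test_negative_characteristic_abundance_decays_to_extinction(self):
        rep = RepresentativeParams(M=1, N_star=np.array([-0.5]))
        run = simulate_representative(rep, 80.0, 0.01, 2, N_c=1e-8, seed=0,
                                      N0=np.array([0.5]), checkpoint_dt=1.0)
        assert not run.surviving.any()
        assert np.isfinite(run.first_passage).all()

    def test_source_patch_exports_on_average(self):
        # N* = (0.5, -0.5): patch 1 sustains the species and feeds patch 2
        ker = exponential_kernel(0.01, 2.0)
        rep = RepresentativeParams(M=2, N_star=np.array([0.5, -0.5]), d=0.05,
                                   kernel=ker)
        run = simulate_representative(rep, 400.0, 0.02, 100, seed=4,
                                      store_stride=50, checkpoint_dt=1.0)
        X = run.N[:, :, run.times > 100]
        D = rep.D
        diff = np.einsum("rvt,uv->rut", X, D) - X * D.sum(axis=1)[None, :, None]
        assert diff[:, 0].mean() < 0 < diff[:, 1].mean()

    def test_coarse_step_rejected(self):
        rep = RepresentativeParams(M=1, N_star=np.array([5.0]))
        with pytest.raises(ValueError, match="too coarse"):
            simulate_representative(rep, 10.0, 0.5, 3, seed=0,
                                    N0=np.array([0.1]))


class TestSelfConsistent:
    def test_noiseless_limit_matches_homogeneous_solution(self):
        sc = DisorderScales(mu_tot=2.0, sigma=1e-9)
        sol = self_consistent_solve(sc, B=1.0, M=1, max_iter=8,
                                    n_realizations=40, T=200, burn_in=50,
                                    damping=0.5)
        assert np.isclose(sol.mean_N, 1.0 / 3.0, rtol=1e-3)
        assert sol.phi == 1.0
        assert np.abs(sol.C_xi).max() < 1e-10

    def test_subcritical_noise_agrees_with_static_cavity(self):
        # below the instability the kernel dies out and the moments
        # close on the equilibrium cavity solution
        sc = DisorderScales(mu_tot=2.0, sigma=0.8)
        sol = self_consistent_solve(sc, B=1.0, M=1, N_c=1e-10, T=400,
                                    burn_in=150, dt=0.05, n_realizations=400,
                                    damping=0.5, max_iter=40, tol=8e-3, seed=3)
        eq = equilibrium_theory(sc, B=1.0)
        assert sol.std_xi < 0.05
        assert np.isclose(sol.mean_N, eq["mean_N"], rtol=0.02)
        assert np.isclose(sol.phi, eq["phi"], atol=0.02)

    def test_jensen_inequality_and_kernel_shape(self):
        sc = DisorderScales(mu_tot=10.0, sigma=3.0)
        sol = self_consistent_solve(sc, B=1.0, M=1, N_c=1e-10, T=300,
                                    burn_in=100, dt=0.05, n_realizations=300,
                                    damping=0.5, max_iter=25, tol=2e-2, seed=2)
        assert sol.q >= sol.mean_N**2
        assert sol.C_xi[0] == np.abs(sol.C_xi).max()
        assert 0.0 <= sol.phi <= 1.0

    def test_matched_drive_reproduces_direct_histogram(
        self, scaled_fluctuating_system
    ):
        """Feeding the simulation-measured kernel and N* statistics into
        the representative metapopulation reproduces the simulation's
        stationary abundance distribution (the mapping itself, decoupled
        from the self-consistency iteration)."""
        from metalv import observables as obs
        from metalv.dynamics import integrate
        from metalv.ensemble import disorder_scales

        sys = scaled_fluctuating_system
        sc = disorder_scales(sys.params)
        traj = integrate(sys, horizon=4000.0, store_every=2, seed=8)
        win = (2000.0, 4000.0)
        w = traj.window(*win)
        surv = w.alive[0] & w.alive[-1]
        phi = surv.mean()
        X = w.N[:, surv, :]
        means = X.mean(axis=0)
        m_pool = phi * means.mean()
        q_w = phi * (means**2).mean()
        prod = means[:, :, None] * means[:, None, :]
        q_x = phi * prod[:, ~np.eye(4, dtype=bool)].mean()
        ker = obs.stationary_kernel(traj, sc.sigma, win)
        h = 1.0 - sc.mu_tot * m_pool
        rng = np.random.default_rng(123)
        Nstar = _draw_equicorrelated(
            rng, 400, 4, h, sc.sigma**2 * q_w, sc.sigma**2 * 0.9 * q_x
        )
        rep = RepresentativeParams(M=4, N_star=Nstar, d=0.01,
                                   kernel=(ker.lags, phi * ker.C_xi))
        run = simulate_representative(rep, 800.0, 0.05, 400, N_c=1e-8,
                                      rng=rng, store_stride=20,
                                      checkpoint_dt=1.0)
        pred = run.N[run.surviving][:, :, run.times > 300].ravel()
        pred = pred[pred > 0]
        direct = X[::10].ravel()
        ks = stats.ks_2samp(direct, pred).statistic
        assert ks < 0.1
        assert abs(run.surviving.mean() - phi) < 0.1


class TestEquilibriumTheory:
    def test_zero_heterogeneity(self):
        sc = DisorderScales(mu_tot=3.0, sigma=0.0)
        eq = equilibrium_theory(sc, B=1.0, S=50)
        assert eq["phi"] == 1.0
        assert np.isclose(eq["mean_N"], 0.25)
        assert eq["diversity_bound"] == 50.0

    def test_moment_equations_satisfied_by_quadrature(self):
        # independent oracle: plug the solver output back into the
        # truncated-Gaussian moment integrals evaluated by quadrature
        sc = DisorderScales(mu_tot=9.375, sigma=np.sqrt(8.789))
        eq = equilibrium_theory(sc, B=1.0, S=250)
        m, q, phi = eq["mean_N"], eq["q"], eq["phi"]
        sq = sc.sigma * np.sqrt(q)
        h = 1.0 - sc.mu_tot * m

        def trunc(k):
            f = lambda z: max(h + sq * z, 0.0) ** k * stats.norm.pdf(z)
            return sint.quad(f, -12, 12)[0]

        assert np.isclose(trunc(1), m, rtol=1e-6)
        assert np.isclose(trunc(2), q, rtol=1e-6)
        assert np.isclose(trunc(0) - stats.norm.cdf(-h / sq), phi, atol=1e-9)

    def test_bound_monotone_in_heterogeneity(self):
        bounds = [
            equilibrium_theory(DisorderScales(mu_tot=5.0, sigma=s), B=1.0,
                               S=100)["diversity_bound"]
            for s in (0.5, 1.0, 1.5, 2.0, 3.0)
        ]
        assert all(b1 >= b2 for b1, b2 in zip(bounds, bounds[1:]))


class TestNstarDistribution:
    def _toy_solution(self, M=4, var=0.09, rho_frac=0.5):
        lags = np.linspace(0, 10, 11)
        return DMFTSolution(
            mean_Nstar=0.2, var_Nstar=var, cov_Nstar_cross=rho_frac * var,
            phi=0.6, mean_N=0.3, q=0.2, lags=lags,
            C_xi=0.1 * np.exp(-lags / 3), C_N=0.1 * np.exp(-lags / 3),
            converged=True, iterations=5, residual_history=[], sigma=1.0,
            mu_tot=5.0, M=M, rho=0.5, d=0.01, B=1.0,
        )

    def test_single_patch_reduces_to_gaussian_marginal(self):
        sol = self._toy_solution(M=1)
        grid, dens, phi = predicted_nstar_distribution(sol, M=1)
        expect = stats.norm.pdf(grid, 0.2, 0.3)
        assert np.allclose(dens, expect, rtol=1e-6, atol=1e-9)
        assert np.isclose(phi, 1 - stats.norm.cdf(-0.2 / 0.3), atol=1e-6)

    def test_density_integrates_to_survival_probability(self):
        sol = self._toy_solution(M=4)
        grid, dens, phi = predicted_nstar_distribution(sol)
        # extend the grid upward so the positive mass is fully covered
        grid = np.linspace(0, 3.0, 2000)
        grid, dens, phi = predicted_nstar_distribution(sol, grid=grid)
        integral = np.trapezoid(dens, grid)
        assert abs(integral - phi) < 1e-3

    def test_unconverged_solution_refused(self):
        sol = self._toy_solution()
        sol.converged = False
        with pytest.raises(ValueError):
            predicted_nstar_distribution(sol)
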