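import numpy as np
import pytest

from metalv.dynamics import (
    TrajectorySet,
    anneal_to_fixed_point,
    apply_extinction_rule,
    detect_fixed_point,
    integrate,
    rhs,
)
from metalv.ensemble import EnsembleParams, InteractionSet, migration_matrix, sample_interactions


def _bare_system(S, M, B=1.0, d=0.0, N_c=1e-8):
    params = EnsembleParams(S=S, M=M, c=0.0, mu_A=0.0, sd_A=0.0, d=d, N_c=N_c)
    return InteractionSet(
        A=np.zeros((S, S, M)),
        B=np.full((S, M), B),
        D=migration_matrix(M, d),
        mask=np.zeros((S, S), dtype=bool),
        params=params,
    )


class TestRhs:
    def test_logistic_rate(self):
        sys = _bare_system(1, 1)
        assert np.isclose(rhs(np.array([[0.5]]), sys)[0, 0], 0.25)

    def test_pure_diffusion(self):
        sys = _bare_system(1, 2, d=0.1)
        r = rhs(np.array([[1.0, 0.0]]), sys)
        assert np.isclose(r[0, 1], 0.1)

    def test_matches_scalar_loop_oracle(self, small_random_system):
        sys = small_random_system
        rng = np.random.default_rng(0)
        N = rng.uniform(0.1, 1.0, (sys.S, sys.M))
        expected = np.zeros_like(N)
        for i in range(sys.S):
            for u in range(sys.M):
                inter = sum(sys.A[i, j, u] * N[j, u] for j in range(sys.S))
                growth = N[i, u] * (sys.B[i, u] - N[i, u] - inter)
                migr = sum(
                    sys.D[u, v] * (N[i, v] - N[i, u]) for v in range(sys.M)
                )
                expected[i, u] = growth + migr
        assert np.allclose(rhs(N, sys), expected, atol=1e-12)

    def test_shape_and_nan_rejected(self, small_random_system):
        with pytest.raises(ValueError):
            rhs(np.ones((3, 3)), small_random_system)
        bad = np.ones((10, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            rhs(bad, small_random_system)


class TestExtinctionRule:
    def test_survives_in_one_patch(self):
        N = np.array([[0.5e-8, 2e-8]])
        out, removed = apply_extinction_rule(N, 1e-8)
        assert removed == [] and np.array_equal(out, N)

    def test_below_everywhere_removed(self):
        N = np.array([[0.5e-8, 0.9e-8]])
        out, removed = apply_extinction_rule(N, 1e-8)
        assert removed == [0] and (out == 0).all()

    def test_boundary_is_strict(self):
        N = np.array([[1e-8]])
        out, removed = apply_extinction_rule(N, 1e-8)
        assert removed == []


class TestIntegrate:
    def test_two_species_symmetric_equilibrium(self, two_species_symmetric):
        traj = integrate(
            two_species_symmetric, N0=np.array([[0.3], [0.9]]), horizon=80.0
        )
        assert np.allclose(traj.final_state(), 2 / 3, atol=1e-6)

    def test_nonnegativity_and_extinct_stay_zero(self, scaled_fluctuating_system):
        traj = integrate(scaled_fluctuating_system, horizon=300.0,
                         store_every=5, seed=1)
        assert (traj.N >= 0).all()
        for sp, t_ext in traj.extinction_log:
            after = traj.times >= t_ext
            assert (traj.N[after, sp, :] == 0).all()
        s_star = traj.alive.sum(axis=1)
        assert (np.diff(s_star) <= 0).all()

    def test_decoupled_patches_match_independent_runs(self):
        p = EnsembleParams(S=12, M=2, c=0.5, mu_A=0.2, sd_A=0.2, rho=0.0,
                           d=0.0, N_c=1e-8, seed=4)
        sys = sample_interactions(p)
        N0 = np.random.default_rng(1).uniform(0.2, 1.0, (12, 2))
        joint = integrate(sys, N0=N0, horizon=150.0)
        for u in range(2):
            sub = InteractionSet(
                A=sys.A[:, :, u][:, :, None],
                B=sys.B[:, [u]],
                D=np.zeros((1, 1)),
                mask=sys.mask,
                params=p.replace(M=1, rho=0.0),
            )
            alone = integrate(sub, N0=N0[:, [u]], horizon=150.0)
            assert np.allclose(
                joint.final_state()[:, u], alone.final_state()[:, 0], atol=1e-5
            )

    def test_species_relabeling_equivariance(self, small_random_system):
        sys = small_random_system
        rng = np.random.default_rng(7)
        N0 = rng.uniform(0.2, 1.0, (sys.S, sys.M))
        perm = rng.permutation(sys.S)
        permed = InteractionSet(
            A=sys.A[np.ix_(perm, perm)],
            B=sys.B[perm],
            D=sys.D,
            mask=sys.mask[np.ix_(perm, perm)],
            params=sys.params,
        )
        a = integrate(sys, N0=N0, horizon=60.0)
        b = integrate(permed, N0=N0[perm], horizon=60.0)
        assert np.allclose(a.final_state()[perm], b.final_state(), atol=1e-6)

    def test_tolerance_convergence(self, small_random_system):
        N0 = np.random.default_rng(2).uniform(0.2, 1.0, (10, 2))
        loose = integrate(small_random_system, N0=N0, horizon=30.0,
                          rtol=1e-6, atol=1e-10)
        tight = integrate(small_random_system, N0=N0, horizon=30.0,
                          rtol=1e-8, atol=1e-12)
        assert np.abs(loose.final_state() - tight.final_state()).max() < 1e-4

    def test_hdf5_roundtrip(self, small_random_system, tmp_path):
        traj = integrate(small_random_system, horizon=20.0, seed=3)
        path = tmp_path / "traj.h5"
        traj.to_hdf5(path)
        back = TrajectorySet.from_hdf5(path)
        assert np.array_equal(back.N, traj.N)
        assert back.extinction_log == traj.extinction_log
        assert back.params == traj.params
        df = traj.to_frame()
        assert len(df) == traj.N.size


class TestFixedPoint:
    def test_all_zero_state_is_fixed_point(self, small_random_system):
        rep = detect_fixed_point(np.zeros((10, 2)), small_random_system)
        assert rep.is_fixed_point and rep.residual == 0.0

    def test_two_species_equilibrium_detected(self, two_species_symmetric):
        rep = detect_fixed_point(
            np.full((2, 1), 2 / 3), two_species_symmetric, tol=1e-8
        )
        assert rep.is_fixed_point

    def test_transient_state_is_not_fixed_point(self, scaled_fluctuating_system):
        traj = integrate(scaled_fluctuating_system, horizon=50.0, seed=1)
        rep = detect_fixed_point(traj, scaled_fluctuating_system, tol=1e-8)
        assert not rep.is_fixed_point


class TestAnneal:
    def test_equilibrium_returned_unchanged(self, two_species_symmetric):
        state = np.full((2, 1), 2 / 3)
        out, rep, hist = anneal_to_fixed_point(two_species_symmetric, state)
        assert rep.is_fixed_point
        assert np.allclose(out, 2 / 3, atol=1e-6)
        assert hist["cutoffs"][0] == two_species_symmetric.params.N_c

    def test_marginal_species_removed_first(self):
        # five independent logistic species; one has carrying capacity
        # 10 * N_c, so the rising cutoff removes it first
        S, N_c = 5, 1e-4
        B = np.ones((S, 1))
        B[0, 0] = 10 * N_c
        params = EnsembleParams(S=S, M=1, c=0.0, mu_A=0.0, sd_A=0.0, N_c=N_c)
        sys = InteractionSet(
            A=np.zeros((S, S, 1)), B=B, D=np.zeros((1, 1)),
            mask=np.zeros((S, S), dtype=bool), params=params,
        )
        traj = integrate(sys, horizon=200.0, N_c=N_c)
        state, rep, hist = anneal_to_fixed_point(
            sys, traj.final_state(), fp_tol=1e-7
        )
        assert rep.is_fixed_point
        assert state[0, 0] == 0.0       # the marginal species is gone
        assert (state[1:, 0] > 0.5).all()


def test_homogeneous_community_collapses_to_scalar_logistic():
    # identical interactions a = m/S and identical initial abundances:
    # every species follows one logistic ODE with effective
    # self-regulation 1 + a (S - 1); compare against a scalar oracle
    from scipy.integrate import solve_ivp

    S, m = 20, 2.0
    a = m / S
    A = np.full((S, S, 1), a)
    for i in range(S):
        A[i, i, 0] = 0.0
    params = EnsembleParams(S=S, M=1, c=1.0, mu_A=a, sd_A=0.0, N_c=1e-12)
    sys = InteractionSet(A=A, B=np.ones((S, 1)), D=np.zeros((1, 1)),
                         mask=~np.eye(S, dtype=bool), params=params)
    traj = integrate(sys, N0=np.full((S, 1), 0.2), horizon=40.0)

    k = 1.0 + a * (S - 1)
    sol = solve_ivp(lambda t, y: y * (1 - k * y), (0, 40.0), [0.2],
                    rtol=1e-9, atol=1e-12)
    scalar = sol.y[0, -1]
    assert np.allclose(traj.final_state(), scalar, atol=1e-6)
    assert np.isclose(scalar, 1.0 / k, atol=1e-6)
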