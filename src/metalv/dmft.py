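"""Dynamical mean-field theory of the random metacommunity.

For large, disordered species pools the deterministic many-species
metacommunity maps exactly onto a *stochastic representative
metapopulation*: a single species whose abundance ``N_u`` in patch ``u``
obeys

    dN_u/dt = N_u (N*_u - N_u + xi_u(t)) + sum_v D_uv (N_v - N_u),

where the characteristic abundance ``N*_u`` (a quenched multivariate
Gaussian across patches) carries the time-independent part of the
interactions and ``xi_u(t)`` is a zero-mean Gaussian noise with finite
correlation time carrying the time-dependent part.  Statistical
equivalence of the species closes the theory on itself:

    mean(N*_u)        = B - mu_tot * <N>_pool
    C_xi(tau)         = sigma**2 * C_N(tau)          (connected, within patch)
    var(N*_u)         = sigma**2 * <Nbar_u**2>_pool  (persistent part)
    cov(N*_u, N*_v)   = sigma**2 * rho * <Nbar_u Nbar_v>_pool,

with all pool averages counting extinct species as zero abundance.  The
noise is taken independent between patches (cross-patch noise
correlations are negligible in the asynchronous regime of interest; an
override is exposed).  The solver iterates simulation of the
representative process against these closure relations with damping and
common random numbers until the kernel and moments stop moving.

The static (equilibrium) cavity theory for the same disorder -- valid
when the noise vanishes -- is provided as `equilibrium_theory`; its
survival fraction yields the maximal-diversity bound ``S * phi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numba
import numpy as np
from scipy import optimize, stats

from .ensemble import DisorderScales, migration_matrix

__all__ = [
    "RepresentativeParams",
    "DMFTSolution",
    "generate_colored_noise",
    "simulate_representative",
    "self_consistent_solve",
    "equilibrium_theory",
    "predicted_nstar_distribution",
    "exponential_kernel",
]


def exponential_kernel(amplitude: float, tau: float) -> Callable[[np.ndarray], np.ndarray]:
    """C(t) = amplitude * exp(-|t|/tau); two-sided integral 2*amplitude*tau."""

    def C(lag):
        return amplitude * np.exp(-np.abs(lag) / tau)

    return C


def _kernel_values(kernel, dt: float, n: int) -> np.ndarray:
    """Evaluate a kernel (callable or (lags, values) pair) on a step grid."""
    lags = np.arange(n) * dt
    if callable(kernel):
        return np.asarray(kernel(lags), dtype=float)
    k_lags, k_vals = kernel
    return np.interp(lags, k_lags, k_vals, right=0.0)


@dataclass
class RepresentativeParams:
    """Inputs of the representative-metapopulation process.

    ``N_star`` is either a length-M vector (shared by all realizations)
    or an (n_realizations, M) array of quenched characteristic
    abundances.  ``kernel`` drives the colored noise xi_u(t); patches
    receive independent noise unless ``interpatch_noise_corr`` is set.
    """

    M: int
    N_star: np.ndarray
    d: float = 0.0
    kernel: Union[Callable, tuple, None] = None
    interpatch_noise_corr: float = 0.0

    @property
    def D(self) -> np.ndarray:
        return migration_matrix(self.M, self.d)


def generate_colored_noise(
    kernel,
    T: float,
    dt: float,
    n_paths: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Stationary Gaussian paths with autocovariance ``kernel``.

    Circulant-embedding (Davies-Harte) sampling on a uniform grid of
    ``n = round(T/dt)`` points.  A kernel that is not positive
    semidefinite on the grid is projected by clipping negative circulant
    eigenvalues, with a warning.  Returns shape ``(n_paths, n)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(T / dt))
    if n < 1:
        raise ValueError("need at least one step")
    c = _kernel_values(kernel, dt, n)
    if not np.any(c):
        return np.zeros((n_paths, n))
    if n == 1:
        return rng.standard_normal((n_paths, 1)) * np.sqrt(max(c[0], 0.0))
    # circular embedding of length 2n-2
    s = np.concatenate([c, c[-2:0:-1]])
    m = s.size
    lam = np.fft.fft(s).real
    if lam.min() < -1e-10 * max(lam.max(), 1.0):
        warnings.warn(
            f"kernel not PSD on the grid (min eigenvalue {lam.min():.3g}); "
            "clipping to the nearest PSD kernel",
            stacklevel=2,
        )
    lam = np.clip(lam, 0.0, None)
    # one complex draw yields two independent real paths (Re and Im);
    # batch the draws so the complex work array stays modest
    n_half = (n_paths + 1) // 2
    batch = max(1, int(2**24 // m))
    amp = np.sqrt(lam / m)
    x = np.empty((2 * n_half, n))
    for k0 in range(0, n_half, batch):
        k1 = min(k0 + batch, n_half)
        z = rng.standard_normal((k1 - k0, m)) + 1j * rng.standard_normal((k1 - k0, m))
        y = np.fft.fft(z * amp, axis=1)
        x[k0:k1] = y.real[:, :n]
        x[n_half + k0 : n_half + k1] = y.imag[:, :n]
    return x[:n_paths]


@dataclass
class RepresentativeRun:
    """Output of `simulate_representative`."""

    times: np.ndarray          # stored checkpoint times
    N: np.ndarray              # (n_real, M, n_stored)
    surviving: np.ndarray      # (n_real,) bool: never absorbed
    first_passage: np.ndarray  # (n_real,) absorption time, inf if censored
    dt: float
    final: Optional[np.ndarray] = None  # state at the horizon


def simulate_representative(
    rep: RepresentativeParams,
    T: float,
    dt: float,
    n_realizations: int,
    N_c: float = 0.0,
    seed: Optional[int] = None,
    *,
    N0: Optional[np.ndarray] = None,
    store_stride: int = 10,
    checkpoint_dt: Optional[float] = None,
    noise: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    max_rel_step: float = 0.2,
) -> RepresentativeRun:
    """Integrate the representative stochastic metapopulation.

    The multiplicative growth part is advanced with an exponential Euler
    step (positivity-preserving down to arbitrarily small abundances)
    and migration is added explicitly:

        N <- N * exp((N* - N + xi) dt) + dt * sum_v D_uv (N_v - N_u).

    Every ``checkpoint_dt`` the all-patch extinction rule is applied:
    realizations below ``N_c`` in every patch are absorbed at 0 and
    their first-passage time recorded.  Aborts if the deterministic part
    of a step exceeds ``max_rel_step`` relative change on average.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    M = rep.M
    n = int(round(T / dt))
    Nstar = np.asarray(rep.N_star, dtype=float)
    if Nstar.ndim == 1:
        Nstar = np.broadcast_to(Nstar, (n_realizations, M)).copy()
    if Nstar.shape != (n_realizations, M):
        raise ValueError("N_star must have shape (M,) or (n_realizations, M)")
    if checkpoint_dt is None:
        checkpoint_dt = max(dt, min(1.0, T / 10))
    check_stride = max(1, int(round(checkpoint_dt / dt)))

    if noise is None:
        if rep.kernel is not None:
            noise = generate_colored_noise(rep.kernel, T, dt, n_realizations * M, rng=rng)
            noise = noise.reshape(n_realizations, M, n)
            if rep.interpatch_noise_corr != 0.0 and M > 1:
                r = rep.interpatch_noise_corr
                shared = generate_colored_noise(rep.kernel, T, dt, n_realizations, rng=rng)
                noise = np.sqrt(1 - r) * noise + np.sqrt(r) * shared[:, None, :]
        else:
            noise = np.zeros((n_realizations, M, n))

    D = rep.D
    Drow = D.sum(axis=1)
    if N0 is None:
        N = np.maximum(Nstar, 0.1).copy()
    else:
        N = np.broadcast_to(np.asarray(N0, dtype=float), (n_realizations, M)).copy()

    alive = np.ones(n_realizations, dtype=bool)
    fp_time = np.full(n_realizations, np.inf)
    stored_idx = np.arange(0, n, store_stride)
    out = np.empty((n_realizations, M, stored_idx.size))
    s_ptr = 0

    # step-size sanity: typical relative change per step on the initial
    # state (outlier draws with strongly negative N* merely decay and do
    # not constrain the step)
    g0 = float(np.median(np.abs(Nstar - N))) if N.size else 0.0
    if g0 * dt > max_rel_step:
        raise ValueError(
            f"dt={dt} too coarse: typical relative step {g0 * dt:.2f} exceeds "
            f"{max_rel_step}"
        )

    _rep_step_loop(
        N,
        Nstar,
        np.ascontiguousarray(noise),
        np.ascontiguousarray(D),
        dt,
        float(N_c),
        check_stride,
        store_stride,
        out,
        alive,
        fp_time,
    )
    return RepresentativeRun(
        times=stored_idx * dt,
        N=out,
        surviving=alive,
        first_passage=fp_time,
        dt=dt,
        final=N.copy(),
    )


@numba.njit(cache=False)
def _rep_step_loop(
    N, Nstar, noise, D, dt, N_c, check_stride, store_stride, out, alive, fp_time
):  # pragma: no cover - exercised through simulate_representative
    n_real, M = N.shape
    n = noise.shape[2]
    s_ptr = 0
    new = np.empty(M)
    for k in range(n):
        if s_ptr < out.shape[2] and s_ptr * store_stride == k:
            for r in range(n_real):
                for u in range(M):
                    out[r, u, s_ptr] = N[r, u]
            s_ptr += 1
        for r in range(n_real):
            if not alive[r]:
                continue
            for u in range(M):
                migr = 0.0
                for v in range(M):
                    migr += D[u, v] * (N[r, v] - N[r, u])
                g = (Nstar[r, u] - N[r, u] + noise[r, u, k]) * dt
                if g > 30.0:
                    g = 30.0
                elif g < -30.0:
                    g = -30.0
                val = N[r, u] * np.exp(g) + migr * dt
                new[u] = val if val > 0.0 else 0.0
            for u in range(M):
                N[r, u] = new[u]
        if (k + 1) % check_stride == 0 and N_c > 0.0:
            for r in range(n_real):
                if alive[r]:
                    below = True
                    for u in range(M):
                        if N[r, u] >= N_c:
                            below = False
                            break
                    if below:
                        alive[r] = False
                        fp_time[r] = (k + 1) * dt
                        for u in range(M):
                            N[r, u] = 0.0


@dataclass
class DMFTSolution:
    """Converged self-consistent state of the representative theory."""

    mean_Nstar: float
    var_Nstar: float
    cov_Nstar_cross: float
    phi: float
    mean_N: float
    q: float
    lags: np.ndarray
    C_xi: np.ndarray
    C_N: np.ndarray
    converged: bool
    iterations: int
    residual_history: list
    sigma: float
    mu_tot: float
    M: int
    rho: float
    d: float
    B: float

    @property
    def std_xi(self) -> float:
        return float(np.sqrt(max(self.C_xi[0], 0.0)))

    @property
    def W(self) -> float:
        """Two-sided integral of the converged noise kernel."""
        return 2.0 * float(np.trapezoid(self.C_xi, self.lags))

    def closure_residual(self) -> float:
        denom = max(self.C_xi[0], 1e-300)
        return float(np.abs(self.C_xi - self.sigma**2 * self.C_N).max() / denom)


def self_consistent_solve(
    scales: DisorderScales,
    B: float = 1.0,
    M: int = 1,
    rho: float = 0.0,
    d: float = 0.0,
    *,
    N_c: float = 1e-8,
    T: float = 500.0,
    burn_in: float = 150.0,
    dt: float = 0.05,
    n_realizations: int = 300,
    damping: float = 0.3,
    max_iter: int = 40,
    tol: float = 5e-3,
    seed: int = 0,
    init_noise_frac: float = 0.3,
    interpatch_noise_corr: float = 0.0,
    phi_fix: Optional[float] = None,
) -> DMFTSolution:
    """Solve the DMFT closure by damped fixed-point iteration.

    Each iteration (1) draws quenched ``N*`` vectors from the current
    multivariate Gaussian, (2) simulates the representative
    metapopulation under the current noise kernel, (3) re-measures the
    pool statistics (mean abundance, connected within-patch kernel,
    persistent within/cross-patch plateaus), (4) maps them through the
    closure relations, and (5) damps the update.  Common random numbers
    (the same seed every iteration) make the iteration map deterministic
    so it can converge to solver precision; ``tol`` bounds the relative
    change of the kernel and moments between iterations.

    The noiseless (sigma -> 0) limit converges to mean_N = B/(1+mu_tot),
    phi = 1, C_xi = 0.  An equilibrium-bound system converges to a
    vanishing kernel; a fluctuating one sustains a finite kernel fed by
    its own abundance fluctuations.

    ``phi_fix`` evaluates the theory *at a given diversity*: the
    contributing pool is restricted to the surviving realizations with
    the highest effective characteristic abundance (max over patches),
    keeping a fraction ``phi_fix`` of the pool, and all pool averages
    are rescaled accordingly.  Fluctuating states form a continuum in
    diversity, and a finite-population simulation settles below the
    maximal-diversity state the unconstrained closure selects; pinning
    the survivor fraction asks the theory about the state the
    simulation actually reached.
    """
    sigma, mu_tot = scales.sigma, scales.mu_tot
    if not 0.0 < damping <= 1.0:
        raise ValueError("damping must lie in (0, 1]")

    # initial guess from the static cavity theory, with a finite seed
    # kernel so a fluctuating solution can bootstrap itself
    eq = equilibrium_theory(scales, B=B, S=None)
    m = eq["mean_N"]
    q_w = eq["q"]
    q_x = rho * q_w
    n_lag = int(round(min(T - burn_in, 100.0) / dt / 2))
    lag_grid = np.arange(n_lag + 1) * dt
    tau0 = 5.0
    C_xi = (init_noise_frac * sigma * max(m, 0.05)) ** 2 * np.exp(-lag_grid / tau0)

    n_keep = int(round((T - burn_in) / dt))
    residual_history: list[float] = []
    converged = False
    C_N_meas = C_xi / sigma**2 if sigma > 0 else C_xi * 0.0
    phi = eq["phi"]
    it = 0

    for it in range(1, max_iter + 1):
        rng = np.random.default_rng(seed)  # common random numbers
        h = B - mu_tot * m
        var_w = sigma**2 * q_w
        cov_x = sigma**2 * rho * q_x
        Nstar = _draw_equicorrelated(rng, n_realizations, M, h, var_w, cov_x)
        rep = RepresentativeParams(
            M=M,
            N_star=Nstar,
            d=d,
            kernel=(lag_grid, C_xi),
            interpatch_noise_corr=interpatch_noise_corr,
        )
        with warnings.catch_warnings():
            # measured kernels truncated at the lag horizon are routinely
            # projected to PSD inside the iteration; not noteworthy here
            warnings.filterwarnings("ignore", message=".*not PSD.*")
            run = simulate_representative(
                rep, T, dt, n_realizations, N_c=N_c, rng=rng,
                store_stride=1, checkpoint_dt=max(10 * dt, 1.0),
            )
        X = run.N[:, :, -n_keep:]  # (n_real, M, n_keep)

        if phi_fix is None:
            contrib = np.ones(n_realizations, dtype=bool)
        else:
            # keep the surviving realizations with the highest effective
            # characteristic abundance, a fraction phi_fix of the pool
            n_keep_reps = max(1, int(round(phi_fix * n_realizations)))
            order = np.argsort(-Nstar.max(axis=1))
            contrib = np.zeros(n_realizations, dtype=bool)
            chosen = [r for r in order if run.surviving[r]][:n_keep_reps]
            contrib[chosen] = True
        Xc = X[contrib]
        means = Xc.mean(axis=2)                      # (n_contrib, M)
        w = contrib.mean()                           # pool dilution factor
        m_new = float(means.mean()) * w
        q_new = float((Xc**2).mean()) * w
        q_w_new = float((means**2).mean()) * w
        if M > 1:
            prod = means[:, :, None] * means[:, None, :]
            off = prod[:, ~np.eye(M, dtype=bool)]
            q_x_new = float(off.mean()) * w
        else:
            q_x_new = q_w_new
        C_N_meas = _pool_autocov(Xc - means[:, :, None], n_lag) * w
        C_xi_new = sigma**2 * C_N_meas
        phi_measured = float(run.surviving.mean())

        kernel_scale = max(
            C_xi[0], C_xi_new[0], 1e-2 * sigma**2 * max(q_w, q_w_new, 1e-12)
        )
        res = max(
            abs(m_new - m) / max(m, m_new, 1e-12),
            float(np.abs(C_xi_new - C_xi).max()) / kernel_scale,
        )
        residual_history.append(res)

        a = damping
        m = (1 - a) * m + a * m_new
        q_w = (1 - a) * q_w + a * q_w_new
        q_x = (1 - a) * q_x + a * q_x_new
        C_xi = (1 - a) * C_xi + a * C_xi_new

        if res < tol:
            converged = True
            break

    q = q_new
    # long-term presence requires a positive characteristic abundance in
    # at least one patch; the finite-horizon survival fraction overcounts
    # slowly decaying species, so phi comes from the converged Gaussian
    if phi_fix is not None:
        phi = float(phi_fix)
    else:
        phi = _phi_positive(
            B - mu_tot * m, sigma**2 * q_w, sigma**2 * rho * q_x, M
        )
    return DMFTSolution(
        mean_Nstar=float(B - mu_tot * m),
        var_Nstar=float(sigma**2 * q_w),
        cov_Nstar_cross=float(sigma**2 * rho * q_x),
        phi=phi,
        mean_N=float(m),
        q=q,
        lags=lag_grid,
        C_xi=C_xi,
        C_N=C_N_meas,
        converged=converged,
        iterations=it,
        residual_history=residual_history,
        sigma=sigma,
        mu_tot=mu_tot,
        M=M,
        rho=rho,
        d=d,
        B=B,
    )


def _phi_positive(mean, var, cov, M, n_hermite=80):
    """P(max_u N*_u > 0) for the equicorrelated Gaussian patch vector."""
    if var <= 1e-300:
        return 1.0 if mean > 0 else 0.0
    cov = min(max(cov, 0.0), var)
    a = np.sqrt(cov)
    b = np.sqrt(max(var - cov, 1e-300))
    if M == 1 or cov == 0.0:
        return float(1.0 - stats.norm.cdf(-mean / np.sqrt(var)) ** M)
    zs, wts = np.polynomial.hermite_e.hermegauss(n_hermite)
    wts = wts / np.sqrt(2 * np.pi)
    cdf0 = (stats.norm.cdf(-(mean + a * zs) / b) ** M * wts).sum()
    return float(1.0 - cdf0)


def _draw_equicorrelated(rng, n, M, mean, var, cov):
    """n draws of an M-vector with equal variances and equal covariances."""
    if M == 1:
        return mean + np.sqrt(max(var, 0.0)) * rng.standard_normal((n, 1))
    cov = min(cov, var)
    a = np.sqrt(max(cov, 0.0))
    b = np.sqrt(max(var - max(cov, 0.0), 0.0))
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, M))
    return mean + a * shared + b * own


def _pool_autocov(Y: np.ndarray, n_lag: int) -> np.ndarray:
    """Mean autocovariance over (realization, patch) series in Y.

    Y has shape (n_real, M, n_t), already mean-centred per series;
    extinct realizations are flat zero and dilute the pool average, as
    the closure requires.
    """
    n_real, M, n_t = Y.shape
    Z = Y.reshape(-1, n_t)
    nfft = int(2 ** np.ceil(np.log2(2 * n_t)))
    F = np.fft.rfft(Z, n=nfft, axis=1)
    acov = np.fft.irfft((F * F.conj()).real, n=nfft, axis=1)[:, : n_lag + 1]
    counts = n_t - np.arange(n_lag + 1)
    return acov.mean(axis=0) / counts


def stationary_abundance_samples(
    solution: DMFTSolution,
    n_realizations: int = 400,
    T: float = 800.0,
    dt: float = 0.05,
    burn_in: float = 300.0,
    N_c: float = 1e-8,
    seed: int = 0,
    store_stride: int = 20,
) -> np.ndarray:
    """Pooled stationary abundances of surviving representatives.

    Draws quenched ``N*`` vectors from the solution's multivariate
    Gaussian, runs the representative metapopulation under the converged
    kernel, and returns the abundances of surviving realizations over
    the post-burn-in window (flattened over realizations, patches and
    times) -- the theory's prediction for the stationary abundance
    histogram of surviving species-patch pairs.
    """
    rng = np.random.default_rng(seed)
    Nstar = _draw_equicorrelated(
        rng, n_realizations, solution.M, solution.mean_Nstar,
        solution.var_Nstar, solution.cov_Nstar_cross,
    )
    rep = RepresentativeParams(
        M=solution.M, N_star=Nstar, d=solution.d,
        kernel=(solution.lags, solution.C_xi),
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*not PSD.*")
        run = simulate_representative(
            rep, T, dt, n_realizations, N_c=N_c, rng=rng,
            store_stride=store_stride, checkpoint_dt=1.0,
        )
    X = run.N[run.surviving][:, :, run.times > burn_in]
    samples = X.ravel()
    return samples[samples > 0]


def equilibrium_theory(
    scales: DisorderScales,
    B: float = 1.0,
    S: Optional[int] = None,
) -> dict:
    """Static cavity solution for the single-patch equilibrium ensemble.

    With unstructured interactions (no reciprocal correlation) the
    response correction vanishes and survivors obey
    ``N = max(0, B - mu_tot m + sigma sqrt(q) z)`` with z standard
    normal.  Self-consistency closes on the truncated-Gaussian moments

        w1(Delta) = Delta Phi(Delta) + phi(Delta),
        w2(Delta) = (Delta**2 + 1) Phi(Delta) + Delta phi(Delta) = 1/sigma**2,

    giving the survival fraction ``phi = Phi(Delta)``, the mean
    abundance and second moment, and -- when ``S`` is supplied -- the
    maximal-diversity bound ``S * phi``.
    """
    sigma, mu = scales.sigma, scales.mu_tot
    if sigma < 1e-12:
        out = {
            "phi": 1.0,
            "mean_N": B / (1.0 + mu),
            "q": (B / (1.0 + mu)) ** 2,
            "Delta": np.inf,
        }
        if S is not None:
            out["diversity_bound"] = float(S)
        return out

    target = 1.0 / sigma**2

    def w2(delta):
        return (delta**2 + 1.0) * stats.norm.cdf(delta) + delta * stats.norm.pdf(delta)

    lo, hi = -40.0, max(40.0, 2.0 / sigma)
    delta = optimize.brentq(lambda x: w2(x) - target, lo, hi, xtol=1e-12)
    w1 = delta * stats.norm.cdf(delta) + stats.norm.pdf(delta)
    phi = float(stats.norm.cdf(delta))
    m = B * w1 / (delta + mu * w1)
    sq = (B - mu * m) / (delta * sigma) if abs(delta) > 1e-12 else np.nan
    q = float(sq**2) if np.isfinite(sq) else float("nan")
    out = {"phi": phi, "mean_N": float(m), "q": q, "Delta": float(delta)}
    if S is not None:
        out["diversity_bound"] = float(S * phi)
    return out


def predicted_nstar_distribution(
    solution: DMFTSolution,
    M: Optional[int] = None,
    grid: Optional[np.ndarray] = None,
    n_hermite: int = 80,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Density of the effective characteristic abundance of survivors.

    ``N*_eff = max_u N*_u`` over the equicorrelated Gaussian patch
    vector implied by the solution; survival requires ``N*_eff > 0``
    (one source patch suffices to sustain the species).  Returns
    ``(grid, density, phi_pred)`` where the density is truncated to the
    positive axis and integrates to ``phi_pred = P(N*_eff > 0)``.
    """
    if not solution.converged:
        raise ValueError("refusing to evaluate an unconverged solution")
    if M is None:
        M = solution.M
    h = solution.mean_Nstar
    var = solution.var_Nstar
    cov = min(solution.cov_Nstar_cross, var)
    a2 = max(cov, 0.0)
    b2 = max(var - a2, 0.0)
    a, b = np.sqrt(a2), np.sqrt(max(b2, 1e-300))
    if grid is None:
        s = np.sqrt(max(var, 1e-300))
        grid = np.linspace(0.0, h + 5 * s, 400)
    zs, wts = np.polynomial.hermite_e.hermegauss(n_hermite)
    wts = wts / np.sqrt(2 * np.pi)

    # conditional on the shared factor z0, the patch values are iid
    # Normal(h + a z0, b^2); the max has an analytic density
    x = grid[:, None]
    mu_c = h + a * zs[None, :]
    zz = (x - mu_c) / b
    pdf = (
        M * stats.norm.pdf(zz) / b * stats.norm.cdf(zz) ** (M - 1)
        if M > 1
        else stats.norm.pdf(zz) / b
    )
    density = (pdf * wts[None, :]).sum(axis=1)
    cdf0 = (stats.norm.cdf((0.0 - mu_c) / b) ** M * wts).sum()
    phi_pred = float(1.0 - cdf0)
    return grid, density, phi_pred
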