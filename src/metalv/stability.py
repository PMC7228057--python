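"""Linear stability of metacommunity fixed points and the diversity sweep.

The community Jacobian at a state ``N`` (live species only) is

    J[(i,u),(j,v)] = delta_uv [ delta_ij (B_iu - 2 N_iu - (A_u N_u)_i)
                                - N_iu A_ij_u ]
                     + delta_ij ( D_uv - delta_uv sum_w D_uw ),

and ``lambda_stab`` is the maximal real part of its spectrum.  The
diversity sweep probes the same metacommunity at decreasing diversity by
removing the most extinction-prone species in batches, re-equilibrating,
and recording the fluctuation strength std(xi) together with the
stability of the (putative) fixed point at that diversity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import root

from .dynamics import TrajectorySet, detect_fixed_point, integrate, rhs
from .ensemble import InteractionSet, disorder_scales
from . import observables as obs

__all__ = [
    "StabilityReport",
    "jacobian_at",
    "lambda_stab",
    "find_fixed_point",
    "diversity_sweep",
]

#: modes with |Re lambda| below this are treated as exact zeros of
#: extinct coordinates and excluded
ZERO_MODE_TOL = 1e-10


@dataclass
class StabilityReport:
    lambda_stab: float
    spectrum: np.ndarray
    diversity: int
    at_fixed_point: bool = True
    residual: float = 0.0


def jacobian_at(
    state: np.ndarray,
    system: InteractionSet,
    warn_if_not_fp: bool = True,
    fp_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Jacobian over live (species, patch) coordinates.

    Returns ``(J, live_species_index)`` where ``J`` is the
    ``(s*M, s*M)`` matrix in species-major ordering of the live species.
    A state failing the fixed-point residual test still gets a Jacobian,
    with a warning (its spectrum describes a putative equilibrium).
    """
    N = np.asarray(state, dtype=float)
    if warn_if_not_fp:
        rep = detect_fixed_point(N, system, tol=fp_tol)
        if not rep.is_fixed_point:
            warnings.warn(
                f"state is not a fixed point (residual {rep.residual:.2e}); "
                "spectrum describes a putative equilibrium",
                stacklevel=2,
            )
    live = (N > 0).any(axis=1)
    idx = np.flatnonzero(live)
    s, M = idx.size, system.M
    A = system.A[np.ix_(idx, idx)]  # (s, s, M)
    B = system.B[idx]
    D = system.D
    Ns = N[idx]
    J = np.zeros((s * M, s * M))
    Drow = D.sum(axis=1)
    for u in range(M):
        Au = A[:, :, u]
        inter = Au @ Ns[:, u]
        diag = B[:, u] - 2.0 * Ns[:, u] - inter - Drow[u]
        block = -Ns[:, u, None] * Au
        block[np.diag_indices(s)] += diag
        J[u::M, u::M] = block
        for v in range(M):
            if v != u:
                J[u::M, v::M] += np.eye(s) * D[u, v]
    return J, idx


def lambda_stab(
    state: np.ndarray,
    system: InteractionSet,
    warn_if_not_fp: bool = True,
    fp_tol: float = 1e-6,
) -> StabilityReport:
    """Maximal real part of the community spectrum at ``state``.

    Exact-zero modes (|Re| < ZERO_MODE_TOL) of extinct coordinates never
    enter because the Jacobian is built on live coordinates only; any
    residual numerical zeros are excluded from the maximum as well.
    """
    rep = detect_fixed_point(state, system, tol=fp_tol)
    J, idx = jacobian_at(state, system, warn_if_not_fp=warn_if_not_fp, fp_tol=fp_tol)
    eig = np.linalg.eigvals(J) if J.size else np.array([])
    re = eig.real
    nonzero = np.abs(re) >= ZERO_MODE_TOL
    lam = float(re[nonzero].max()) if nonzero.any() else 0.0
    return StabilityReport(
        lambda_stab=lam,
        spectrum=eig,
        diversity=int(idx.size),
        at_fixed_point=rep.is_fixed_point,
        residual=rep.residual,
    )


def find_fixed_point(
    system: InteractionSet,
    guess: np.ndarray,
    tol: float = 1e-12,
    neg_tol: float = 1e-8,
    max_drops: int = 10,
) -> tuple[np.ndarray, bool]:
    """Solve for a (putative) fixed point of the live community.

    Newton/hybrid root-finding seeded at ``guess``; species with
    all-zero rows in the guess are held extinct.  A live species must be
    positive in every patch at an interior fixed point (migration feeds
    even its sink patches), so if the root drives a species negative the
    species is dropped and the solve repeats on the remainder.  Returns
    ``(state, converged)``; the state may be dynamically unstable --
    that is what `lambda_stab` diagnoses.
    """
    N0 = np.asarray(guess, dtype=float)
    live = (N0 > 0).any(axis=1)
    for _ in range(max_drops):
        idx = np.flatnonzero(live)
        if idx.size == 0:
            return np.zeros_like(N0), True
        sub = _subsystem(system, idx)
        x0 = np.maximum(N0[idx], 1e-8).ravel()

        def F(x):
            return _sub_rhs(x.reshape(idx.size, system.M), sub).ravel()

        def Jac(x):
            return _sub_jacobian(x.reshape(idx.size, system.M), sub)

        sol = root(F, x0, jac=Jac, method="hybr", tol=tol)
        X = sol.x.reshape(idx.size, system.M)
        bad = (X.min(axis=1) < -neg_tol)
        if sol.success and not bad.any():
            N = np.zeros_like(N0)
            N[idx] = np.clip(X, 0.0, None)
            # denominator floored well above the tiny sink abundances so
            # the relative test reflects the dynamically relevant scale
            resid = float(
                np.abs(rhs(N, system)[idx] / np.maximum(N[idx], 1e-6)).max()
            )
            return N, bool(resid < 1e-6)
        if sol.success and bad.any():
            live[idx[bad]] = False  # infeasible species: drop and re-solve
            continue
        return np.zeros_like(N0), False
    return np.zeros_like(N0), False


def _subsystem(system: InteractionSet, idx: np.ndarray):
    A = np.ascontiguousarray(np.moveaxis(system.A[np.ix_(idx, idx)], 2, 0))
    return A, system.B[idx], system.D


def _sub_rhs(N, sub):
    At, B, D = sub
    inter = np.matmul(At, N.T[:, :, None])[:, :, 0].T
    return N * (B - N - inter) + N @ D.T - N * D.sum(axis=1)


def _sub_jacobian(N, sub):
    At, B, D = sub
    s, M = N.shape
    J = np.zeros((s * M, s * M))
    Drow = D.sum(axis=1)
    for u in range(M):
        Au = At[u]
        inter = Au @ N[:, u]
        diag = B[:, u] - 2.0 * N[:, u] - inter - Drow[u]
        block = -N[:, u, None] * Au
        block[np.diag_indices(s)] += diag
        J[u::M, u::M] = block
        for v in range(M):
            if v != u:
                J[u::M, v::M] += np.eye(s) * D[u, v]
    return J


def diversity_sweep(
    system: InteractionSet,
    state: np.ndarray,
    *,
    n_steps: int = 12,
    batch: int = 5,
    window: float = 300.0,
    n_windows: int = 3,
    checkpoint_dt: float = 1.0,
    rtol: float = 1e-6,
) -> pd.DataFrame:
    """Probe the same metacommunity at decreasing diversity.

    From a stationary ``state``, iteratively: (1) measure std(xi) over
    ``n_windows`` replicate windows of length ``window``; (2) solve for
    the putative fixed point seeded at the time-averaged abundances and
    record its ``lambda_stab``; (3) remove the ``batch`` species most
    prone to extinction -- ranked by lowest time-averaged max-over-patch
    abundance, a monotone proxy for the effective characteristic
    abundance that controls extinction risk.

    Returns a DataFrame with columns (S_star, std_xi, std_xi_over_sigma,
    lambda_stab, fp_converged).
    """
    sigma = disorder_scales(system.params).sigma if system.params else 1.0
    current = np.asarray(state, dtype=float).copy()
    rows = []
    for step in range(n_steps):
        S_star = int((current > 0).any(axis=1).sum())
        if S_star <= batch:
            break
        # settle after the previous removal before measuring
        settle = integrate(
            system,
            current,
            horizon=window,
            checkpoint_dt=checkpoint_dt,
            store_every=max(1, int(window / checkpoint_dt)),
            rtol=rtol,
        )
        current = settle.final_state()
        stds = []
        last_traj = None
        for w in range(n_windows):
            traj = integrate(
                system,
                current,
                horizon=window,
                checkpoint_dt=checkpoint_dt,
                store_every=1,
                rtol=rtol,
            )
            current = traj.final_state()
            stds.append(
                obs.noise_strength(traj, sigma, (traj.times[0], traj.times[-1]))
            )
            last_traj = traj
        std_xi = float(np.mean(stds))

        # time-averaged abundances over the last window seed the putative
        # fixed point and the extinction-risk ranking
        mean_N = last_traj.N.mean(axis=0)
        mean_N[~last_traj.final_alive()] = 0.0
        fp_state, ok = find_fixed_point(system, np.maximum(mean_N, 0.0))
        if ok:
            srep = lambda_stab(fp_state, system, warn_if_not_fp=False)
            lam = srep.lambda_stab
        else:
            lam = float("nan")
        rows.append(
            {
                "S_star": S_star,
                "std_xi": std_xi,
                "std_xi_over_sigma": std_xi / sigma,
                "lambda_stab": lam,
                "fp_converged": ok,
            }
        )

        # remove the most extinction-prone batch: lowest time-averaged
        # max-over-patches abundance among live species
        live = np.flatnonzero((current > 0).any(axis=1))
        score = mean_N[live].max(axis=1)
        doomed = live[np.argsort(score)[:batch]]
        current[doomed] = 0.0
    return pd.DataFrame(rows)
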