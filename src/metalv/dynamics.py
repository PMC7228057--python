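"""Deterministic metacommunity Lotka-Volterra dynamics with extinctions.

The abundance ``N[i, u]`` of species ``i`` in patch ``u`` obeys

    dN_iu/dt = N_iu (B_iu - N_iu - sum_j A_ij_u N_ju)
               + sum_v D_uv (N_iv - N_iu),

integrated with an adaptive-error Runge-Kutta scheme between checkpoints.
At every checkpoint the extinction rule is applied: a species whose
abundance is below the cutoff ``N_c`` in *all* patches is removed from the
metacommunity and cannot return.  The cutoff represents the minimum
sustainable number of individuals, so ``1/N_c`` sets the absolute
population-size scale.

Extinct species are excised from the working system (the interaction
tensor is re-compacted), which makes long runs progressively cheaper as
the transient sheds species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ensemble import EnsembleParams, InteractionSet

__all__ = [
    "TrajectorySet",
    "FixedPointReport",
    "rhs",
    "integrate",
    "apply_extinction_rule",
    "detect_fixed_point",
    "anneal_to_fixed_point",
    "default_initial_state",
]


@dataclass
class TrajectorySet:
    """Checkpointed abundance paths plus the extinction event log.

    ``N`` has shape ``(n_times, S, M)`` (extinct species exactly zero
    from their removal checkpoint onward), ``alive`` shape
    ``(n_times, S)``.
    """

    times: np.ndarray
    N: np.ndarray
    alive: np.ndarray
    extinction_log: list  # [(species, time), ...]
    params: Optional[EnsembleParams] = None

    @property
    def S(self) -> int:
        return self.N.shape[1]

    @property
    def M(self) -> int:
        return self.N.shape[2]

    def final_state(self) -> np.ndarray:
        return self.N[-1]

    def final_alive(self) -> np.ndarray:
        return self.alive[-1]

    def window(self, t0: float, t1: float) -> "TrajectorySet":
        """Restrict to checkpoints with t0 <= t <= t1."""
        sel = (self.times >= t0) & (self.times <= t1)
        return TrajectorySet(
            times=self.times[sel],
            N=self.N[sel],
            alive=self.alive[sel],
            extinction_log=[e for e in self.extinction_log if t0 <= e[1] <= t1],
            params=self.params,
        )

    def to_hdf5(self, path: Union[str, Path]) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("N", data=self.N)
            f.create_dataset("alive", data=self.alive)
            log = np.array(
                [(int(i), float(t)) for i, t in self.extinction_log],
                dtype=[("species", "i8"), ("time", "f8")],
            )
            f.create_dataset("extinction_log", data=log)
            if self.params is not None:
                f.attrs["params"] = json.dumps(self.params.to_dict())

    @classmethod
    def from_hdf5(cls, path: Union[str, Path]) -> "TrajectorySet":
        with h5py.File(path, "r") as f:
            params = None
            if "params" in f.attrs:
                params = EnsembleParams.from_dict(json.loads(f.attrs["params"]))
            log = [(int(r["species"]), float(r["time"])) for r in f["extinction_log"][...]]
            return cls(
                times=f["times"][...],
                N=f["N"][...],
                alive=f["alive"][...].astype(bool),
                extinction_log=log,
                params=params,
            )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export (time, species, patch, N)."""
        n_t, S, M = self.N.shape
        t = np.repeat(self.times, S * M)
        i = np.tile(np.repeat(np.arange(S), M), n_t)
        u = np.tile(np.arange(M), n_t * S)
        return pd.DataFrame({"time": t, "species": i, "patch": u, "N": self.N.ravel()})


@dataclass
class FixedPointReport:
    is_fixed_point: bool
    residual: float
    state: np.ndarray
    time_reached: Optional[float] = None
    tol: float = 1e-8


def rhs(
    state: np.ndarray,
    system: InteractionSet,
    alive: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Exact right-hand side of the metacommunity dynamics.

    ``state`` has shape (S, M).  Rows of species marked dead (or of
    all-zero abundance rows when ``alive`` is omitted) are identically 0.
    """
    N = np.asarray(state, dtype=float)
    if N.shape != (system.S, system.M):
        raise ValueError(f"state shape {N.shape} != {(system.S, system.M)}")
    if np.isnan(N).any():
        raise ValueError("NaN in state")
    At = system.patch_stack()
    out = _rhs_raw(N, At, system.B, system.D)
    if alive is not None:
        out[~alive] = 0.0
    return out


def _rhs_raw(N: np.ndarray, At: np.ndarray, B: np.ndarray, D: np.ndarray) -> np.ndarray:
    # At: (M, s, s); N, B: (s, M); D: (M, M)
    inter = np.matmul(At, N.T[:, :, None])[:, :, 0].T  # (s, M)
    growth = N * (B - N - inter)
    migr = N @ D.T - N * D.sum(axis=1)
    return growth + migr


def apply_extinction_rule(state: np.ndarray, N_c: float) -> tuple[np.ndarray, list[int]]:
    """Zero out species below the cutoff in every patch (strict ``<``).

    Returns the updated state and the list of removed species indices.
    Species already at zero everywhere are left untouched (not re-logged).
    """
    N = np.array(state, dtype=float)
    below = (N < N_c).all(axis=1)
    already_zero = (N == 0.0).all(axis=1)
    removed = np.flatnonzero(below & ~already_zero)
    N[below] = 0.0
    return N, removed.tolist()


def default_initial_state(S: int, M: int, seed: int = 0) -> np.ndarray:
    """I.i.d. uniform [0.1, 1] abundances per species-patch."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.1, 1.0, size=(S, M))


def integrate(
    system: InteractionSet,
    N0: Optional[np.ndarray] = None,
    horizon: float = 1000.0,
    checkpoint_dt: float = 1.0,
    *,
    N_c: Optional[float] = None,
    rtol: float = 1e-6,
    atol: float = 1e-12,
    store_every: int = 1,
    t0: float = 0.0,
    seed: int = 0,
    clamp_tol: float = 1e-9,
) -> TrajectorySet:
    """Integrate the metacommunity ODEs with checkpointed extinctions.

    The interval ``[t0, t0 + horizon]`` is covered in steps of
    ``checkpoint_dt``; after each step abundances in ``(-clamp_tol, 0)``
    are clamped to 0 and the all-patch extinction rule is applied.
    Species extinct in ``N0`` (all-zero rows) stay extinct.  Only every
    ``store_every``-th checkpoint is stored (the final one always is).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    S, M = system.S, system.M
    if N0 is None:
        N0 = default_initial_state(S, M, seed=seed)
    N0 = np.asarray(N0, dtype=float)
    if (N0 < 0).any():
        raise ValueError("initial abundances must be non-negative")
    if N_c is None:
        N_c = system.params.N_c if system.params is not None else 1e-8

    alive = (N0 > 0).any(axis=1)
    idx = np.flatnonzero(alive)
    At_full = system.patch_stack()
    At, B, D = _compact(At_full, system.B, system.D, idx)
    Drow = D.sum(axis=1)
    y = N0[idx].copy()

    n_check = int(round(horizon / checkpoint_dt))
    times = [t0]
    stored_N = [N0.copy()]
    stored_alive = [alive.copy()]
    extinction_log: list[tuple[int, float]] = []
    first_step = min(0.1, checkpoint_dt)

    def fun(t, yflat):
        N = yflat.reshape(y.shape)
        return _rhs_raw(N, At, B, D).ravel()

    t = t0
    for k in range(1, n_check + 1):
        if idx.size:
            sol = solve_ivp(
                fun,
                (0.0, checkpoint_dt),
                y.ravel(),
                method="RK45",
                rtol=rtol,
                atol=atol,
                first_step=first_step,
            )
            if not sol.success:
                raise RuntimeError(
                    f"integrator failure at t={t:.3f}: {sol.message}; "
                    f"state dump min={y.min():.3g} max={y.max():.3g}"
                )
            if len(sol.t) > 2:
                first_step = min(float(sol.t[-1] - sol.t[-2]), checkpoint_dt)
            y = sol.y[:, -1].reshape(y.shape)
            if (y < -clamp_tol).any():
                raise RuntimeError(
                    f"negative abundance {y.min():.3g} beyond clamp tolerance at t={t:.3f}"
                )
            np.clip(y, 0.0, None, out=y)
        t = t0 + k * checkpoint_dt

        y, removed_local = apply_extinction_rule(y, N_c)
        if removed_local:
            removed_global = idx[removed_local]
            for g in removed_global:
                extinction_log.append((int(g), t))
            alive = alive.copy()
            alive[removed_global] = False
            keep = np.ones(idx.size, dtype=bool)
            keep[removed_local] = False
            idx = idx[keep]
            y = y[keep]
            At, B, D = _compact(At_full, system.B, system.D, idx)

        if k % store_every == 0 or k == n_check:
            full = np.zeros((S, M))
            full[idx] = y
            times.append(t)
            stored_N.append(full)
            stored_alive.append(alive.copy())

    return TrajectorySet(
        times=np.array(times),
        N=np.array(stored_N),
        alive=np.array(stored_alive),
        extinction_log=extinction_log,
        params=system.params,
    )


def _compact(At_full, B_full, D, idx):
    At = np.ascontiguousarray(At_full[:, idx[:, None], idx[None, :]])
    B = B_full[idx]
    return At, B, D


def detect_fixed_point(
    state_or_traj: Union[np.ndarray, TrajectorySet],
    system: InteractionSet,
    tol: float = 1e-8,
    N_c: Optional[float] = None,
) -> FixedPointReport:
    """Residual test: max over live species-patches of |dN/dt| / max(N, N_c).

    Given a trajectory, the final state is tested and ``time_reached`` is
    the first checkpoint at which the criterion holds from then on being
    irrelevant -- only that checkpoint's own residual is evaluated,
    scanning backwards until it first fails.
    """
    if N_c is None:
        N_c = system.params.N_c if system.params is not None else 1e-8

    if isinstance(state_or_traj, TrajectorySet):
        traj = state_or_traj
        state = traj.final_state()
        report = _fp_report(state, system, tol, N_c)
        if report.is_fixed_point:
            t_reached = traj.times[-1]
            for k in range(len(traj.times) - 2, -1, -1):
                if _fp_report(traj.N[k], system, tol, N_c).is_fixed_point:
                    t_reached = traj.times[k]
                else:
                    break
            report.time_reached = float(t_reached)
        return report
    return _fp_report(np.asarray(state_or_traj, dtype=float), system, tol, N_c)


def _fp_report(state, system, tol, N_c) -> FixedPointReport:
    rates = rhs(state, system)
    denom = np.maximum(state, N_c)
    live = state > 0
    resid = float(np.abs(rates[live] / denom[live]).max()) if live.any() else 0.0
    return FixedPointReport(
        is_fixed_point=resid < tol, residual=resid, state=state.copy(), tol=tol
    )


def anneal_to_fixed_point(
    system: InteractionSet,
    state: np.ndarray,
    *,
    start_cutoff: Optional[float] = None,
    factor: float = 10 ** 0.25,
    stage_window: float = 2000.0,
    chunk: float = 200.0,
    max_cutoff: float = 1.0,
    fp_tol: float = 1e-6,
    checkpoint_dt: float = 1.0,
    rtol: float = 1e-6,
    atol: float = 1e-12,
) -> tuple[np.ndarray, FixedPointReport, dict]:
    """Force an equilibrium by geometrically raising the extinction cutoff.

    Starting from a late-time ``state``, the working cutoff is multiplied
    by ``factor`` per stage.  At each stage the system is re-integrated
    in chunks of ``chunk`` time units: while extinctions keep occurring
    the stage continues (the raised cutoff is still weeding species out,
    up to ``stage_window`` time units); once a chunk passes with no
    extinction the stage ends -- with success if the fixed-point residual
    is below ``fp_tol``, otherwise the cutoff is raised again.  Reports
    failure when the cutoff exceeds ``max_cutoff`` without stabilising.
    """
    if start_cutoff is None:
        start_cutoff = system.params.N_c if system.params is not None else 1e-8
    cutoff = float(start_cutoff)
    current = np.asarray(state, dtype=float).copy()
    history = {"cutoffs": [], "diversity": [], "residuals": []}

    while cutoff <= max_cutoff:
        current, _ = apply_extinction_rule(current, cutoff)
        elapsed = 0.0
        report = detect_fixed_point(current, system, tol=fp_tol, N_c=cutoff)
        while not report.is_fixed_point and elapsed < stage_window:
            prev_resid = report.residual
            traj = integrate(
                system,
                current,
                horizon=chunk,
                checkpoint_dt=checkpoint_dt,
                N_c=cutoff,
                rtol=rtol,
                atol=atol,
                store_every=max(1, int(chunk / checkpoint_dt)),
            )
            current = traj.final_state()
            elapsed += chunk
            report = detect_fixed_point(current, system, tol=fp_tol, N_c=cutoff)
            decaying = report.residual < 0.7 * prev_resid
            if not traj.extinction_log and not report.is_fixed_point and not decaying:
                break  # neither weeding out species nor relaxing; raise cutoff
        history["cutoffs"].append(cutoff)
        history["diversity"].append(int((current > 0).any(axis=1).sum()))
        history["residuals"].append(report.residual)
        if report.is_fixed_point:
            return current, report, history
        cutoff *= factor

    report = detect_fixed_point(current, system, tol=fp_tol, N_c=cutoff)
    return current, report, history
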