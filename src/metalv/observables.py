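"""Summary statistics of metacommunity trajectories.

Diversity series, stationary autocorrelation kernels and the integrated
noise power W, the ecological-noise strength std(xi), per-pair migration
(source/sink) statistics, and inter-patch synchrony.

All two-time statistics are computed over a stationary window in which
one-time observables have stopped drifting; the averaging population is
the set of species that survive through the window, over all patches,
with connected correlations (each species-patch pair's own time mean
removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dynamics import TrajectorySet
from .ensemble import InteractionSet

__all__ = [
    "CorrelationKernel",
    "SourceSinkTable",
    "diversity_series",
    "stationary_window",
    "stationary_kernel",
    "noise_strength",
    "diffusion_contribution",
    "source_sink_stats",
    "interpatch_synchrony",
]


@dataclass
class CorrelationKernel:
    """Stationary lag kernels of abundance and ecological noise.

    ``C_N`` is the connected, species/patch-averaged autocorrelation of
    abundance; ``C_N_raw`` adds back the persistent (squared-time-mean)
    part; ``C_xi = sigma**2 * C_N`` is the noise kernel; ``W`` its
    full-line (two-sided) integral; ``tau_c`` the 1/e decay lag.
    """

    lags: np.ndarray
    C_N: np.ndarray
    C_N_raw: np.ndarray
    C_xi: np.ndarray
    W: float
    tau_c: float
    sigma: float
    n_pairs: int = 0
    window: tuple = (0.0, 0.0)
    reliable: bool = True
    # convention marker: W integrates C_xi over the whole real line
    w_convention: str = "two-sided"

    def plateau(self, frac: float = 0.2) -> float:
        """Mean of C_N over the last ``frac`` of lags (persistence level)."""
        k = max(1, int(len(self.lags) * frac))
        return float(self.C_N[-k:].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag": self.lags, "C_N": self.C_N, "C_N_raw": self.C_N_raw,
             "C_xi": self.C_xi}
        )


def diversity_series(traj: TrajectorySet) -> pd.Series:
    """S*(t): number of not-yet-extinct species at each checkpoint."""
    return pd.Series(traj.alive.sum(axis=1), index=traj.times, name="S_star")


def stationary_window(
    traj: TrajectorySet,
    frac: float = 0.5,
    drift_tol: float = 0.05,
    strict: bool = False,
) -> tuple[float, float]:
    """Locate a stationary late-time window (the last ``frac`` of the run).

    Stationarity is a split-half test on the window itself: the mean
    abundance of through-window survivors and the diversity must both
    drift by less than ``drift_tol`` (relative) between the two halves.
    A failing window raises if ``strict`` else warns.
    """
    t0 = traj.times[0] + (1.0 - frac) * (traj.times[-1] - traj.times[0])
    t1 = float(traj.times[-1])
    w = traj.window(t0, t1)
    half = len(w.times) // 2
    surv = w.alive[-1]
    m1 = w.N[:half][:, surv].mean()
    m2 = w.N[half:][:, surv].mean()
    drift = abs(m2 - m1) / max(m1, m2, 1e-300)
    s1, s2 = w.alive[:half].sum(1).mean(), w.alive[half:].sum(1).mean()
    s_drift = abs(s2 - s1) / max(s1, s2, 1.0)
    if drift > drift_tol or s_drift > drift_tol:
        msg = (
            f"window [{t0:.0f}, {t1:.0f}] fails the stationarity test: "
            f"mean-abundance drift {drift:.2%}, diversity drift {s_drift:.2%}"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return float(t0), t1


def _survivor_block(traj: TrajectorySet, window: Optional[tuple] = None):
    """(n_t, n_surv, M) abundance block of through-window survivors."""
    if window is not None:
        traj = traj.window(*window)
    surv = traj.alive[-1] & traj.alive[0]
    return traj.times, traj.N[:, surv, :], surv


def _mean_autocorr(X: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Connected and raw autocorrelation averaged over columns of X.

    X has shape (n_t, n_series); FFT-based, unbiased per-lag
    normalisation.  Returns (connected, raw) arrays of length max_lag+1.
    """
    n_t, n_series = X.shape
    means = X.mean(axis=0)
    Y = X - means
    nfft = int(2 ** np.ceil(np.log2(2 * n_t)))
    F = np.fft.rfft(Y, n=nfft, axis=0)
    acov = np.fft.irfft((F * F.conj()).real, n=nfft, axis=0)[: max_lag + 1]
    counts = (n_t - np.arange(max_lag + 1))[:, None]
    acov = acov / counts
    conn = acov.mean(axis=1)
    raw = (acov + (means**2)[None, :]).mean(axis=1)
    return conn, raw


def stationary_kernel(
    traj: TrajectorySet,
    sigma: float,
    window: Optional[tuple] = None,
    max_lag_frac: float = 0.25,
    min_window_tau: float = 50.0,
) -> CorrelationKernel:
    """Estimate C_N, C_xi, W and tau_c over a stationary window.

    The kernel is truncated for the W integral at the first lag beyond
    which |C_xi| stays below a noise floor (2x the standard error of the
    large-lag estimates); W is the symmetric two-sided integral.
    """
    if window is None:
        window = stationary_window(traj)
    times, block, _ = _survivor_block(traj, window)
    n_t = len(times)
    if n_t < 8:
        raise ValueError("stationary window holds too few checkpoints")
    dt = float(np.median(np.diff(times)))
    max_lag = max(2, int(n_t * max_lag_frac))
    X = block.reshape(n_t, -1)
    conn, raw = _mean_autocorr(X, max_lag)
    lags = np.arange(max_lag + 1) * dt
    C_xi = sigma**2 * conn

    # noise floor from the outer half of lags
    tail = C_xi[max_lag // 2 :]
    floor = 2.0 * float(tail.std())  # per-lag scatter of the outer half
    if C_xi[0] > 0:
        below = np.abs(C_xi) < max(floor, 1e-12 * C_xi[0])
        k_max = int(np.argmax(below)) if below.any() else max_lag
        k_max = max(k_max, 1)
    else:
        k_max = max_lag
    W = 2.0 * float(np.trapezoid(C_xi[: k_max + 1], lags[: k_max + 1])) - 0.0

    tau_c = _decay_lag(lags, C_xi)
    reliable = True
    span = window[1] - window[0]
    if tau_c > 0 and span < min_window_tau * tau_c:
        warnings.warn(
            f"window of {span:.0f} time units is shorter than "
            f"{min_window_tau:.0f} correlation times (tau_c={tau_c:.2f}); "
            "kernel estimate flagged unreliable",
            stacklevel=2,
        )
        reliable = False
    return CorrelationKernel(
        lags=lags,
        C_N=conn,
        C_N_raw=raw,
        C_xi=C_xi,
        W=W,
        tau_c=tau_c,
        sigma=sigma,
        n_pairs=X.shape[1],
        window=tuple(window),
        reliable=reliable,
    )


def _decay_lag(lags: np.ndarray, C: np.ndarray) -> float:
    """First lag at which C drops to C(0)/e (linear interpolation)."""
    if C[0] <= 0:
        return 0.0
    target = C[0] / np.e
    below = np.flatnonzero(C <= target)
    if below.size == 0:
        return float(lags[-1])
    k = below[0]
    if k == 0:
        return 0.0
    f = (C[k - 1] - target) / (C[k - 1] - C[k])
    return float(lags[k - 1] + f * (lags[k] - lags[k - 1]))


def noise_strength(
    traj: TrajectorySet, sigma: float, window: Optional[tuple] = None
) -> float:
    """std(xi) = sigma * sqrt(mean temporal variance of N) = sqrt(C_xi(0))."""
    if window is None:
        window = stationary_window(traj)
    _, block, _ = _survivor_block(traj, window)
    X = block.reshape(block.shape[0], -1)
    if X.shape[1] == 0:
        return 0.0
    v = float(X.var(axis=0, ddof=0).mean())
    return sigma * np.sqrt(v)


def diffusion_contribution(
    traj: TrajectorySet, system: InteractionSet
) -> np.ndarray:
    """(dN/dt)_diff = sum_v D_uv (N_iv - N_iu) along the trajectory.

    Negative for sources (net exporters), positive for sinks.  Shape
    (n_t, S, M); rows of extinct species are zero.
    """
    N = traj.N
    D = system.D
    return np.einsum("tiv,uv->tiu", N, D) - N * D.sum(axis=1)


@dataclass
class SourceSinkTable:
    """Per species-patch migration statistics over a stationary window."""

    table: pd.DataFrame  # columns: species, patch, mean_diff, sd_diff, label, persistent
    frac_sources_persistent: float
    frac_all_persistent: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def source_sink_stats(
    diff_series: np.ndarray,
    traj: TrajectorySet,
    window: Optional[tuple] = None,
) -> SourceSinkTable:
    """Classify species-patch pairs as persistent sources or sinks.

    A pair is a *source* when its time-averaged migration contribution is
    negative (it exports individuals) and *persistent* when that average
    is at least one temporal standard deviation away from zero.  Only
    species alive through the window are tabulated.
    """
    if window is None:
        window = stationary_window(traj)
    sel = (traj.times >= window[0]) & (traj.times <= window[1])
    surv = traj.alive[sel][-1] & traj.alive[sel][0]
    block = diff_series[sel][:, surv, :]  # (n_t, n_surv, M)
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=0)
    species = np.repeat(np.flatnonzero(surv), traj.M)
    patch = np.tile(np.arange(traj.M), int(surv.sum()))
    mean_f, sd_f = mean.ravel(), sd.ravel()
    persistent = np.abs(mean_f) >= sd_f
    label = np.where(mean_f < 0, "source", "sink")
    df = pd.DataFrame(
        {
            "species": species,
            "patch": patch,
            "mean_diff": mean_f,
            "sd_diff": sd_f,
            "label": label,
            "persistent": persistent,
        }
    )
    is_src = mean_f < 0
    frac_src = float(persistent[is_src].mean()) if is_src.any() else float("nan")
    frac_all = float(persistent.mean()) if len(persistent) else float("nan")
    return SourceSinkTable(
        table=df, frac_sources_persistent=frac_src, frac_all_persistent=frac_all
    )


def interpatch_synchrony(
    traj: TrajectorySet, window: Optional[tuple] = None
) -> float:
    """Mean Pearson correlation of a species' fluctuations across patches.

    Averaged over surviving species and unordered patch pairs; requires
    M >= 2.
    """
    if traj.M < 2:
        raise ValueError("synchrony needs at least two patches")
    if window is None:
        window = stationary_window(traj)
    _, block, _ = _survivor_block(traj, window)
    n_t, n_s, M = block.shape
    if n_s == 0:
        return float("nan")
    Y = block - block.mean(axis=0)
    sd = Y.std(axis=0, ddof=0)
    vals = []
    for u in range(M):
        for v in range(u + 1, M):
            num = (Y[:, :, u] * Y[:, :, v]).mean(axis=0)
            den = sd[:, u] * sd[:, v]
            ok = den > 0
            if ok.any():
                vals.append((num[ok] / den[ok]).mean())
    return float(np.mean(vals))
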