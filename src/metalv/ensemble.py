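"""Quenched random disorder for metacommunity Lotka-Volterra systems.

A metacommunity instance is defined by a species pool of size ``S`` spread
over ``M`` patches coupled by all-to-all migration.  Each directed species
pair ``(i, j)`` interacts with probability ``c`` (one Bernoulli draw shared
by every patch); conditional on interacting, the patch values
``A[i, j, u]`` are jointly Gaussian with common marginal
``Normal(mu_A, sd_A**2)`` and equicorrelation ``rho`` between patches.
The construction uses a shared latent component,

    A[i, j, u] = mu_A + sd_A * (sqrt(rho) * z_ij + sqrt(1 - rho) * z_ij_u),

which realises the equicorrelation exactly.  Setting ``gamma`` non-zero
correlates ``A[i, j, u]`` with ``A[j, i, u]`` (symmetric vs antisymmetric
interaction structure); in that case the sparsity mask is drawn per
unordered pair so that the reciprocal coefficient always exists.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import yaml

__all__ = [
    "EnsembleParams",
    "InteractionSet",
    "DisorderScales",
    "sample_interactions",
    "disorder_scales",
]


@dataclass(frozen=True)
class EnsembleParams:
    """Parameters of the random-disorder ensemble.

    Attributes
    ----------
    S : int
        Species-pool size.
    M : int
        Number of patches.
    c : float
        Connectance: probability that a directed pair interacts.
    mu_A : float
        Mean of the non-zero interaction coefficients.
    sd_A : float
        Standard deviation of the non-zero interaction coefficients.
    rho : float
        Inter-patch correlation of a given coefficient's values across
        patches.  Must lie in ``[-1/(M-1), 1]`` for the equicorrelated
        Gaussian to be positive semidefinite.
    gamma : float
        Correlation between reciprocal coefficients ``A_ij`` and ``A_ji``
        (0 = unstructured interactions).
    B : float
        Carrying capacity, identical for every species and patch.
    d : float
        Total migration rate out of a patch; pairwise rate is
        ``d / (M - 1)``.
    N_c : float
        Extinction cutoff: a species dropping below ``N_c`` in *all*
        patches is removed permanently.
    seed : int
        Seed of the quenched-disorder draw.
    """

    S: int
    M: int
    c: float
    mu_A: float
    sd_A: float
    rho: float = 0.0
    gamma: float = 0.0
    B: float = 1.0
    d: float = 0.0
    N_c: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1 or self.M < 1:
            raise ValueError("S and M must be at least 1")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("connectance c must lie in [0, 1]")
        if self.sd_A < 0:
            raise ValueError("sd_A must be non-negative")
        if self.N_c <= 0:
            raise ValueError("N_c must be positive")
        if self.d < 0:
            raise ValueError("migration rate d must be non-negative")
        lo = -1.0 / (self.M - 1) if self.M > 1 else 0.0
        if self.M > 1 and not lo <= self.rho <= 1.0:
            raise ValueError(
                f"rho={self.rho} outside the positive-semidefinite range "
                f"[{lo:.4g}, 1] for M={self.M} equicorrelated patches"
            )
        if not -1.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [-1, 1]")

    def replace(self, **kw) -> "EnsembleParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleParams":
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "EnsembleParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class InteractionSet:
    """One quenched draw of the metacommunity disorder.

    ``A`` has shape ``(S, S, M)`` with zero diagonal, ``B`` shape
    ``(S, M)``, ``D`` shape ``(M, M)`` with zero diagonal, and ``mask``
    is the ``(S, S)`` boolean sparsity pattern shared by all patches.
    """

    A: np.ndarray
    B: np.ndarray
    D: np.ndarray
    mask: np.ndarray
    params: EnsembleParams

    @property
    def S(self) -> int:
        return self.A.shape[0]

    @property
    def M(self) -> int:
        return self.A.shape[2]

    def patch_stack(self) -> np.ndarray:
        """Interactions as a contiguous ``(M, S, S)`` stack (fast matmul)."""
        return np.ascontiguousarray(np.moveaxis(self.A, 2, 0))

    def to_hdf5(self, path: Union[str, Path]) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("A", data=self.A)
            f.create_dataset("B", data=self.B)
            f.create_dataset("D", data=self.D)
            f.create_dataset("mask", data=self.mask)
            f.attrs["params"] = json.dumps(self.params.to_dict())

    @classmethod
    def from_hdf5(cls, path: Union[str, Path]) -> "InteractionSet":
        with h5py.File(path, "r") as f:
            params = EnsembleParams.from_dict(json.loads(f.attrs["params"]))
            return cls(
                A=f["A"][...],
                B=f["B"][...],
                D=f["D"][...],
                mask=f["mask"][...].astype(bool),
                params=params,
            )


@dataclass(frozen=True)
class DisorderScales:
    """Rescaled disorder parameters of the interaction ensemble.

    ``mu_tot = c S mu_A`` is the total mean interaction load felt by one
    species and ``sigma = sqrt(c S var(A))`` the rescaled interaction
    heterogeneity, with the variance taken over the *full* entry
    distribution (zeros included):
    ``var(A) * S = c S (sd_A**2 + (1 - c) mu_A**2)``.
    """

    mu_tot: float
    sigma: float

    def __post_init__(self):
        if not np.isfinite(self.mu_tot) or not np.isfinite(self.sigma):
            raise ValueError("disorder scales must be finite")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def disorder_scales(params: EnsembleParams) -> DisorderScales:
    """Compute (mu_tot, sigma) from the ensemble parameters.

    The convention includes the zero mass of the sparse entries, so the
    fully connected case ``c = 1`` reduces to ``sigma = sd_A sqrt(S)``.
    """
    cS = params.c * params.S
    mu_tot = cS * params.mu_A
    var_full = cS * (params.sd_A**2 + (1.0 - params.c) * params.mu_A**2)
    return DisorderScales(mu_tot=mu_tot, sigma=float(np.sqrt(var_full)))


def migration_matrix(M: int, d: float) -> np.ndarray:
    """All-to-all migration operator: off-diagonal ``d/(M-1)``, zero diagonal."""
    if M == 1:
        return np.zeros((1, 1))
    D = np.full((M, M), d / (M - 1))
    np.fill_diagonal(D, 0.0)
    return D


def sample_interactions(params: EnsembleParams) -> InteractionSet:
    """Draw one quenched realisation of the metacommunity disorder.

    Deterministic given ``params.seed``.  The sparsity mask is shared by
    every patch; only the coefficient values vary with the patch index,
    with exact equicorrelation ``rho``.
    """
    S, M = params.S, params.M
    rng = np.random.default_rng(params.seed)

    if params.gamma != 0.0:
        # reciprocal correlation requires both directions of a pair to
        # exist together: draw the mask per unordered pair
        upper = np.triu(rng.random((S, S)) < params.c, k=1)
        mask = upper | upper.T
    else:
        mask = rng.random((S, S)) < params.c
        np.fill_diagonal(mask, False)

    z_shared = _pair_correlated_normal(rng, S, params.gamma)
    z_patch = np.empty((S, S, M))
    for u in range(M):
        z_patch[:, :, u] = _pair_correlated_normal(rng, S, params.gamma)

    r = min(max(params.rho, 0.0), 1.0)
    if params.M > 1 and params.rho < 0:
        # negative equicorrelation: fall back to an exact Cholesky draw of
        # the M-variate kernel for each pair component
        A_fluct = _equicorrelated_negative(rng, S, M, params.rho, params.gamma)
    else:
        A_fluct = np.sqrt(r) * z_shared[:, :, None] + np.sqrt(1.0 - r) * z_patch
    A = params.mu_A + params.sd_A * A_fluct
    A *= mask[:, :, None]

    B = np.full((S, M), float(params.B))
    D = migration_matrix(M, params.d)
    return InteractionSet(A=A, B=B, D=D, mask=mask, params=params)


def _pair_correlated_normal(rng: np.random.Generator, S: int, gamma: float) -> np.ndarray:
    """An (S, S) standard-normal matrix with corr(z_ij, z_ji) = gamma."""
    g = rng.standard_normal((S, S))
    if gamma == 0.0:
        return g
    a = np.sqrt((1.0 + gamma) / 2.0)
    b = np.sqrt((1.0 - gamma) / 2.0)
    sym = (g + g.T) / np.sqrt(2.0)
    asym = (g - g.T) / np.sqrt(2.0)
    return a * sym + b * asym


def _equicorrelated_negative(
    rng: np.random.Generator, S: int, M: int, rho: float, gamma: float
) -> np.ndarray:
    cov = np.full((M, M), rho)
    np.fill_diagonal(cov, 1.0)
    L = np.linalg.cholesky(cov)
    z = np.empty((S, S, M))
    for u in range(M):
        z[:, :, u] = _pair_correlated_normal(rng, S, gamma)
    return z @ L.T
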