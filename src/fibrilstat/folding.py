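"""Zimm-Bragg and zipper models for helix-coil transitions in single chains.

The coil residue is the reference state (weight 1); ``s`` is the
equilibrium constant for extending a helical block by one residue and
``sigma`` the additional initiation penalty for starting a block, so a
block of ``n`` helical residues carries the weight ``sigma * s**n``.

The zipper model allows at most one helical stretch; the Zimm-Bragg model
allows any number and is solved with a 2x2 transfer matrix whose largest
eigenvalue gives the long-chain (thermodynamic-limit) closed forms for the
helicity and the mean helical segment length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tmcore import log_derivative_scalar

__all__ = [
    "FoldingParams",
    "FoldingObservables",
    "zipper_partition",
    "zb_partition_thermolimit",
    "zb_lambda1",
    "helicity_closed",
    "mean_helix_length_closed",
    "zb_partition_finite",
    "chain_averages",
]


@dataclass(frozen=True)
class FoldingParams:
    """Zimm-Bragg parameters of one chain."""

    sigma: float
    s: float
    N: int
    N_H: int | None = None

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.s > 0):
            raise ValueError("sigma and s must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.N_H is not None and self.N_H > self.N:
            raise ValueError("N_H cannot exceed N")

    @property
    def n_helix_max(self) -> int:
        return self.N if self.N_H is None else self.N_H


@dataclass(frozen=True)
class FoldingObservables:
    """Helicity, segment count and mean segment length of a finite chain."""

    theta: float
    nu: float
    L: float


def zipper_partition(N: int, sigma: float, s: float) -> float:
    """Zipper-model partition function ``1 + sum_k (N-k+1) sigma s**k``.

    A single helical stretch of any length 1..N may form; the degeneracy
    ``N - k + 1`` counts its placements.  Evaluated by the closed form
    ``1 + sigma (s**(N+2) - (N+1) s**2 + N s) / (s-1)**2`` with the exact
    ``s = 1`` sum ``1 + sigma N (N+1) / 2`` used near ``s = 1``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if abs(s - 1.0) < 1e-4:
        # the closed form cancels catastrophically near s=1; the direct sum
        # of positive terms is exact there (and reduces to 1 + sigma N(N+1)/2
        # at s=1)
        sk, acc = 1.0, 0.0
        for k in range(1, N + 1):
            sk *= s
            acc += (N - k + 1) * sk
        return 1.0 + sigma * acc
    return 1.0 + sigma * (s ** (N + 2) - (N + 1) * s**2 + N * s) / (s - 1.0) ** 2


def zb_lambda1(sigma: float, s: float) -> float:
    """Largest transfer-matrix eigenvalue ``(1 + s + sqrt((s-1)^2 + 4 s sigma))/2``."""
    return 0.5 * (1.0 + s + math.sqrt((s - 1.0) ** 2 + 4.0 * s * sigma))


def zb_partition_thermolimit(N: int, sigma: float, s: float) -> float:
    """Thermodynamic-limit partition function ``lambda_1**N``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return zb_lambda1(sigma, s) ** N


def helicity_closed(sigma: float, s: float) -> float:
    """Long-chain helicity ``1/2 + (s-1) / (2 sqrt((s-1)^2 + 4 sigma s))``."""
    if not (sigma > 0 and s > 0):
        raise ValueError("sigma and s must be positive")
    return 0.5 + (s - 1.0) / (2.0 * math.sqrt((s - 1.0) ** 2 + 4.0 * sigma * s))


def mean_helix_length_closed(sigma: float, s: float) -> float:
    """Long-chain mean helical segment length ``1 + 2s / (1 - s + sqrt((1-s)^2 + 4 sigma s))``."""
    if not (sigma > 0 and s > 0):
        raise ValueError("sigma and s must be positive")
    return 1.0 + 2.0 * s / (1.0 - s + math.sqrt((1.0 - s) ** 2 + 4.0 * sigma * s))


def _zb_matrix(sigma: float, s: float) -> np.ndarray:
    # T[new, old] over states (coil, helix); helix growth is one-directional:
    # coil after helix costs nothing, helix after coil nucleates (sigma*s)
    return np.array([[1.0, 1.0], [sigma * s, s]])


def zb_partition_finite(N: int, sigma: float, s: float) -> float:
    """Finite-chain Zimm-Bragg partition function (open chain).

    The first residue carries weight 1 (coil) or ``sigma * s`` (helix,
    nucleating a block at the chain start); subsequent residues follow the
    pair weights cc:1, hc:1, ch:``sigma s``, hh:``s``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    v = np.array([1.0, sigma * s])
    T = _zb_matrix(sigma, s)
    for _ in range(N - 1):
        v = T @ v
    return float(v.sum())


def chain_averages(
    N: int, sigma: float, s: float, N_H: int | None = None
) -> FoldingObservables:
    """Finite-chain helicity, segment count and mean segment length.

    Obtained as logarithmic derivatives of the finite-chain partition
    function: every helical residue carries one factor of ``s`` and every
    segment one factor of ``sigma``, so
    ``theta = (1/N_H) dlnZ/dln s`` and ``nu = dlnZ/dln sigma``; the mean
    segment length is ``L = N_H * theta / nu``.
    """
    if N < 2:
        raise ValueError("chain averages need N >= 2")
    nh = N if N_H is None else N_H
    dln_s = log_derivative_scalar(lambda x: zb_partition_finite(N, sigma, x), s)
    dln_sig = log_derivative_scalar(lambda x: zb_partition_finite(N, x, s), sigma)
    theta = dln_s / nh
    nu = dln_sig
    L = nh * theta / nu if nu > 0 else float("nan")
    return FoldingObservables(theta=theta, nu=nu, L=L)
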