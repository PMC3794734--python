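"""Transfer matrices and partition functions for canonical aggregate models.

A column of the lattice (all ``Ly * Lz`` proteins at a given position along
the propagation axis) is a composite state.  The transfer matrix entry
``T[new, old]`` carries the full Boltzmann weight of the *new* column (its
propagation weights and intra-column sheet-sheet bonds) together with the
interfacial weights ``sigma(new_site, old_site)`` across the inter-column
interface, one factor per filament row.  The polymerization weight ``k`` is
a global prefactor, counted once per nearest-neighbour protein pair.

With the initial vector carrying the first column's intrinsic weight and the
final vector selecting allowed final states, the open-chain partition
function is ``Z = k**n_bonds * <f| T^(Lx-1) |i>``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .params import BOUNDARIES, EnergyParams, LatticeSpec

__all__ = [
    "TransferMatrixRep",
    "SpectralData",
    "build_transfer_matrix",
    "partition_open",
    "partition_periodic",
    "spectral_decompose",
    "log_derivative",
]


def _prop_weights(spec: LatticeSpec, params: EnergyParams) -> dict[int, float]:
    """Per-site propagation weight of each conformation."""
    if spec.q == 2:
        return {0: 1.0, 1: params.s1}
    return {0: 1.0, 1: params.s1, 2: params.s2}


def _sigma_pair(spec: LatticeSpec, params: EnergyParams) -> dict[tuple[int, int], float]:
    """Interfacial weight between two adjacent conformations.

    In the two-state model each coil/ordered interface carries
    ``exp(-R1) = sqrt(sigma1)``, so a full ordered segment bounded by coil
    pays the classic Zimm-Bragg initiation weight ``sigma1 = exp(-2 R1)``
    and the transfer matrix shares its characteristic equation with the
    helix-coil (folding) matrix.  The three-state Potts model carries the
    full ``sigma(r, r')`` on every interface, as its Hamiltonian is
    written.
    """
    if spec.q == 2:
        rs = math.sqrt(params.sigma1)
        return {(0, 0): 1.0, (1, 1): 1.0, (0, 1): rs, (1, 0): rs}
    pairs = {(0, 1): params.sigma1, (0, 2): params.sigma2, (1, 2): params.sigma3}
    out = {(r, r): 1.0 for r in range(3)}
    for (a, c), w in pairs.items():
        out[(a, c)] = w
        out[(c, a)] = w
    return out


def column_states(spec: LatticeSpec) -> list[tuple[int, ...]]:
    """Ordered composite column states (tuples of per-site conformations).

    Site order within a column is protofibril-major: the first ``Ly`` sites
    belong to the first strip layer, the next ``Ly`` to the second (cube).
    """
    alphabet = range(spec.q) if spec.q == 3 else (0, 1)
    return list(itertools.product(alphabet, repeat=spec.sites_per_column))


def intra_column_weight(
    state: tuple[int, ...], spec: LatticeSpec, params: EnergyParams
) -> float:
    """Intrinsic Boltzmann weight of one column (propagation + lateral bonds).

    Lateral sheet-sheet pairs within a strip layer each carry ``b``; for the
    cube model one further ``b`` is carried by a column whose four proteins
    are all sheet (the inter-protofibril bond of the all-sheet column).
    """
    prop = _prop_weights(spec, params)
    sheet = spec.sheet_state
    w = 1.0
    for r in state:
        w *= prop[r]
    Ly, Lz = spec.Ly, spec.Lz
    for z in range(Lz):
        layer = state[z * Ly : (z + 1) * Ly]
        for y in range(Ly - 1):
            if layer[y] == sheet and layer[y + 1] == sheet:
                w *= params.b
    if spec.geometry == "cube" and all(r == sheet for r in state):
        w *= params.b
    return w


def _boundary_mask(
    states: Sequence[tuple[int, ...]], spec: LatticeSpec, boundary: str
) -> np.ndarray:
    if boundary in ("free", "periodic"):
        return np.ones(len(states))
    if boundary == "coil_only":
        return np.array([1.0 if all(r == 0 for r in st) else 0.0 for st in states])
    if boundary == "sheet_or_coil":
        if spec.q == 2:
            return np.ones(len(states))
        return np.array([1.0 if all(r != 1 for r in st) else 0.0 for st in states])
    raise ValueError(f"boundary must be one of {BOUNDARIES}")


@dataclass
class TransferMatrixRep:
    """Transfer matrix with its state labels and parameter snapshot."""

    matrix: np.ndarray
    state_labels: list[tuple[int, ...]]
    intra_weights: np.ndarray
    spec: LatticeSpec
    params: EnergyParams

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def boundary_vectors(self, boundary: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Final (row) and initial (column) vectors for an open chain.

        The initial vector holds each allowed initial column's intrinsic
        weight; the final vector is an indicator of allowed final columns.
        """
        boundary = boundary or self.spec.boundary
        mask = _boundary_mask(self.state_labels, self.spec, boundary)
        return mask.copy(), self.intra_weights * mask


def build_transfer_matrix(spec: LatticeSpec, params: EnergyParams) -> TransferMatrixRep:
    """Transfer matrix of the filament / strip / cube model.

    ``T[new, old] = intra(new) * prod_rows sigma(new_site, old_site)``.
    """
    states = column_states(spec)
    n = len(states)
    sig = _sigma_pair(spec, params)
    intra = np.array([intra_column_weight(st, spec, params) for st in states])
    T = np.empty((n, n))
    for i_new, new in enumerate(states):
        w_new = intra[i_new]
        for i_old, old in enumerate(states):
            w = w_new
            for a, c in zip(new, old):
                w *= sig[(a, c)]
            T[i_new, i_old] = w
    if not np.all(np.isfinite(T)):
        raise ValueError("non-finite transfer-matrix entries; check parameters")
    return TransferMatrixRep(T, states, intra, spec, params)


def _apply_power(T: np.ndarray, v: np.ndarray, n: int) -> np.ndarray:
    for _ in range(n):
        v = T @ v
    return v


def partition_open(
    rep: TransferMatrixRep, Lx: int, boundary: str | None = None
) -> float:
    """Open-chain partition function ``k**n_bonds * <f| T^(Lx-1) |i>``."""
    if Lx < 1:
        raise ValueError("Lx must be >= 1")
    boundary = boundary or rep.spec.boundary
    if boundary == "periodic":
        return partition_periodic(rep, Lx)
    f, i = rep.boundary_vectors(boundary)
    z = float(f @ _apply_power(rep.matrix, i, Lx - 1))
    if z <= 0.0:
        raise ValueError("partition function is not positive; incompatible boundary")
    return rep.params.k ** rep.spec.n_bonds(Lx) * z


def partition_periodic(rep: TransferMatrixRep, Lx: int) -> float:
    """Ring partition function ``k**n_bonds * trace(T^Lx)``."""
    if Lx < 2:
        raise ValueError("periodic chains need Lx >= 2")
    z = float(np.trace(np.linalg.matrix_power(rep.matrix, Lx)))
    return rep.params.k ** rep.spec.n_bonds(Lx, periodic=True) * z


@dataclass
class SpectralData:
    """Eigenvalues and boundary coefficients of a transfer matrix.

    ``sum_i coeffs[i] * eigenvalues[i]**(Lx-1)`` reproduces the
    boundary-contracted matrix power ``<f| T^(Lx-1) |i>``; the k prefactor
    is *not* included.  ``condition`` estimates the conditioning of the
    eigenvector basis; above ~1e8 the spectral sum is unreliable and
    callers should fall back to direct matrix powers.
    """

    eigenvalues: np.ndarray
    coeffs: np.ndarray
    condition: float
    boundary: str = "free"

    @property
    def lambda1(self) -> float:
        return float(np.real(self.eigenvalues[0]))

    def contracted_power(self, Lx: int) -> float:
        """``<f| T^(Lx-1) |i>`` from the spectral sum."""
        return float(np.real(np.sum(self.coeffs * self.eigenvalues ** (Lx - 1))))


CONDITION_LIMIT = 1e8


def spectral_decompose(
    rep: TransferMatrixRep, boundary: str | None = None
) -> SpectralData:
    """Eigen-decomposition with boundary coefficients, sorted by |lambda|."""
    boundary = boundary or rep.spec.boundary
    lam, V = np.linalg.eig(rep.matrix)
    f, i = rep.boundary_vectors(boundary)
    try:
        cond = float(np.linalg.cond(V))
    except np.linalg.LinAlgError:  # pragma: no cover - defective basis
        cond = np.inf
    coeffs = (f @ V) * np.linalg.solve(V, i.astype(complex))
    order = np.argsort(-np.abs(lam), kind="stable")
    return SpectralData(lam[order], coeffs[order], cond, boundary)


def _log_derivative_scalar(fn: Callable[[float], float], x0: float, h: float = 1e-4) -> float:
    """d ln fn / d ln x at x0, centered differences + one Richardson step."""
    if not (x0 > 0.0 and np.isfinite(x0)):
        raise ValueError("evaluation point must be positive and finite")

    def d(step: float) -> float:
        fp = fn(x0 * np.exp(step))
        fm = fn(x0 * np.exp(-step))
        if not (fp > 0.0 and fm > 0.0):
            raise ValueError("field must be positive near the evaluation point")
        return (np.log(fp) - np.log(fm)) / (2.0 * step)

    d1 = d(h)
    d2 = d(h / 2.0)
    return (4.0 * d2 - d1) / 3.0


def log_derivative(
    scalar_field: Callable[[EnergyParams], float],
    weight_name: str,
    point: EnergyParams,
    h: float = 1e-4,
) -> float:
    """``d ln field / d ln w`` for one Boltzmann weight ``w`` of ``point``.

    These logarithmic derivatives of partition functions are the canonical
    thermodynamic averages (e.g. the helicity is the ``s`` log-derivative of
    ``ln Z`` divided by the chain length).
    """
    x0 = point.weight(weight_name)
    return _log_derivative_scalar(
        lambda w: scalar_field(point.with_weight(weight_name, w)), x0, h=h
    )


# re-exported for modules that need a plain-scalar version (e.g. fugacity
# derivatives where the variable is not an EnergyParams weight)
log_derivative_scalar = _log_derivative_scalar
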