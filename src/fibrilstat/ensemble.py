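"""Dilute multi-species equilibria of filaments, protofibrils and fibrils.

In a dilute, well-mixed solution each aggregate species (filament, strip of
``Ly`` filaments, cube of two stacked strips) occurs with number density

    rho(L) = Z(L) * z**L,

where ``Z(L)`` is the canonical partition function of the aggregate with
``L = Lx * Ly * Lz`` proteins and ``z = exp(mu)`` is the protein fugacity.
Densities and the fugacity are dimensionless activities relative to a
declared standard-state concentration (default 1 uM).  Fixing the total
protein concentration ``phi`` closes the model: the mass balance

    phi = sum_species sum_Lx L * rho(L)

is solved for ``z``, and every observable (sheet fraction, mean lengths,
fibril mass share) follows from the resulting size distributions.

Species sums are evaluated in the spectral basis of each species' transfer
matrix, where they are geometric/arithmetic-geometric series in
``x_i = k**a * z**l * lambda_i`` (``a`` bonds and ``l`` proteins added per
column); they converge for ``x_1 < 1`` and diverge at the species'
saturation fugacity, so a root of the mass balance always exists.
An adaptive direct sum over ``Lx`` provides an internal cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import EnergyParams, LatticeSpec
from .tmcore import (
    TransferMatrixRep,
    build_transfer_matrix,
    log_derivative,
    spectral_decompose,
)

__all__ = [
    "Species",
    "SpeciesEnsemble",
    "DiluteState",
    "EnsembleObservables",
    "species_density",
    "ensemble_sums",
    "solve_fugacity",
    "sheet_fraction",
    "mean_length",
    "mass_fraction_curve",
    "half_rise_concentration",
]


@dataclass(frozen=True)
class Species:
    """One aggregate species: a lattice geometry growing along x."""

    geometry: str = "filament"
    Ly: int = 1
    Lz: int = 1
    Lx_min: int = 1
    boundary: str = "free"
    q: int = 2

    def __post_init__(self) -> None:
        if self.Lx_min < 1:
            raise ValueError("Lx_min must be >= 1")
        # validate geometry constraints eagerly
        self.lattice(max(self.Lx_min, 1))

    @property
    def mass_per_column(self) -> int:
        return self.Ly * self.Lz

    def lattice(self, Lx: int = 1) -> LatticeSpec:
        return LatticeSpec(
            geometry=self.geometry,
            Lx=Lx,
            Ly=self.Ly,
            Lz=self.Lz,
            q=self.q,
            boundary=self.boundary,
        )

    def label(self) -> str:
        if self.geometry == "filament":
            return "filament"
        if self.geometry == "strip":
            return f"strip(Ly={self.Ly})"
        return "cube(2x2)"


@dataclass(frozen=True)
class SpeciesEnsemble:
    """The list of aggregate species coexisting at equilibrium."""

    species: tuple[Species, ...]
    standard_state_uM: float = 1.0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("ensemble needs at least one species")
        if self.standard_state_uM <= 0:
            raise ValueError("standard state must be positive")

    @classmethod
    def abeta40(
        cls, boundary: str = "sheet_or_coil", standard_state_uM: float = 1.0
    ) -> "SpeciesEnsemble":
        """Filament + two-filament strip + 2x2 cube (the A-beta(1-40) set)."""
        return cls(
            (
                Species("filament", boundary=boundary),
                Species("strip", Ly=2, boundary=boundary),
                Species("cube", Ly=2, Lz=2, boundary=boundary),
            ),
            standard_state_uM,
        )

    @classmethod
    def alpha_synuclein(
        cls, boundary: str = "sheet_or_coil", standard_state_uM: float = 1.0
    ) -> "SpeciesEnsemble":
        """Strips of one to four filaments (the alpha-synuclein set)."""
        return cls(
            tuple(
                Species("strip" if Ly > 1 else "filament", Ly=Ly, boundary=boundary)
                for Ly in (1, 2, 3, 4)
            ),
            standard_state_uM,
        )


class _SpeciesSums:
    """Spectral data of one species, with closed-form size sums."""

    def __init__(self, sp: Species, params: EnergyParams):
        self.species = sp
        spec = sp.lattice()
        self.rep: TransferMatrixRep = build_transfer_matrix(spec, params)
        sd = spectral_decompose(self.rep, sp.boundary)
        self.lam = sd.eigenvalues  # complex, |lam| descending
        self.coef = sd.coeffs
        self.condition = sd.condition
        self.ell = sp.mass_per_column  # proteins per column
        # bonds(Lx) = a*Lx + b0 (a bonds and ell proteins added per column)
        self.a = spec.n_bonds(2) - spec.n_bonds(1)
        self.b0 = spec.n_bonds(1) - self.a
        self.k = params.k
        self.Lx_min = sp.Lx_min
        self.lambda1 = float(np.real(self.lam[0]))
        if not np.isfinite(self.lambda1) or self.lambda1 <= 0:
            raise ValueError("species transfer matrix has no positive leading eigenvalue")

    @property
    def z_max(self) -> float:
        """Saturation fugacity: series diverge when k**a * z**ell * lambda1 -> 1."""
        return (1.0 / (self.k**self.a * self.lambda1)) ** (1.0 / self.ell)

    def rho_phi(self, z) -> tuple[np.ndarray, np.ndarray]:
        """Number density and mass density of this species, vectorized in z.

        With ``y = k**a z**ell`` and ``x = y lam_i``,

            rho = k**b0 * sum_i c_i y x_i**(m-1) / (1 - x_i)
            phi = ell * k**b0 * sum_i c_i y x_i**(m-1) (m-(m-1)x_i)/(1-x_i)**2

        (the ``x**(m-1)`` form keeps zero eigenvalues — singular transfer
        matrices such as the sigma = 1 case — finite).
        """
        m = self.Lx_min
        y = self.k**self.a * np.asarray(z, dtype=float)[..., None] ** self.ell
        x = y * self.lam
        pref = self.k**self.b0 * self.coef * y * x ** (m - 1)
        rho = np.real(np.sum(pref / (1.0 - x), axis=-1))
        phi = self.ell * np.real(
            np.sum(pref * (m - (m - 1) * x) / (1.0 - x) ** 2, axis=-1)
        )
        return rho, phi

    def phi_first_term(self, z) -> np.ndarray:
        """Mass held in the smallest (Lx = Lx_min) aggregates of the species."""
        m = self.Lx_min
        zc = self.k ** (self.a * m + self.b0) * np.asarray(z) ** (self.ell * m)
        Zm = float(np.real(np.sum(self.coef * self.lam ** (m - 1))))
        return self.ell * m * Zm * zc

    def mean_columns(self, z) -> np.ndarray:
        """Mean number of columns <Lx> of this species at fugacity z."""
        rho, phi = self.rho_phi(z)
        return phi / (self.ell * rho)

    def rho_phi_direct(
        self, z: float, rtol: float = 1e-12, max_columns: int = 200_000
    ) -> tuple[float, float]:
        """Adaptive direct sum over Lx (independent of the spectral forms)."""
        f, i = self.rep.boundary_vectors(self.species.boundary)
        T = self.rep.matrix
        v = i.copy()
        rho = phi = 0.0
        zc = float(z) ** self.ell
        for Lx in range(1, max_columns + 1):
            if Lx > 1:
                v = T @ v
            if Lx < self.Lx_min:
                continue
            Zl = self.k ** (self.a * Lx + self.b0) * float(f @ v)
            term = Zl * zc**Lx
            rho += term
            phi += self.ell * Lx * term
            if Lx > self.Lx_min + 4 and self.ell * Lx * term < rtol * max(phi, 1e-300):
                return rho, phi
        raise RuntimeError("direct species sum did not converge; z too close to z_max")


class EnsembleCalculator:
    """Caches per-species spectral sums for one parameter set.

    All species' eigen-sums are flattened into single arrays so that the
    mass balance and its z-derivative evaluate as a handful of vectorized
    operations per fugacity grid.
    """

    def __init__(self, ensemble: SpeciesEnsemble, params: EnergyParams):
        self.ensemble = ensemble
        self.params = params
        self.sums = [_SpeciesSums(sp, params) for sp in ensemble.species]
        self.z_max = min(s.z_max for s in self.sums)
        # flattened eigen data across species
        self._lam = np.concatenate([s.lam for s in self.sums])
        self._pref = np.concatenate(
            [s.k**s.b0 * s.coef for s in self.sums]
        )
        self._scale = np.concatenate(
            [np.full(len(s.lam), s.k**s.a) for s in self.sums]
        )
        self._ell = np.concatenate(
            [np.full(len(s.lam), float(s.ell)) for s in self.sums]
        )
        self._m = np.concatenate(
            [np.full(len(s.lam), float(s.Lx_min)) for s in self.sums]
        )
        # entries with a real positive eigenvalue, where 1-x suffers
        # cancellation near saturation and is computed through expm1
        lam = self._lam
        self._real_pos = (np.abs(lam.imag) <= 1e-12 * np.abs(lam.real)) & (
            lam.real > 0
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            self._log_scale_lam = np.where(
                self._real_pos, np.log(np.abs(self._scale * lam.real) + 1e-300), 0.0
            )

    def _x_one(self, z) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """y(z), x_i(z) and an accurately cancelled 1 - x_i(z)."""
        z = np.asarray(z, dtype=float)[..., None]
        y = self._scale * z**self._ell
        x = y * self._lam
        t = self._log_scale_lam + self._ell * np.log(z)
        one = np.where(self._real_pos, -np.expm1(t), 1.0 - x)
        return y, x, one

    def rho_phi(self, z) -> tuple[np.ndarray, np.ndarray]:
        """Total number and mass density (vectorized in z)."""
        y, x, one = self._x_one(z)
        m = self._m
        pref = self._pref * y * x ** (m - 1)
        rho = np.real(np.sum(pref / one, axis=-1))
        phi = np.real(np.sum(self._ell * pref * (m - (m - 1) * x) / one**2, axis=-1))
        return rho, phi

    def _phi_and_slope(self, z) -> tuple[np.ndarray, np.ndarray]:
        """phi(z) and d phi / d ln z (exact, from the closed-form sums)."""
        y, x, one = self._x_one(z)
        m = self._m
        pref = self._pref * y * x ** (m - 1)
        s1 = pref * (m - (m - 1) * x) / one**2
        # (x d/dx) of the mass sum, written so lam = 0 terms stay finite
        ds1 = (
            m * pref * (m - (m - 1) * x) / one**2
            - pref * (m - 1) * x / one**2
            + 2.0 * pref * (m - (m - 1) * x) * x / one**3
        )
        phi = np.real(np.sum(self._ell * s1, axis=-1))
        slope = np.real(np.sum(self._ell**2 * ds1, axis=-1))
        return phi, slope

    def phi_by_species(self, z) -> np.ndarray:
        return np.stack([s.rho_phi(z)[1] for s in self.sums], axis=-1)

    def rho_by_species(self, z) -> np.ndarray:
        return np.stack([s.rho_phi(z)[0] for s in self.sums], axis=-1)

    def solve_z(self, phi_target, bits: int = 40, newton: int = 12) -> np.ndarray:
        """Fugacities solving the mass balance.

        phi(z) is strictly increasing on (0, z_max) and diverges at z_max,
        so the root exists and is unique for every positive target.
        Bisection in ln z localizes it; safeguarded Newton iterations on
        ln phi(ln z), using the exact slope of the closed-form sums,
        polish it to full precision.
        """
        phi_target = np.atleast_1d(np.asarray(phi_target, dtype=float))
        if np.any(phi_target <= 0):
            raise ValueError("total concentration must be positive")
        hi = np.full(phi_target.shape, math.log(self.z_max) - 1e-14)
        lo = np.minimum(np.log(phi_target) - 60.0, hi - 60.0)
        target = np.log(phi_target)
        for _ in range(bits):
            mid = 0.5 * (lo + hi)
            phi = self.rho_phi(np.exp(mid))[1]
            high = np.log(np.maximum(phi, 1e-300)) > target
            hi = np.where(high, mid, hi)
            lo = np.where(high, lo, mid)
        u = 0.5 * (lo + hi)
        for _ in range(newton):
            phi, slope = self._phi_and_slope(np.exp(u))
            g = np.log(np.maximum(phi, 1e-300)) - target
            high = g > 0
            hi = np.where(high, u, hi)
            lo = np.where(high, lo, u)
            step = g * phi / np.maximum(slope, 1e-300)
            u_new = u - step
            bad = (u_new <= lo) | (u_new >= hi) | ~np.isfinite(u_new)
            u = np.where(bad, 0.5 * (lo + hi), u_new)
        return np.exp(u)


def species_density(
    species: Species, Lx: int, z: float, params: EnergyParams
) -> float:
    """Number density ``Z(L) * z**L`` of one aggregate size (L = Lx*Ly*Lz)."""
    if Lx < species.Lx_min:
        raise ValueError("Lx below the species' minimum aggregate size")
    if z == 0.0:
        return 0.0
    from .tmcore import partition_open

    rep = build_transfer_matrix(species.lattice(Lx), params)
    Z = partition_open(rep, Lx, species.boundary)
    return Z * z ** (Lx * species.mass_per_column)


def ensemble_sums(
    z: float,
    ensemble: SpeciesEnsemble,
    params: EnergyParams,
    rtol: float = 1e-8,
) -> tuple[float, float]:
    """Total number density and mass density at fugacity ``z``.

    Evaluated both by the closed-form spectral sums and by adaptive direct
    summation over aggregate sizes; the two routes must agree to ``rtol``
    or a ``ValueError`` is raised.
    """
    calc = EnsembleCalculator(ensemble, params)
    if not z < calc.z_max:
        raise ValueError(
            f"fugacity {z} is outside the convergence domain (z_max = {calc.z_max:g})"
        )
    rho_s, phi_s = calc.rho_phi(float(z))
    rho_d = phi_d = 0.0
    for s in calc.sums:
        r, p = s.rho_phi_direct(float(z))
        rho_d += r
        phi_d += p
    if abs(rho_s - rho_d) > rtol * abs(rho_d) or abs(phi_s - phi_d) > rtol * abs(phi_d):
        raise ValueError(
            "spectral and direct species sums disagree: "
            f"rho {rho_s:g} vs {rho_d:g}, phi {phi_s:g} vs {phi_d:g}"
        )
    return float(rho_s), float(phi_s)


@dataclass
class DiluteState:
    """Solution of the mass balance at one total concentration."""

    z: float
    phi: float
    rho_by_species: dict[str, float]
    phi_by_species: dict[str, float]
    eta: float
    standard_state_uM: float
    params: EnergyParams

    @property
    def mu(self) -> float:
        return math.log(self.z)


def solve_fugacity(
    phi_target: float, ensemble: SpeciesEnsemble, params: EnergyParams
) -> DiluteState:
    """Solve ``phi(z) = phi_target`` for the protein fugacity.

    ``phi_target`` is the total (monomer-equivalent) protein concentration
    in units of the ensemble's standard state.
    """
    calc = EnsembleCalculator(ensemble, params)
    z = float(calc.solve_z(phi_target)[0])
    rho = calc.rho_by_species(z)
    phis = calc.phi_by_species(z)
    first = sum(float(s.phi_first_term(z)) for s in calc.sums)
    labels = [s.label() for s in ensemble.species]
    return DiluteState(
        z=z,
        phi=float(np.sum(phis)),
        rho_by_species=dict(zip(labels, map(float, rho))),
        phi_by_species=dict(zip(labels, map(float, phis))),
        eta=1.0 - first / float(np.sum(phis)),
        standard_state_uM=ensemble.standard_state_uM,
        params=params,
    )


def sheet_fraction(
    z: float, ensemble: SpeciesEnsemble, params: EnergyParams
) -> float:
    """Mass-weighted sheet fraction ``<theta_2>`` of all aggregates.

    The sheet count of an aggregate is the log-derivative of its partition
    function with respect to the sheet propagation weight, so the
    mass-weighted fraction is ``s * d(rho_total)/ds / phi`` at fixed
    fugacity.
    """
    weight = "s1" if ensemble.species[0].q == 2 else "s2"

    def rho_total(p: EnergyParams) -> float:
        return float(EnsembleCalculator(ensemble, p).rho_phi(float(z))[0])

    calc = EnsembleCalculator(ensemble, params)
    rho, phi = calc.rho_phi(float(z))
    if phi == 0.0:
        raise ValueError("sheet fraction undefined at zero concentration")
    dln = log_derivative(rho_total, weight, params)
    return float(rho * dln / phi)


@dataclass
class EnsembleObservables:
    """Mean-size and composition observables of the dilute ensemble."""

    theta2: float
    mean_size: float  # mean number of proteins per aggregate, all species
    mean_columns_by_species: dict[str, float]
    rho_fib_over_phi: float  # mass share of the largest species
    eta: float


def mean_length(
    z: float, ensemble: SpeciesEnsemble, params: EnergyParams
) -> EnsembleObservables:
    """Aggregate-size observables at fugacity ``z``.

    ``mean_size`` is the ensemble-wide mean degree of polymerization
    (proteins per aggregate); per-species mean lengths are reported in
    columns along the growth axis, i.e. proteins / (Ly*Lz).
    """
    calc = EnsembleCalculator(ensemble, params)
    rho, phi = calc.rho_phi(float(z))
    labels = [s.species.label() for s in calc.sums]
    mean_cols = {
        lab: float(s.mean_columns(float(z))) for lab, s in zip(labels, calc.sums)
    }
    phis = calc.phi_by_species(float(z))
    first = sum(float(s.phi_first_term(float(z))) for s in calc.sums)
    return EnsembleObservables(
        theta2=sheet_fraction(z, ensemble, params),
        mean_size=float(phi / rho),
        mean_columns_by_species=mean_cols,
        rho_fib_over_phi=float(phis[-1] / phi),
        eta=1.0 - first / float(phi),
    )


def mass_fraction_curve(
    ensemble: SpeciesEnsemble,
    params: EnergyParams,
    phi_grid: np.ndarray,
    species_index: int = -1,
) -> np.ndarray:
    """Mass fraction of one species along a grid of total concentrations."""
    calc = EnsembleCalculator(ensemble, params)
    z = calc.solve_z(np.asarray(phi_grid, dtype=float))
    phis = calc.phi_by_species(z)
    return phis[..., species_index] / np.sum(phis, axis=-1)


def half_rise_concentration(
    phi_grid: np.ndarray, fraction: np.ndarray
) -> float:
    """Concentration at which a sigmoidal mass fraction reaches half of its
    high-concentration plateau (log-interpolated between grid points)."""
    phi_grid = np.asarray(phi_grid, dtype=float)
    fraction = np.asarray(fraction, dtype=float)
    plateau = fraction[-1]
    half = 0.5 * plateau
    above = np.nonzero(fraction >= half)[0]
    if len(above) == 0 or above[0] == 0:
        raise ValueError("half-rise not bracketed by the concentration grid")
    j = above[0]
    x0, x1 = np.log(phi_grid[j - 1]), np.log(phi_grid[j])
    y0, y1 = fraction[j - 1], fraction[j]
    return float(np.exp(x0 + (half - y0) * (x1 - x0) / (y1 - y0)))
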