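"""Grand-canonical lattice-gas models of fibril formation.

Lattice sites hold either a solvent cluster (state 0) or a protein in a
coil (1) or sheet (2) conformation; each protein carries the fugacity
``z = exp(beta mu_PC)``.  Beyond the canonical interactions (sheet
propagation ``P1``, polymerization ``K``, interfacial ``R1``), the models
add a nucleation/surface free energy ``A`` paid at solvent-aggregate
boundaries (weight ``sqrt(alpha) = exp(-A)`` per boundary) and an
inter-filament sheet-link free energy ``F``.

Two strip variants are implemented:

* variant A — filaments run along x, each row carrying its own nucleation
  window of ``nc`` columns; filaments in adjacent rows are linked by ``F``
  between lateral sheet pairs.  For ``nc > 1`` the nucleation term couples
  next-nearest columns, handled by augmenting the transfer-matrix state
  with the occupancy pattern of the previous ``nc - 1`` columns.
* variant B — the nucleus is a full column (perpendicular to the growth
  axis); the y direction carries full bond interactions (``F`` as the
  lateral sheet propagation, plus ``K`` and ``R1``) and ``A`` is paid when
  a uniformly occupied column meets its complete opposite.

The lattice is periodic along x; in the thermodynamic limit the grand
potential per site is ``ln lambda_1 / Ly`` (largest transfer-matrix
eigenvalue), and occupancy, sheet-segment, filament-count and
filament-mass observables follow as logarithmic derivatives.  Because
every matrix entry is a monomial in the weights, the derivatives are
evaluated exactly through the entrywise exponent matrices rather than by
finite differences.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .params import EnergyParams

__all__ = [
    "GCModelSpec",
    "GCTransferMatrix",
    "GCObservables",
    "SolutionLink",
    "build_gc_transfer_matrix",
    "gc_log_partition_per_site",
    "gc_partition_periodic",
    "gc_observables",
    "mu_pc_from_concentration",
]

KCAL_GAS_CONSTANT = 1.98720425864083e-3  # kcal / (mol K)

_MAX_COMPOSITE_SITES = 8


@dataclass(frozen=True)
class GCModelSpec:
    """A grand-canonical strip model (variant A or B)."""

    params: EnergyParams
    z: float
    variant: str = "A"
    q: int = 2
    Ly: int = 1
    nc: int = 1

    def __post_init__(self) -> None:
        if self.variant not in ("A", "B"):
            raise ValueError("variant must be 'A' or 'B'")
        if self.q != 2:
            raise NotImplementedError("grand-canonical models support q=2")
        if self.Ly < 1 or self.nc < 1:
            raise ValueError("Ly and nc must be >= 1")
        if self.z <= 0:
            raise ValueError("fugacity must be positive")
        if self.variant == "A" and self.nc * self.Ly > _MAX_COMPOSITE_SITES:
            raise ValueError(
                f"variant A supports nc*Ly <= {_MAX_COMPOSITE_SITES} composite sites"
            )

    def with_z(self, z: float) -> "GCModelSpec":
        return replace(self, z=z)

    def with_params(self, params: EnergyParams) -> "GCModelSpec":
        return replace(self, params=params)


class _Counts:
    """Log-weight accumulator: a product of weights and their exponents."""

    __slots__ = ("w", "z", "s1", "k", "alpha")

    def __init__(self) -> None:
        self.w = 1.0
        self.z = 0.0
        self.s1 = 0.0
        self.k = 0.0
        self.alpha = 0.0


@dataclass
class GCTransferMatrix:
    """Transfer matrix over (occupancy, conformation) column states.

    ``exponents[name][u, v]`` is the power of the named weight carried by
    entry ``(u, v)`` (for ``alpha`` in units of ``ln alpha``, i.e. half
    the count of ``exp(-A)`` boundary factors); they make exact
    thermodynamic derivatives possible.
    """

    matrix: np.ndarray
    state_labels: list[tuple]
    spec: GCModelSpec
    exponents: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def _occ(r: int) -> int:
    return 1 if r != 0 else 0


def _col_terms(col: tuple[int, ...], spec: GCModelSpec, c: _Counts) -> None:
    """Fugacity and intra-column (y-direction) terms of one column."""
    p = spec.params
    rs = math.sqrt(p.sigma1)
    npr = sum(_occ(r) for r in col)
    c.w *= spec.z**npr
    c.z += npr
    for j in range(spec.Ly - 1):
        r, rn = col[j], col[j + 1]
        if spec.variant == "A":
            if r == 2 and rn == 2:
                c.w *= p.f
        else:
            if _occ(r) and _occ(rn):
                c.w *= p.k
                c.k += 1
                if r == 2:
                    c.w *= p.f
                if (r == 2) != (rn == 2):
                    c.w *= rs
            elif _occ(r) != _occ(rn):
                if r == 2 or rn == 2:
                    c.w *= rs


def _x_bond_terms(
    col: tuple[int, ...], nxt: tuple[int, ...], spec: GCModelSpec, c: _Counts
) -> None:
    """x-direction bond terms between two adjacent columns, all rows."""
    p = spec.params
    rs = math.sqrt(p.sigma1)
    for r, rn in zip(col, nxt):
        if _occ(r) and _occ(rn):
            c.w *= p.k
            c.k += 1
            if r == 2:
                c.w *= p.s1
                c.s1 += 1
            if (r == 2) != (rn == 2):
                c.w *= rs
        elif _occ(r) != _occ(rn):
            if r == 2 or rn == 2:
                c.w *= rs


def build_gc_transfer_matrix(spec: GCModelSpec) -> GCTransferMatrix:
    """Transfer matrix of the lattice-gas model.

    ``T[u, v]`` is the weight of appending column(v) after column(u), so
    ``trace(T^N)`` is the grand partition function of the periodic strip.
    For variant A with ``nc > 1`` the state is ``(column, occupancy history
    of the previous nc-1 columns)`` and the nucleation weight ``exp(-A)``
    is applied once per row whenever solvent and protein face each other
    across ``nc`` columns with a fully occupied interior.
    """
    p = spec.params
    ra = math.sqrt(p.alpha)
    cols = list(itertools.product(range(3), repeat=spec.Ly))

    def nuc_simple(u_col, v_col, c: _Counts) -> None:
        if spec.variant == "A":
            # nc = 1: per-row solvent<->protein boundary
            for r, rn in zip(u_col, v_col):
                if _occ(r) != _occ(rn):
                    c.w *= ra
                    c.alpha += 0.5
        else:
            occ_u = [_occ(r) for r in u_col]
            occ_v = [_occ(r) for r in v_col]
            if len(set(occ_u)) == 1 and all(a != b for a, b in zip(occ_u, occ_v)):
                c.w *= ra
                c.alpha += 0.5

    def finish(labels, entries):
        n = len(labels)
        T = np.zeros((n, n))
        exps = {name: np.zeros((n, n)) for name in ("z", "s1", "k", "alpha")}
        for iu, iv, c in entries:
            T[iu, iv] = c.w
            exps["z"][iu, iv] = c.z
            exps["s1"][iu, iv] = c.s1
            exps["k"][iu, iv] = c.k
            exps["alpha"][iu, iv] = c.alpha
        if not np.all(np.isfinite(T)):
            raise ValueError("non-finite transfer-matrix entries; check parameters")
        return GCTransferMatrix(T, labels, spec, exps)

    if spec.variant == "B" or spec.nc == 1:
        entries = []
        for iu, u in enumerate(cols):
            for iv, v in enumerate(cols):
                c = _Counts()
                _col_terms(v, spec, c)
                _x_bond_terms(u, v, spec, c)
                nuc_simple(u, v, c)
                entries.append((iu, iv, c))
        return finish(list(cols), entries)

    # variant A, nc > 1: augment with occupancy history
    occ_patterns = list(itertools.product((0, 1), repeat=spec.Ly))
    hists = list(itertools.product(occ_patterns, repeat=spec.nc - 1))
    labels = [(c, h) for c in cols for h in hists]
    index = {lab: i for i, lab in enumerate(labels)}
    entries = []
    for (u_col, u_hist), iu in index.items():
        occ_u = tuple(_occ(r) for r in u_col)
        v_hist = (occ_u,) + u_hist[:-1]
        for v_col in cols:
            iv = index[(v_col, v_hist)]
            c = _Counts()
            _col_terms(v_col, spec, c)
            _x_bond_terms(u_col, v_col, spec, c)
            # nucleation windows ending at the new column: occupancies of
            # columns (i+1-nc .. i+1) are (u_hist[-1], ..., u_hist[0],
            # occ_u, occ_v)
            window = list(reversed(u_hist)) + [occ_u, tuple(_occ(r) for r in v_col)]
            for j in range(spec.Ly):
                rowocc = [wv[j] for wv in window]
                if rowocc[0] != rowocc[-1] and all(rowocc[1:-1]):
                    c.w *= ra
                    c.alpha += 0.5
            entries.append((iu, iv, c))
    return finish(labels, entries)


def gc_partition_periodic(spec: GCModelSpec, N: int) -> float:
    """Grand partition function of a periodic strip of ``N`` columns."""
    if N < spec.nc + 1:
        raise ValueError("periodic strip must be longer than the nucleation window")
    T = build_gc_transfer_matrix(spec).matrix
    return float(np.trace(np.linalg.matrix_power(T, N)))


def _perron(T: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Largest eigenvalue with its right and left eigenvectors."""
    lam, V = np.linalg.eig(T)
    i = int(np.argmax(np.abs(lam)))
    lam1 = float(np.real(lam[i]))
    v = np.real(V[:, i])
    lamL, U = np.linalg.eig(T.T)
    j = int(np.argmax(np.abs(lamL)))
    u = np.real(U[:, j])
    if u @ v < 0:
        u = -u
    return lam1, u, v


def gc_log_partition_per_site(spec: GCModelSpec) -> float:
    """Grand potential per lattice site, ``ln lambda_1 / Ly``."""
    lam1, _, _ = _perron(build_gc_transfer_matrix(spec).matrix)
    return math.log(lam1) / spec.Ly


@dataclass(frozen=True)
class GCObservables:
    """Per-site grand-canonical averages."""

    occupancy: float  # <N_p> per site
    theta: float  # sheet-propagation segments per site
    gamma: float  # filaments per site (half the aggregate boundaries)
    psi: float  # proteins in filaments per site

    @property
    def sheet_fraction(self) -> float:
        return self.theta / self.occupancy if self.occupancy > 0 else 0.0


def gc_observables(spec: GCModelSpec, N: int | None = None) -> GCObservables:
    """Occupancy, sheet, filament-count and filament-mass averages.

    All are logarithmic derivatives of ``ln Q``: occupancy with respect to
    the fugacity, sheet segments with respect to ``s1 = exp(P1)``,
    filament count with respect to ``alpha = exp(-2A)`` (half the expected
    number of aggregate boundaries), and proteins in filaments as the
    ``k`` derivative plus the filament count.  With ``N`` given they are
    evaluated on the finite periodic strip (per site); otherwise in the
    thermodynamic limit from ``lambda_1``.  Since every matrix entry is a
    monomial in the weights the derivatives are exact:
    ``d ln tr(T^N) / d ln x = N tr((T*E) T^(N-1)) / tr(T^N)`` and
    ``d ln lambda_1 / d ln x = u (T*E) v / (lambda_1 u.v)`` with ``E`` the
    entrywise exponent matrix and ``u, v`` the leading eigenvectors.
    """
    rep = build_gc_transfer_matrix(spec)
    T = rep.matrix

    if N is None:
        lam1, u, v = _perron(T)
        norm = lam1 * (u @ v)

        def dln(name: str) -> float:
            return float(u @ (T * rep.exponents[name]) @ v) / norm

        sites = spec.Ly
    else:
        if N < spec.nc + 1:
            raise ValueError("periodic strip must be longer than the nucleation window")
        Tn1 = np.linalg.matrix_power(T, N - 1)
        Q = float(np.trace(T @ Tn1))

        def dln(name: str) -> float:
            return N * float(np.trace((T * rep.exponents[name]) @ Tn1)) / Q

        sites = spec.Ly * N

    gamma = dln("alpha") / sites
    return GCObservables(
        occupancy=dln("z") / sites,
        theta=dln("s1") / sites,
        gamma=gamma,
        psi=dln("k") / sites + gamma,
    )


@dataclass(frozen=True)
class SolutionLink:
    """Chemical-potential bridge between solution and aggregate phases.

    At phase equilibrium ``mu_PC = mu_ST + mu_SR + RT ln c - mu_PV``:
    the translational+rotational solution free energy plus the
    concentration term, minus the vibrational free energy of proteins in
    the aggregate.  Energies in kcal/mol; ``c`` in units of
    ``standard_state_M`` (default 1 M).  By default ``mu_PV`` is taken as
    three quarters of ``mu_ST + mu_SR``.
    """

    mu_st_sr: float = -29.0
    mu_pv: float | None = None
    temperature: float = 298.15
    standard_state_M: float = 1.0

    @property
    def RT(self) -> float:
        return KCAL_GAS_CONSTANT * self.temperature

    @property
    def mu_pv_value(self) -> float:
        return 0.75 * self.mu_st_sr if self.mu_pv is None else self.mu_pv

    def mu_pc(self, c: float) -> float:
        """Aggregate-contact chemical potential (kcal/mol) at concentration c."""
        if c <= 0:
            raise ValueError("concentration must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        return (
            self.mu_st_sr
            + self.RT * math.log(c / self.standard_state_M)
            - self.mu_pv_value
        )

    def fugacity(self, c: float) -> float:
        """Lattice fugacity ``z = exp(mu_PC / RT)`` at concentration c."""
        return math.exp(self.mu_pc(c) / self.RT)


def mu_pc_from_concentration(
    c: float, link: SolutionLink | None = None
) -> tuple[float, float]:
    """``(mu_PC, z)`` for a solution concentration ``c`` (see SolutionLink)."""
    link = link or SolutionLink()
    return link.mu_pc(c), link.fugacity(c)
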