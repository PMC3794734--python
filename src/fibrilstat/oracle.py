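"""Exhaustive-enumeration reference implementations.

Every partition function in the package can be certified against a direct
sum over all microstates of the corresponding effective Hamiltonian.  The
enumerations here are written term by term from the Hamiltonians — per-site
propagation weights, per-interface initiation weights, per-bond
polymerization weights — and never touch the transfer-matrix code, so they
are an independent ground truth for small lattices.

Sums are accumulated with ``math.fsum`` in a fixed lexicographic
configuration order, so identical inputs give bit-identical results.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterator


from .params import EnergyParams, LatticeSpec

__all__ = ["enumerate_partition", "enumerate_gc_partition"]

_MAX_STATES = 2**24


def _site_alphabet(q: int) -> tuple[int, ...]:
    return (0, 1) if q == 2 else (0, 1, 2)


def _sigma_lookup(spec: LatticeSpec, params: EnergyParams) -> dict[tuple[int, int], float]:
    # two-state: exp(-R1) per interface, so a full ordered segment pays the
    # Zimm-Bragg sigma1 = exp(-2 R1); three-state Potts: full sigma(r, r')
    # per interface, as the Potts Hamiltonian is written
    if spec.q == 2:
        rs = math.sqrt(params.sigma1)
        return {(0, 0): 1.0, (1, 1): 1.0, (0, 1): rs, (1, 0): rs}
    out = {}
    table = {(0, 1): params.sigma1, (0, 2): params.sigma2, (1, 2): params.sigma3}
    for a in range(3):
        for c in range(3):
            if a == c:
                out[(a, c)] = 1.0
            else:
                out[(a, c)] = table[(min(a, c), max(a, c))]
    return out


def _configs(n_sites: int, alphabet: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
    return itertools.product(alphabet, repeat=n_sites)


def enumerate_partition(
    spec: LatticeSpec,
    params: EnergyParams,
    Lx: int | None = None,
    boundary: str | None = None,
) -> tuple[float, dict[str, float]]:
    """Exact partition function and site-count expectations by direct sum.

    A configuration assigns one conformation to each of the
    ``Lx * Ly * Lz`` sites.  Its weight is the product of

    * the propagation weight of every site (1, s1 or s2),
    * ``sigma(r, r')`` for every x-adjacent pair of sites in the same
      filament row,
    * ``b`` for every y-adjacent sheet-sheet pair within a strip layer,
      plus (cube model) one ``b`` per column whose proteins are all sheet,
    * ``k`` per nearest-neighbour protein pair on the lattice.

    Returns ``(Z, expectations)`` where expectations hold the mean number
    of sheet sites, helix sites and (for ``q=2``) ordered segments per
    aggregate.
    """
    Lx = spec.Lx if Lx is None else Lx
    boundary = boundary or spec.boundary
    periodic = boundary == "periodic"
    alphabet = _site_alphabet(spec.q)
    Ly, Lz = spec.Ly, spec.Lz
    spc = Ly * Lz
    n_sites = Lx * spc
    if len(alphabet) ** n_sites > _MAX_STATES:
        raise ValueError("state space too large for enumeration")

    prop = {0: 1.0, 1: params.s1} if spec.q == 2 else {0: 1.0, 1: params.s1, 2: params.s2}
    sig = _sigma_lookup(spec, params)
    sheet = spec.sheet_state
    kpref = params.k ** spec.n_bonds(Lx, periodic=periodic)

    weights: list[float] = []
    n_sheet_w: list[float] = []
    n_helix_w: list[float] = []
    n_seg_w: list[float] = []

    def site(config: tuple[int, ...], x: int, z: int, y: int) -> int:
        # configuration is laid out column-major: column x holds sites
        # [x*spc : (x+1)*spc], protofibril-major within the column
        return config[x * spc + z * Ly + y]

    for config in _configs(n_sites, alphabet):
        if boundary == "coil_only" and any(
            r != 0 for r in config[:spc] + config[-spc:]
        ):
            continue
        if boundary == "sheet_or_coil" and spec.q == 3 and any(
            r == 1 for r in config[:spc] + config[-spc:]
        ):
            continue
        w = 1.0
        for r in config:
            w *= prop[r]
        # x-direction interfaces, per filament row
        x_pairs = range(Lx) if periodic else range(Lx - 1)
        for x in x_pairs:
            x2 = (x + 1) % Lx
            for z in range(Lz):
                for y in range(Ly):
                    w *= sig[(site(config, x2, z, y), site(config, x, z, y))]
        # lateral sheet-sheet bonds within each strip layer
        for x in range(Lx):
            for z in range(Lz):
                for y in range(Ly - 1):
                    if site(config, x, z, y) == sheet and site(config, x, z, y + 1) == sheet:
                        w *= params.b
            if spec.geometry == "cube" and all(
                site(config, x, z, y) == sheet for z in range(Lz) for y in range(Ly)
            ):
                w *= params.b
        weights.append(w)
        ns = sum(1 for r in config if r == sheet)
        n_sheet_w.append(ns * w)
        n_helix_w.append(sum(1 for r in config if r == 1) * w if spec.q == 3 else 0.0)
        if spec.q == 2:
            seg = 0
            for z in range(Lz):
                for y in range(Ly):
                    row = [site(config, x, z, y) for x in range(Lx)]
                    prev = 0 if not periodic else row[-1]
                    for r in row:
                        if r == sheet and prev != sheet:
                            seg += 1
                        prev = r
            n_seg_w.append(seg * w)
        else:
            n_seg_w.append(0.0)

    Z = math.fsum(weights)
    expectations = {
        "n_sheet": math.fsum(n_sheet_w) / Z,
        "n_helix": math.fsum(n_helix_w) / Z,
        "n_segments": math.fsum(n_seg_w) / Z,
    }
    return kpref * Z, expectations


# ---------------------------------------------------------------------------
# grand-canonical enumeration
# ---------------------------------------------------------------------------


def enumerate_gc_partition(
    gc_spec, N: int, periodic: bool = True
) -> tuple[float, dict[str, float]]:
    """Exact grand partition function for a lattice-gas aggregation model.

    ``gc_spec`` is a :class:`fibrilstat.grand.GCModelSpec`.  Sites on an
    ``N x Ly`` periodic lattice hold either a solvent cluster (state 0) or
    a protein in conformation coil (1) or sheet (2); each protein carries
    the fugacity ``z``.  The Boltzmann weight is assembled term by term
    from the lattice-gas Hamiltonian (protein-protein bonds, sheet
    propagation, interfacial penalties at conformation changes and at
    protein-solvent boundaries, lateral sheet links, and the nucleation
    penalty ``A`` at aggregate boundaries).

    Returns ``(Q, expectations)`` with expectations of the protein count
    ``Np``, sheet-propagation bond count ``theta``, filament count
    ``gamma`` (half the nucleation-boundary count) and proteins in
    filaments ``psi`` (pp-bond count plus ``gamma``).
    """
    if gc_spec.q != 2:
        raise NotImplementedError("grand-canonical enumeration supports q=2")
    Ly = gc_spec.Ly
    nc = gc_spec.nc
    p = gc_spec.params
    z = gc_spec.z
    if 3 ** (N * Ly) > _MAX_STATES:
        raise ValueError("state space too large for enumeration")
    if not periodic:
        raise NotImplementedError("grand-canonical lattices are periodic")

    root_sigma1 = math.sqrt(p.sigma1)  # exp(-R1), one interface side
    root_alpha = math.sqrt(p.alpha)  # exp(-A), one nucleation boundary

    def occ(r: int) -> int:
        return 1 if r != 0 else 0

    def is_sheet(r: int) -> bool:
        return r == 2

    weights: list[float] = []
    np_w: list[float] = []
    th_w: list[float] = []
    bd_w: list[float] = []
    pp_w: list[float] = []

    for config in itertools.product((0, 1, 2), repeat=N * Ly):
        def site(i: int, j: int) -> int:
            return config[(i % N) * Ly + j]

        w = 1.0
        n_p = 0
        n_theta = 0.0
        n_bound = 0.0
        n_pp = 0.0
        for i in range(N):
            for j in range(Ly):
                r = site(i, j)
                if occ(r):
                    n_p += 1
                    w *= z
        # x-direction bonds, per row (Eq.-45-type terms)
        for i in range(N):
            for j in range(Ly):
                r, rn = site(i, j), site(i + 1, j)
                if occ(r) and occ(rn):
                    w *= p.k
                    n_pp += 1
                    if is_sheet(r):
                        w *= p.s1
                        n_theta += 1
                    if is_sheet(r) != is_sheet(rn):
                        w *= root_sigma1
                elif occ(r) != occ(rn):
                    # protein-solvent interface: each sheet side pays exp(-R1)
                    if occ(r) and is_sheet(r):
                        w *= root_sigma1
                    if occ(rn) and is_sheet(rn):
                        w *= root_sigma1
        if gc_spec.variant == "A":
            # per-row nucleation window along x: solvent<->protein change
            # across nc columns with all-protein interior
            for i in range(N):
                for j in range(Ly):
                    if occ(site(i, j)) != occ(site(i + nc, j)) and all(
                        occ(site(i + m, j)) for m in range(1, nc)
                    ):
                        w *= root_alpha
                        n_bound += 1
            # lateral sheet-sheet links (F)
            for i in range(N):
                for j in range(Ly - 1):
                    if is_sheet(site(i, j)) and is_sheet(site(i, j + 1)):
                        w *= p.f
        else:  # variant B: full y-direction interactions + column nucleus
            for i in range(N):
                for j in range(Ly - 1):
                    r, rn = site(i, j), site(i, j + 1)
                    if occ(r) and occ(rn):
                        w *= p.k
                        n_pp += 1
                        if is_sheet(r):
                            w *= p.f
                        if is_sheet(r) != is_sheet(rn):
                            w *= root_sigma1
                    elif occ(r) != occ(rn):
                        if occ(r) and is_sheet(r):
                            w *= root_sigma1
                        if occ(rn) and is_sheet(rn):
                            w *= root_sigma1
            for i in range(N):
                col = [occ(site(i, j)) for j in range(Ly)]
                nxt = [occ(site(i + 1, j)) for j in range(Ly)]
                if len(set(col)) == 1 and all(a != b for a, b in zip(col, nxt)):
                    w *= root_alpha
                    n_bound += 1
        weights.append(w)
        np_w.append(n_p * w)
        th_w.append(n_theta * w)
        bd_w.append(n_bound * w)
        pp_w.append(n_pp * w)

    Q = math.fsum(weights)
    gamma = math.fsum(bd_w) / Q / 2.0
    expectations = {
        "Np": math.fsum(np_w) / Q,
        "theta": math.fsum(th_w) / Q,
        "gamma": gamma,
        "psi": math.fsum(pp_w) / Q + gamma,
    }
    return Q, expectations
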