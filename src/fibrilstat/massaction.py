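"""Oosawa-Kasai mass-action model of linear (1D) protein aggregation.

Nucleation is dimer formation with equilibrium constant ``sigma * s``;
each further monomer addition has equilibrium constant ``s``, giving the
k-mer concentration ``n_k = sigma * s**(k-1) * n1**k`` for ``k >= 2``
(the monomer is the reference species, ``n_1 = n1``).  Concentrations are
dimensionless activities relative to a declared standard state (default
1 uM), so ``sigma`` and ``s`` absorb the per-concentration units.

Summing the mass series gives the total protein concentration

    m_tot = n1 * (1 - sigma + sigma / (1 - s*n1)**2),

which converges for ``s * n1 < 1``, is strictly increasing in ``n1`` and
diverges at ``n1 -> 1/s``; inverting it for the monomer concentration at a
given total concentration is therefore always possible.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "MassActionState",
    "kmer_concentration",
    "total_mass",
    "solve_monomer",
    "mass_weighted_mean_size",
]


def kmer_concentration(k: int, n1: float, sigma: float, s: float) -> float:
    """Equilibrium concentration of the k-mer (k=1 returns the monomer)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n1 <= 0:
        raise ValueError("monomer concentration must be positive")
    if k == 1:
        return n1
    return sigma * s ** (k - 1) * n1**k


def total_mass(n1: float, sigma: float, s: float) -> float:
    """Total protein concentration implied by monomer concentration ``n1``."""
    if n1 <= 0:
        raise ValueError("monomer concentration must be positive")
    if sigma == 0.0:
        return n1
    if s * n1 >= 1.0:
        raise ValueError(
            f"mass series diverges: requires s*n1 < 1, got s*n1 = {s * n1:g}"
        )
    return n1 * (1.0 - sigma + sigma / (1.0 - s * n1) ** 2)


def solve_monomer(m_tot: float, sigma: float, s: float) -> float:
    """Monomer concentration at total concentration ``m_tot``.

    ``total_mass`` is strictly increasing on ``(0, 1/s)`` and diverges at
    the upper end, so the root is unique and bracketed.
    """
    if m_tot <= 0:
        raise ValueError("total concentration must be positive")
    if sigma == 0.0 or s == 0.0:
        # no nucleation, or no elongation: the mass series collapses to n1
        return m_tot
    lo = m_tot * 1e-16
    hi = min(m_tot, (1.0 - 1e-14) / s)
    return float(
        brentq(
            lambda x: total_mass(x, sigma, s) - m_tot,
            lo,
            hi,
            xtol=1e-300,
            rtol=8.881784197001252e-16,
            maxiter=300,
        )
    )


def mass_weighted_mean_size(n1: float, sigma: float, s: float) -> float:
    """Mass-weighted mean aggregate size ``sum k^2 n_k / sum k n_k``.

    Closed forms of the convergent series at ``s*n1 < 1``.
    """
    x = s * n1
    if x >= 1.0:
        raise ValueError("requires s*n1 < 1")
    mass = total_mass(n1, sigma, s)
    # sum_{k>=2} k^2 sigma s^(k-1) n1^k = (sigma/s) * (sum k^2 x^k - x)
    k2 = x * (1.0 + x) / (1.0 - x) ** 3
    second = n1 + (sigma / s) * (k2 - x) if s > 0 else n1
    return second / mass


@dataclass(frozen=True)
class MassActionState:
    """Solved mass-action equilibrium at one total concentration."""

    m_tot: float
    sigma: float
    s: float
    n1: float
    standard_state_uM: float = 1.0

    @classmethod
    def solve(
        cls, m_tot: float, sigma: float, s: float, standard_state_uM: float = 1.0
    ) -> "MassActionState":
        return cls(m_tot, sigma, s, solve_monomer(m_tot, sigma, s), standard_state_uM)

    def n_k(self, k: int) -> float:
        return kmer_concentration(k, self.n1, self.sigma, self.s)

    @property
    def monomer_fraction(self) -> float:
        return self.n1 / self.m_tot

    @property
    def mean_size(self) -> float:
        return mass_weighted_mean_size(self.n1, self.sigma, self.s)
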