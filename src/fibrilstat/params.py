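"""Model parameters and lattice geometry.

All free energies are dimensionless (units of RT) and enter the partition
function as Boltzmann weights.  The sign conventions follow the effective
Hamiltonians of generalized Zimm-Bragg / Potts models for protein
aggregation:

* interfacial free energies ``R1, R2, R3`` (helix-coil, sheet-coil,
  helix-sheet) give initiation weights ``sigma_i = exp(-2 R_i)``;
* propagation free energies ``P1, P2`` (helix, sheet) give propagation
  weights ``s_i = exp(P_i)``, measured relative to the coil state (weight 1);
* the polymerization free energy ``K`` gives the weight ``k = exp(K)``
  carried once per nearest-neighbour protein pair on the lattice;
* the inter-filament sheet-sheet binding free energy ``B`` gives
  ``b = exp(B)`` (canonical models), and ``F`` gives ``f = exp(F)``
  (grand-canonical models);
* the nucleation/surface free energy ``A`` gives ``alpha = exp(-2 A)``
  (grand-canonical models).

A weight of 1 (free energy 0) means an interaction is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["EnergyParams", "LatticeSpec", "BOUNDARIES"]

# weight name -> (free-energy field, weight <-> energy mapping)
_WEIGHT_FIELDS = {
    "sigma1": "R1",
    "sigma2": "R2",
    "sigma3": "R3",
    "s1": "P1",
    "s2": "P2",
    "k": "K",
    "b": "B",
    "f": "F",
    "alpha": "A",
}
# weights of the form exp(-2*G)
_HALF_NEG = {"sigma1", "sigma2", "sigma3", "alpha"}


@dataclass(frozen=True)
class EnergyParams:
    """Dimensionless free energies (RT units) of the aggregation models."""

    R1: float = 0.0
    R2: float = 0.0
    R3: float = 0.0
    P1: float = 0.0
    P2: float = 0.0
    K: float = 0.0
    B: float = 0.0
    F: float = 0.0
    A: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "R3", "P1", "P2", "K", "B", "F", "A"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"free energy {name} must be finite, got {v}")

    # -- Boltzmann weights ------------------------------------------------
    @property
    def sigma1(self) -> float:
        return math.exp(-2.0 * self.R1)

    @property
    def sigma2(self) -> float:
        return math.exp(-2.0 * self.R2)

    @property
    def sigma3(self) -> float:
        return math.exp(-2.0 * self.R3)

    @property
    def s1(self) -> float:
        return math.exp(self.P1)

    @property
    def s2(self) -> float:
        return math.exp(self.P2)

    @property
    def k(self) -> float:
        return math.exp(self.K)

    @property
    def b(self) -> float:
        return math.exp(self.B)

    @property
    def f(self) -> float:
        return math.exp(self.F)

    @property
    def alpha(self) -> float:
        return math.exp(-2.0 * self.A)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_weights(cls, **weights: float) -> "EnergyParams":
        """Build from Boltzmann weights (``sigma1=..., s1=..., k=...``)."""
        energies = {}
        for name, w in weights.items():
            if name not in _WEIGHT_FIELDS:
                raise KeyError(f"unknown weight {name!r}")
            if not (w > 0.0 and math.isfinite(w)):
                raise ValueError(f"weight {name} must be positive and finite, got {w}")
            g = -0.5 * math.log(w) if name in _HALF_NEG else math.log(w)
            energies[_WEIGHT_FIELDS[name]] = g
        return cls(**energies)

    @classmethod
    def two_state(
        cls,
        P: float,
        R: float,
        K: float = 0.0,
        B: float = 0.0,
        A: float = 0.0,
        F: float = 0.0,
    ) -> "EnergyParams":
        """Parameters of a two-state (ordered/coil) model.

        Two-state sheet-coil and helix-coil models have a single propagation
        free energy and a single interfacial free energy; following the
        aggregation-model convention they are stored in the ``P1``/``R1``
        slots regardless of whether the ordered conformation is a sheet or a
        helix (published fits quote them variously as ``P1``/``P2`` and
        ``R2``; in a two-state model they are the same parameter).
        """
        return cls(P1=P, R1=R, K=K, B=B, A=A, F=F)

    @classmethod
    def from_file(cls, path) -> "EnergyParams":
        """Load free energies (RT units) from a YAML or JSON mapping.

        Recognized keys are the free-energy fields (R1..R3, P1, P2, K, B,
        F, A); unknown keys raise.  kcal/mol inputs can be declared with
        ``units: kcal/mol`` plus ``temperature_K`` (default 298.15) and are
        converted to RT units on load.
        """
        import yaml

        # YAML is a superset of JSON, so one loader covers both formats
        data = yaml.safe_load(open(path).read())
        if not isinstance(data, dict):
            raise ValueError("parameter file must hold a mapping")
        units = data.pop("units", "RT")
        temp = float(data.pop("temperature_K", 298.15))
        fields = set(_WEIGHT_FIELDS.values())
        unknown = set(data) - fields
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        vals = {k: float(v) for k, v in data.items()}
        if units == "kcal/mol":
            rt = 1.98720425864083e-3 * temp
            vals = {k: v / rt for k, v in vals.items()}
        elif units != "RT":
            raise ValueError("units must be 'RT' or 'kcal/mol'")
        return cls(**vals)

    def with_weight(self, name: str, value: float) -> "EnergyParams":
        """Return a copy with one Boltzmann weight replaced."""
        if name not in _WEIGHT_FIELDS:
            raise KeyError(f"unknown weight {name!r}")
        if not (value > 0.0 and math.isfinite(value)):
            raise ValueError(f"weight {name} must be positive and finite, got {value}")
        g = -0.5 * math.log(value) if name in _HALF_NEG else math.log(value)
        return replace(self, **{_WEIGHT_FIELDS[name]: g})

    def weight(self, name: str) -> float:
        if name not in _WEIGHT_FIELDS:
            raise KeyError(f"unknown weight {name!r}")
        return getattr(self, name)


BOUNDARIES = ("free", "coil_only", "sheet_or_coil", "periodic")

_GEOMETRIES = ("filament", "strip", "cube")


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of a (quasi-)1D aggregate lattice.

    The aggregate propagates along x (``Lx`` columns).  A column holds
    ``Ly * Lz`` proteins: ``Ly`` filaments per protofibril and ``Lz``
    stacked protofibrils.  ``q`` counts protein conformations: 2 for
    two-state (coil + ordered) models, 3 for helix-sheet-coil Potts models.
    ``nc`` is the nucleus column count (used by grand-canonical models).

    Internal state labels: 0 = coil; for q=2 state 1 is the ordered
    (sheet-like) conformation; for q=3 state 1 is helix, state 2 is sheet.
    """

    geometry: str = "filament"
    Lx: int = 1
    Ly: int = 1
    Lz: int = 1
    q: int = 2
    nc: int = 1
    boundary: str = "free"

    def __post_init__(self) -> None:
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {_GEOMETRIES}")
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}")
        if self.q not in (2, 3):
            raise ValueError("q must be 2 or 3")
        if self.Lx < 1 or self.Ly < 1 or self.Lz < 1 or self.nc < 1:
            raise ValueError("Lx, Ly, Lz, nc must all be >= 1")
        if self.geometry == "filament" and (self.Ly != 1 or self.Lz != 1):
            raise ValueError("filament requires Ly = Lz = 1")
        if self.geometry == "strip" and self.Lz != 1:
            raise ValueError("strip requires Lz = 1")
        if self.geometry == "cube" and (self.Ly != 2 or self.Lz != 2):
            raise ValueError("cube model is defined for two stacked Ly=2 strips")

    @property
    def sites_per_column(self) -> int:
        return self.Ly * self.Lz

    @property
    def n_sites(self) -> int:
        return self.Lx * self.Ly * self.Lz

    @property
    def sheet_state(self) -> int:
        """Label of the sheet(-like) conformation."""
        return 1 if self.q == 2 else 2

    def n_bonds(self, Lx: int | None = None, periodic: bool = False) -> int:
        """Number of nearest-neighbour protein pairs on the lattice.

        Every such pair carries the polymerization weight ``k`` exactly once.
        """
        Lx = self.Lx if Lx is None else Lx
        nx = Lx if periodic else Lx - 1
        return (
            self.Ly * self.Lz * nx
            + (self.Ly - 1) * self.Lz * Lx
            + (self.Lz - 1) * self.Ly * Lx
        )
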