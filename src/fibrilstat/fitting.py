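"""Fitting model observables to concentration-series data.

The measurable outputs of the equilibrium aggregation models are curves
against total protein concentration: the aggregate sheet fraction
(CD-like data) and the mean fibril length (AFM-like data), or the
grand-canonical sheet fraction ``<theta>/<N_p>``.  This module provides

* a synthetic-curve generator that evaluates the exact model observable
  and adds independent Gaussian noise (for parameter-recovery studies),
* model classes in the statsmodels mould: a model object is built from
  data plus a model configuration, and ``fit()`` returns a results object
  carrying estimates, standard errors, diagnostics and a ``summary()``
  table.

Free parameters are dimensionless free energies (RT units) named by their
:class:`~fibrilstat.params.EnergyParams` fields; parameters can be tied
(e.g. ``K`` equal to ``P1``) and bounded.  The loss is unweighted squared
residuals unless per-point standard errors are supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .ensemble import EnsembleCalculator, SpeciesEnsemble
from .grand import GCModelSpec, SolutionLink, gc_observables
from .params import EnergyParams

__all__ = [
    "CurveDataset",
    "FitResult",
    "FibrilCurveModel",
    "GrandCurveModel",
    "generate_synthetic_curve",
]

_ENERGY_FIELDS = tuple(f.name for f in dc_fields(EnergyParams))

OBSERVABLE_KINDS = ("sheet_fraction", "mean_length")


@dataclass
class CurveDataset:
    """A concentration-vs-observable dataset.

    ``data`` holds columns ``conc_uM``, ``value`` and optionally ``se``;
    ``kind`` names the observable.  ``provenance`` records either the file
    the data came from or the seed and generating parameters of a
    synthetic curve.
    """

    data: pd.DataFrame
    kind: str = "sheet_fraction"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in OBSERVABLE_KINDS:
            raise ValueError(f"kind must be one of {OBSERVABLE_KINDS}")
        d = self.data
        if not {"conc_uM", "value"} <= set(d.columns):
            raise ValueError("dataset needs 'conc_uM' and 'value' columns")
        conc = d["conc_uM"].to_numpy(dtype=float)
        if np.any(conc <= 0) or np.any(np.diff(conc) < 0):
            raise ValueError("concentrations must be positive and sorted")
        v = d["value"].to_numpy(dtype=float)
        if self.kind == "sheet_fraction" and (v.min() < 0 or v.max() > 1):
            raise ValueError("sheet fractions must lie in [0, 1]")
        if self.kind == "mean_length" and v.min() < 1:
            raise ValueError("mean lengths must be >= 1")

    @property
    def conc(self) -> np.ndarray:
        return self.data["conc_uM"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)

    @property
    def se(self) -> np.ndarray | None:
        if "se" in self.data.columns and self.data["se"].notna().all():
            return self.data["se"].to_numpy(dtype=float)
        return None

    @classmethod
    def from_csv(cls, path, kind: str = "sheet_fraction") -> "CurveDataset":
        return cls(pd.read_csv(path), kind, provenance={"path": str(path)})


# ---------------------------------------------------------------------------
# model curve evaluation
# ---------------------------------------------------------------------------


def _ensemble_curve(
    ensemble: SpeciesEnsemble,
    params: EnergyParams,
    conc_uM: np.ndarray,
    kind: str,
    species_index: int = -1,
    s_step: float = 1e-5,
) -> np.ndarray:
    """Exact model observable at each total concentration (vectorized).

    Concentrations are converted to standard-state activities, the mass
    balance is solved for the fugacity, and the observable follows from
    the species sums; the sheet fraction uses a centered difference in
    ``ln s`` at fixed fugacity.
    """
    phi = np.asarray(conc_uM, dtype=float) / ensemble.standard_state_uM
    calc = EnsembleCalculator(ensemble, params)
    z = calc.solve_z(phi)
    if kind == "mean_length":
        return calc.sums[species_index].mean_columns(z)
    weight = "s1" if ensemble.species[0].q == 2 else "s2"
    w0 = params.weight(weight)
    up = EnsembleCalculator(ensemble, params.with_weight(weight, w0 * math.exp(s_step)))
    dn = EnsembleCalculator(ensemble, params.with_weight(weight, w0 * math.exp(-s_step)))
    rho, phi_tot = calc.rho_phi(z)
    dln = (np.log(up.rho_phi(z)[0]) - np.log(dn.rho_phi(z)[0])) / (2.0 * s_step)
    return rho * dln / phi_tot


def _gc_curve(
    spec: GCModelSpec, link: SolutionLink, conc_uM: np.ndarray
) -> np.ndarray:
    """Grand-canonical sheet fraction <theta>/<N_p> at each concentration."""
    out = np.empty(len(conc_uM))
    for i, c in enumerate(np.asarray(conc_uM, dtype=float)):
        z = link.fugacity(c * 1e-6 * link.standard_state_M)  # uM -> M
        out[i] = gc_observables(spec.with_z(z)).sheet_fraction
    return out


def generate_synthetic_curve(
    true_params: EnergyParams,
    model_spec: SpeciesEnsemble | GCModelSpec,
    concentrations_uM: Sequence[float],
    noise_sd: float,
    seed: int,
    kind: str = "sheet_fraction",
    species_index: int = -1,
    link: SolutionLink | None = None,
) -> CurveDataset:
    """Evaluate the exact model curve and add independent Gaussian noise.

    Sheet fractions are clipped to [0, 1] and mean lengths to >= 1 after
    adding noise.  The generating parameters and seed are recorded in the
    dataset's provenance so recovery tests can compare against the truth.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    conc = np.asarray(sorted(float(c) for c in concentrations_uM))
    if isinstance(model_spec, SpeciesEnsemble):
        exact = _ensemble_curve(model_spec, true_params, conc, kind, species_index)
    else:
        if kind != "sheet_fraction":
            raise ValueError("grand-canonical curves provide sheet_fraction only")
        exact = _gc_curve(model_spec.with_params(true_params), link or SolutionLink(), conc)
    rng = np.random.default_rng(seed)
    noisy = exact + rng.normal(0.0, noise_sd, size=len(conc)) if noise_sd > 0 else exact.copy()
    if kind == "sheet_fraction":
        noisy = np.clip(noisy, 0.0, 1.0)
    else:
        noisy = np.maximum(noisy, 1.0)
    df = pd.DataFrame({"conc_uM": conc, "value": noisy})
    return CurveDataset(
        df,
        kind,
        provenance={
            "synthetic": True,
            "seed": int(seed),
            "noise_sd": float(noise_sd),
            "true_params": {f: getattr(true_params, f) for f in _ENERGY_FIELDS},
            "exact": exact,
        },
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of a curve fit.

    ``bse`` are Gauss-Newton standard errors from the quadratic
    approximation at the optimum; a parameter whose residual Jacobian
    column is numerically null is reported as ``flat`` (the data do not
    constrain it) with an undefined standard error.
    """

    model: "FibrilCurveModel"
    params: EnergyParams
    values: dict[str, float]
    bse: dict[str, float]
    flat: dict[str, bool]
    rss: float
    nobs: int
    nfev: int
    success: bool
    message: str
    cov: np.ndarray | None

    def predict(self, conc_uM: Sequence[float] | None = None) -> np.ndarray:
        conc = self.model.conc if conc_uM is None else np.asarray(conc_uM, float)
        return self.model.predict(self.params, conc)

    @property
    def residuals(self) -> np.ndarray:
        return self.model.values - self.predict()

    def within(self, truth: dict[str, float], n_se: float = 3.0) -> bool:
        """Are all free parameters within ``n_se`` standard errors of truth?"""
        for name, true_val in truth.items():
            if self.flat.get(name, False):
                return False
            se = self.bse[name]
            if not (abs(self.values[name] - true_val) <= n_se * se):
                return False
        return True

    def plot_fit(self, ax=None, n_curve: int = 120):
        """Data and fitted curve on a log concentration axis (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        conc = self.model.conc
        grid = np.geomspace(conc.min(), conc.max(), n_curve)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.plot(conc, self.model.values, "ko", ms=4, label="data")
        ax.set_xscale("log")
        ax.set_xlabel("total concentration (uM)")
        ax.set_ylabel(self.model.kind.replace("_", " "))
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit  ({self.model.kind})",
            f"  observations: {self.nobs}   RSS: {self.rss:.6g}   "
            f"model evaluations: {self.nfev}",
            f"  converged: {self.success}  ({self.message})",
            "  parameter    estimate      std err",
        ]
        for name in self.model.free:
            se = "flat" if self.flat[name] else f"{self.bse[name]:12.4g}"
            lines.append(f"  {name:<10} {self.values[name]:12.6g} {se:>12}")
        for tgt, src in self.model.ties.items():
            lines.append(f"  {tgt:<10} tied to {src}")
        return "\n".join(lines)


class ConcentrationCurveModel:
    """Shared machinery: free-energy parameter vector, bounds, least squares.

    Subclasses implement :meth:`predict` (the exact model curve at a
    parameter set).  Parameters fixed at their ``params0`` values are
    simply left out of ``free``; ``ties`` keeps one field equal to another
    throughout the fit (e.g. ``{"K": "P1"}``).
    """

    _DEFAULT_BOUNDS = (-8.0, 12.0)

    def __init__(
        self,
        dataset: CurveDataset,
        params0: EnergyParams,
        free: Sequence[str] = ("P1", "B", "R1"),
        ties: dict[str, str] | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
    ):
        self.dataset = dataset
        self.kind = dataset.kind
        self.conc = dataset.conc
        self.values = dataset.values
        self.se = dataset.se
        self.params0 = params0
        self.free = tuple(free)
        self.ties = dict(ties or {})
        for name in self.free + tuple(self.ties) + tuple(self.ties.values()):
            if name not in _ENERGY_FIELDS:
                raise KeyError(f"unknown free-energy field {name!r}")
        self.bounds = {n: (bounds or {}).get(n, self._DEFAULT_BOUNDS) for n in self.free}
        if len(self.conc) == 0:
            raise ValueError("dataset is empty")

    # -- parameter plumbing ------------------------------------------------
    def _to_params(self, x: np.ndarray) -> EnergyParams:
        upd = dict(zip(self.free, map(float, x)))
        p = replace(self.params0, **upd)
        if self.ties:
            p = replace(p, **{t: getattr(p, s) for t, s in self.ties.items()})
        return p

    def start_vector(self) -> np.ndarray:
        return np.array([getattr(self.params0, n) for n in self.free], float)

    # -- evaluation --------------------------------------------------------
    def predict(self, params: EnergyParams, conc_uM: np.ndarray | None = None) -> np.ndarray:
        raise NotImplementedError

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        try:
            pred = self.predict(self._to_params(x))
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return np.full(len(self.values), 1e6)
        r = pred - self.values
        if self.se is not None:
            r = r / self.se
        return r

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        n_restarts: int = 1,
        jitter: float = 0.2,
        seed: int | None = None,
        max_nfev: int = 400,
        diff_step: float = 1e-5,
    ) -> FitResult:
        """Bounded least squares, best of ``n_restarts`` jittered starts.

        The first start is ``params0`` itself; further starts multiply the
        start vector by ``1 + U(-jitter, jitter)`` componentwise (seeded).
        A failed convergence is reported through ``success``/``message``,
        not raised.
        """
        lo = np.array([self.bounds[n][0] for n in self.free])
        hi = np.array([self.bounds[n][1] for n in self.free])
        x0 = np.clip(self.start_vector(), lo, hi)
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(np.clip(x0 * (1 + rng.uniform(-jitter, jitter, len(x0))), lo, hi))
        best = None
        nfev = 0
        for s in starts:
            res = least_squares(
                self._residuals, s, bounds=(lo, hi), method="trf",
                diff_step=diff_step, max_nfev=max_nfev,
            )
            nfev += res.nfev
            if best is None or res.cost < best.cost:
                best = res
        return self._package(best, nfev)

    def _package(self, res, nfev: int) -> FitResult:
        x = res.x
        p = len(x)
        n = len(self.values)
        rss = float(2.0 * res.cost)
        J = res.jac
        colnorm = np.linalg.norm(J, axis=0)
        flat = {name: bool(cn < 1e-8) for name, cn in zip(self.free, colnorm)}
        bse = {}
        cov = None
        good = ~np.array([flat[nm] for nm in self.free])
        if good.any() and n > p:
            Jg = J[:, good]
            try:
                cov_g = np.linalg.inv(Jg.T @ Jg) * (rss / max(n - p, 1))
                cov = np.full((p, p), np.nan)
                idx = np.flatnonzero(good)
                for a, ia in enumerate(idx):
                    for b, ib in enumerate(idx):
                        cov[ia, ib] = cov_g[a, b]
                for nm, ig in zip(self.free, range(p)):
                    bse[nm] = float(np.sqrt(cov[ig, ig])) if good[ig] else float("nan")
            except np.linalg.LinAlgError:
                bse = {nm: float("nan") for nm in self.free}
        else:
            bse = {nm: float("nan") for nm in self.free}
        return FitResult(
            model=self,
            params=self._to_params(x),
            values=dict(zip(self.free, map(float, x))),
            bse=bse,
            flat=flat,
            rss=rss,
            nobs=n,
            nfev=nfev,
            success=bool(res.success),
            message=str(res.message),
            cov=cov,
        )


class FibrilCurveModel(ConcentrationCurveModel):
    """Canonical-ensemble observable curve fitted to concentration data.

    The observable is the dataset's ``kind``: the mass-weighted sheet
    fraction of all aggregates, or the mean length (columns along the
    growth axis) of the species selected by ``species_index``.
    """

    def __init__(
        self,
        dataset: CurveDataset,
        ensemble: SpeciesEnsemble,
        params0: EnergyParams,
        free: Sequence[str] = ("P1", "B", "R1"),
        species_index: int = -1,
        **kwargs,
    ):
        self.ensemble = ensemble
        self.species_index = species_index
        super().__init__(dataset, params0, free=free, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, ensemble: SpeciesEnsemble, params0: EnergyParams,
        kind: str = "sheet_fraction", **kwargs
    ) -> "FibrilCurveModel":
        return cls(CurveDataset(df, kind), ensemble, params0, **kwargs)

    def predict(self, params: EnergyParams, conc_uM: np.ndarray | None = None) -> np.ndarray:
        conc = self.conc if conc_uM is None else np.asarray(conc_uM, float)
        return _ensemble_curve(self.ensemble, params, conc, self.kind, self.species_index)


class GrandCurveModel(ConcentrationCurveModel):
    """Grand-canonical sheet fraction <theta>/<N_p> fitted to CD-like data.

    Free energies remain in RT units; the solution link converts the
    concentration axis (uM) to the lattice fugacity.
    """

    def __init__(
        self,
        dataset: CurveDataset,
        gc_spec: GCModelSpec,
        params0: EnergyParams,
        free: Sequence[str] = ("P1", "K", "R1", "F", "A"),
        link: SolutionLink | None = None,
        **kwargs,
    ):
        if dataset.kind != "sheet_fraction":
            raise ValueError("grand-canonical fits use sheet_fraction data")
        self.gc_spec = gc_spec
        self.link = link or SolutionLink()
        super().__init__(dataset, params0, free=free, **kwargs)

    def predict(self, params: EnergyParams, conc_uM: np.ndarray | None = None) -> np.ndarray:
        conc = self.conc if conc_uM is None else np.asarray(conc_uM, float)
        return _gc_curve(self.gc_spec.with_params(params), self.link, conc)
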