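"""Dilute multi-species equilibrium: species sums, mass balance, observables."""

import math

import numpy as np
import pytest

from fibrilstat import (
    EnergyParams,
    EnsembleCalculator,
    Species,
    SpeciesEnsemble,
    ensemble_sums,
    enumerate_partition,
    half_rise_concentration,
    mass_fraction_curve,
    mean_length,
    sheet_fraction,
    solve_fugacity,
    species_density,
)
from conftest import draw_params

TOY = SpeciesEnsemble((Species("filament"),))  # all weights 1 by default


def test_species_density_examples():
    sp = Species("filament")
    assert species_density(sp, 3, 0.0, EnergyParams()) == 0.0
    # unit weights: Z(Lx) = 2^Lx, so rho = 8 * 0.1^3
    assert species_density(sp, 3, 0.1, EnergyParams()) == pytest.approx(8e-3)
    with pytest.raises(ValueError):
        species_density(Species("filament", Lx_min=2), 1, 0.1, EnergyParams())


def test_species_density_matches_enumeration(rng):
    for _ in range(3):
        p = draw_params(rng)
        for sp in (Species("filament"), Species("strip", Ly=2)):
            for Lx in (1, 3, 6):
                Zo, _ = enumerate_partition(sp.lattice(Lx), p, boundary="free")
                z = 0.07
                got = species_density(sp, Lx, z, p)
                assert got == pytest.approx(Zo * z ** (Lx * sp.mass_per_column), rel=1e-10)


def test_toy_filament_geometric_series():
    """Unit weights: rho = 2z/(1-2z) and phi = 2z/(1-2z)^2 exactly."""
    rho, phi = ensemble_sums(0.25, TOY, EnergyParams())
    assert rho == pytest.approx(1.0, rel=1e-10)
    assert phi == pytest.approx(2.0, rel=1e-10)


def test_ensemble_sums_leading_order_and_domain():
    calc = EnsembleCalculator(TOY, EnergyParams())
    z = 1e-8
    rho, phi = calc.rho_phi(z)
    assert rho == pytest.approx(2 * z, rel=1e-6)  # two single-column states
    with pytest.raises(ValueError, match="convergence"):
        ensemble_sums(0.51, TOY, EnergyParams())


def test_dual_route_species_sums_agree(rng):
    """Closed-form spectral sums vs adaptive direct summation, 1e-8."""
    for _ in range(3):
        p = draw_params(rng)
        ens = SpeciesEnsemble.abeta40()
        calc = EnsembleCalculator(ens, p)
        z = 0.5 * calc.z_max
        rho, phi = ensemble_sums(z, ens, p, rtol=1e-8)
        assert rho > 0 and phi > rho


def test_solve_fugacity_round_trip_and_monomer_limit(rng):
    state = solve_fugacity(2.0, TOY, EnergyParams())
    assert state.z == pytest.approx(0.25, rel=1e-9)
    for phi_t in (1e-4, 0.03, 1.7, 40.0):
        p = draw_params(rng)
        ens = SpeciesEnsemble.abeta40()
        st = solve_fugacity(phi_t, ens, p)
        assert st.phi == pytest.approx(phi_t, rel=1e-9)
        assert sum(st.phi_by_species.values()) == pytest.approx(phi_t, rel=1e-9)
        assert 0.0 <= st.eta <= 1.0


def test_sheet_fraction_symmetric_point_and_saturation():
    # coil/sheet exchange symmetry: all couplings off, s = 1 -> 1/2
    assert sheet_fraction(0.2, TOY, EnergyParams()) == pytest.approx(0.5, rel=1e-7)
    # strong propagation saturates toward all-sheet
    strong = EnergyParams(P1=12.0)
    ens = SpeciesEnsemble((Species("filament"),))
    calc = EnsembleCalculator(ens, strong)
    assert sheet_fraction(0.5 * calc.z_max, ens, strong) > 0.99


def test_sheet_fraction_matches_enumeration_truncated(rng):
    """Mass-weighted sheet fraction equals the per-configuration average
    sum_config (n_sheet) * w * z^L / sum L w z^L summed over species and
    sizes (tail negligible at small fugacity)."""
    p = EnergyParams(R1=0.4, P1=0.3, K=-0.2, B=0.25)
    ens = SpeciesEnsemble((Species("filament"), Species("strip", Ly=2)))
    calc = EnsembleCalculator(ens, p)
    z = 0.02 * calc.z_max
    num = den = 0.0
    for sp in ens.species:
        ell = sp.mass_per_column
        for Lx in range(1, 7):
            Z, expect = enumerate_partition(sp.lattice(Lx), p, boundary="free")
            w = Z * z ** (ell * Lx)
            num += expect["n_sheet"] * w
            den += ell * Lx * w
    assert sheet_fraction(z, ens, p) == pytest.approx(num / den, rel=1e-8)


def test_mean_length_geometric_and_monotone():
    obs = mean_length(0.25, TOY, EnergyParams())
    assert obs.mean_size == pytest.approx(2.0, rel=1e-9)  # 1/(1-2z)
    calc = EnsembleCalculator(TOY, EnergyParams())
    zs = np.linspace(0.01, 0.49, 9) * 1.0
    sizes = [mean_length(z, TOY, EnergyParams()).mean_size for z in zs]
    assert all(a < b for a, b in zip(sizes, sizes[1:]))
    assert mean_length(1e-9, TOY, EnergyParams()).mean_size == pytest.approx(1.0, abs=1e-6)


def test_vanishing_species_leaves_ensemble_continuous():
    """Suppressing one species' weights removes its contribution smoothly."""
    base = SpeciesEnsemble((Species("filament"), Species("strip", Ly=2)))
    p = EnergyParams(P1=0.5, K=0.1)
    only_fil = SpeciesEnsemble((Species("filament"),))
    z = 0.05
    rho2, phi2 = EnsembleCalculator(base, p).rho_phi(z)
    rho1, phi1 = EnsembleCalculator(only_fil, p).rho_phi(z)
    # the strip contribution is the difference; it vanishes as z^2
    assert rho2 - rho1 == pytest.approx(
        EnsembleCalculator(
            SpeciesEnsemble((Species("strip", Ly=2),)), p
        ).rho_phi(z)[0],
        rel=1e-9,
    )
    assert phi2 > phi1


def test_fibril_share_and_sheet_fraction_track_each_other():
    """For the four-strip (alpha-synuclein-like) parameter set the fibril
    mass share and the sheet fraction are both high and nearly flat over
    the experimentally fitted concentration window.

    The sheet fraction plateaus near 0.88 rather than 1: the negative
    interfacial free energy of this parameter set *favors* sheet-coil
    interfaces, so fibrils retain ~12% coil content at equilibrium.  The
    two curves therefore track each other to ~0.15, not arbitrarily
    closely.
    """
    p = EnergyParams.two_state(P=2.7, R=-1.64, K=2.7, B=1.95)
    ens = SpeciesEnsemble.alpha_synuclein()
    calc = EnsembleCalculator(ens, p)
    phi = np.geomspace(10.0, 200.0, 8)
    z = calc.solve_z(phi)
    phis = calc.phi_by_species(z)
    share = phis[:, -1] / phis.sum(axis=1)
    theta = np.array([sheet_fraction(zi, ens, p) for zi in z])
    assert np.all(share > 0.8) and np.all(theta > 0.8)
    assert np.max(np.abs(share - theta)) < 0.2


def test_mass_fraction_curve_sigmoid_and_half_rise():
    p = EnergyParams.two_state(P=2.7, R=-1.64, K=2.7, B=1.95)
    ens = SpeciesEnsemble.alpha_synuclein()
    phi = np.geomspace(1e-6, 10.0, 120)
    frac = mass_fraction_curve(ens, p, phi)
    assert frac[0] < 1e-6 and frac[-1] > 0.99
    assert np.all(np.diff(frac) > -1e-9)  # monotone rise
    c_half = half_rise_concentration(phi, frac)
    assert phi[0] < c_half < phi[-1]
    # consistency: interpolated point sits at half the plateau
    j = np.searchsorted(phi, c_half)
    assert frac[j - 1] <= 0.5 * frac[-1] <= frac[j]
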