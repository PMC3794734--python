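"""Transfer matrices vs closed forms and the enumeration oracle."""

import math

import numpy as np
import pytest

from fibrilstat import (
    EnergyParams,
    LatticeSpec,
    build_transfer_matrix,
    enumerate_partition,
    log_derivative,
    partition_open,
    partition_periodic,
    spectral_decompose,
)
from conftest import draw_params


def test_noninteracting_two_state_matrix():
    """All weights 1: the 2x2 matrix is all ones with eigenvalues {2, 0}."""
    rep = build_transfer_matrix(LatticeSpec("filament"), EnergyParams())
    assert np.allclose(rep.matrix, np.ones((2, 2)))
    lam = np.sort(np.linalg.eigvals(rep.matrix).real)
    assert lam == pytest.approx([0.0, 2.0], abs=1e-12)


def test_three_state_potts_matrix_layout():
    """Rows are (1, s1, s2)-weighted with the pairwise interface weights."""
    p = EnergyParams(R1=0.3, R2=0.5, R3=0.7, P1=0.4, P2=0.9)
    rep = build_transfer_matrix(LatticeSpec("filament", q=3), p)
    s1, s2 = p.s1, p.s2
    o1, o2, o3 = p.sigma1, p.sigma2, p.sigma3
    expected = np.array(
        [
            [1, o1, o2],
            [s1 * o1, s1, s1 * o3],
            [s2 * o2, s2 * o3, s2],
        ]
    )
    assert np.allclose(rep.matrix, expected, rtol=1e-14)


def test_two_state_characteristic_polynomial():
    """trace = 1 + s1, det = s1 (1 - sigma1): one sigma1 per ordered segment."""
    p = EnergyParams.from_weights(sigma1=0.07, s1=2.3)
    rep = build_transfer_matrix(LatticeSpec("filament"), p)
    assert np.trace(rep.matrix) == pytest.approx(1 + 2.3, rel=1e-14)
    assert np.linalg.det(rep.matrix) == pytest.approx(2.3 * (1 - 0.07), rel=1e-12)


def test_strip_factorizes_at_zero_lateral_binding():
    """At B=0 the two-filament strip matrix is the tensor square (entrywise)."""
    p = EnergyParams(R1=0.4, P1=0.8, K=0.3, B=0.0)
    fil = build_transfer_matrix(LatticeSpec("filament"), p).matrix
    strip = build_transfer_matrix(LatticeSpec("strip", Ly=2), p).matrix
    assert np.allclose(strip, np.kron(fil, fil), rtol=1e-13)
    # and the all-sheet diagonal entry picks up exactly b once B != 0
    pb = EnergyParams(R1=0.4, P1=0.8, K=0.3, B=0.9)
    strip_b = build_transfer_matrix(LatticeSpec("strip", Ly=2), pb).matrix
    ratio = strip_b / np.kron(fil, fil)
    assert ratio[-1, :] == pytest.approx(np.full(4, pb.b), rel=1e-13)
    assert np.allclose(ratio[:-1, :], 1.0, rtol=1e-13)


def test_open_partition_trivial_and_zipper_limits():
    p0 = EnergyParams()
    rep = build_transfer_matrix(LatticeSpec("filament"), p0)
    assert partition_open(rep, 3) == pytest.approx(8.0)  # 2^3 unit-weight states
    # sigma1 -> 0 kills every interface: only all-coil and all-sheet survive
    p = EnergyParams.from_weights(sigma1=1e-30, s1=2.0)
    rep = build_transfer_matrix(LatticeSpec("filament"), p)
    assert partition_open(rep, 3) == pytest.approx(1.0 + 8.0, rel=1e-9)


def test_periodic_partition_trivial_and_thermolimit():
    rep = build_transfer_matrix(LatticeSpec("filament"), EnergyParams())
    assert partition_periodic(rep, 4) == pytest.approx(16.0)
    p = EnergyParams.from_weights(sigma1=0.25, s1=2.0)
    rep = build_transfer_matrix(LatticeSpec("filament"), p)
    sd = spectral_decompose(rep)
    lam1 = math.log(sd.lambda1)
    # per-site free energy converges to ln(lambda_1) as the ring grows
    f8 = math.log(partition_periodic(rep, 8)) / 8
    f16 = math.log(partition_periodic(rep, 16)) / 16
    assert abs(f16 - lam1) < abs(f8 - lam1)
    f64 = math.log(partition_periodic(rep, 64)) / 64
    assert f64 == pytest.approx(lam1, abs=1e-10)


@pytest.mark.parametrize(
    "spec",
    [
        LatticeSpec("filament", Lx=6),
        LatticeSpec("filament", Lx=5, q=3),
        LatticeSpec("strip", Lx=4, Ly=2),
        LatticeSpec("strip", Lx=3, Ly=3),
        LatticeSpec("strip", Lx=3, Ly=2, q=3),
        LatticeSpec("cube", Lx=3, Ly=2, Lz=2),
    ],
    ids=lambda s: f"{s.geometry}-q{s.q}-{s.Lx}x{s.Ly}x{s.Lz}",
)
def test_partition_matches_enumeration_all_boundaries(spec, rng):
    """Open/periodic partitions equal the per-site Hamiltonian sums."""
    for _ in range(3):
        p = draw_params(rng, q3=spec.q == 3)
        rep = build_transfer_matrix(spec, p)
        for boundary in ("free", "coil_only", "sheet_or_coil"):
            Zo, _ = enumerate_partition(spec, p, boundary=boundary)
            Zt = partition_open(rep, spec.Lx, boundary)
            assert Zt == pytest.approx(Zo, rel=1e-10)
        Zo, _ = enumerate_partition(spec, p, boundary="periodic")
        assert partition_periodic(rep, spec.Lx) == pytest.approx(Zo, rel=1e-10)


def test_spectral_sum_reproduces_matrix_powers(rng):
    """sum_i c_i lambda_i^(Lx-1) equals the boundary-contracted power."""
    for _ in range(5):
        p = draw_params(rng)
        for spec in (LatticeSpec("filament"), LatticeSpec("strip", Ly=2)):
            rep = build_transfer_matrix(spec, p)
            sd = spectral_decompose(rep)
            assert sd.condition < 1e8
            for Lx in (1, 2, 5, 16):
                direct = partition_open(rep, Lx) / p.k ** spec.n_bonds(Lx)
                assert sd.contracted_power(Lx) == pytest.approx(direct, rel=1e-8)


def test_spectral_closed_form_two_state():
    """lambda_1 = (1 + s + sqrt((s-1)^2 + 4 s sigma)) / 2 for the filament."""
    p = EnergyParams.from_weights(sigma1=0.01, s1=1.5)
    sd = spectral_decompose(build_transfer_matrix(LatticeSpec("filament"), p))
    assert sd.lambda1 == pytest.approx((2.5 + math.sqrt(0.25 + 0.06)) / 2, rel=1e-12)


def test_interface_symmetry_same_spectrum():
    """Moving sigma across the interface leaves the spectrum unchanged."""
    p = EnergyParams(R1=0.6, P1=0.9)
    T = build_transfer_matrix(LatticeSpec("filament"), p).matrix
    rs = math.sqrt(p.sigma1)
    one_sided = np.array([[1.0, 1.0], [p.s1 * p.sigma1, p.s1]])
    assert np.allclose(
        np.sort(np.linalg.eigvals(T).real), np.sort(np.linalg.eigvals(one_sided).real)
    )
    assert T[0, 1] == pytest.approx(rs)


def test_log_derivative_pure_power_and_expectations(rng):
    """d ln(s^N)/d ln s = N; strip s-derivative = oracle mean sheet count."""
    N = 7
    val = log_derivative(lambda p: p.s1**N, "s1", EnergyParams(P1=0.4))
    assert val == pytest.approx(N, rel=1e-9)

    spec = LatticeSpec("strip", Lx=4, Ly=2)
    p = draw_params(rng)
    rep_field = lambda q: partition_open(build_transfer_matrix(spec, q), spec.Lx)
    dln = log_derivative(rep_field, "s1", p)
    _, expect = enumerate_partition(spec, p, boundary="free")
    assert dln == pytest.approx(expect["n_sheet"], rel=1e-6)


def test_nonnegativity_and_positive_leading_eigenvalue(rng):
    for _ in range(5):
        p = draw_params(rng, q3=True)
        for spec in (LatticeSpec("filament", q=3), LatticeSpec("strip", Ly=2)):
            rep = build_transfer_matrix(spec, p)
            assert np.all(rep.matrix >= 0)
            sd = spectral_decompose(rep)
            assert sd.lambda1 > 0
            assert partition_open(rep, 4) > 0
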