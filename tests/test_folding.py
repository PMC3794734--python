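"""Zipper and Zimm-Bragg helix-coil models vs direct sums and closed forms."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrilstat import (
    chain_averages,
    helicity_closed,
    mean_helix_length_closed,
    zb_partition_finite,
    zb_partition_thermolimit,
    zipper_partition,
)
from fibrilstat.folding import zb_lambda1
from fibrilstat.tmcore import log_derivative_scalar


def _zipper_direct(N, sigma, s):
    return 1.0 + sum((N - k + 1) * sigma * s**k for k in range(1, N + 1))


def _zb_enumerate(N, sigma, s):
    """Direct sum over all 2^N chains: each helical run of length m weighs
    sigma * s**m. Returns (Z, <n_helix>, <n_segments>)."""
    Z = nh = nseg = 0.0
    for config in itertools.product((0, 1), repeat=N):
        w = 1.0
        seg = 0
        run = 0
        for r in config:
            if r:
                run += 1
            elif run:
                w *= sigma * s**run
                seg += 1
                run = 0
        if run:
            w *= sigma * s**run
            seg += 1
        Z += w
        nh += sum(config) * w
        nseg += seg * w
    return Z, nh / Z, nseg / Z


@pytest.mark.parametrize(
    "N,sigma,s",
    [(1, 0.3, 1.7), (2, 0.001, 2.0), (5, 0.1, 0.5), (12, 0.02, 1.3), (30, 1.0, 1.0)],
)
def test_zipper_closed_form_equals_direct_sum(N, sigma, s):
    assert zipper_partition(N, sigma, s) == pytest.approx(
        _zipper_direct(N, sigma, s), rel=1e-11
    )


def test_zipper_special_values():
    # N=1: a single residue is coil or one nucleated helical residue
    assert zipper_partition(1, 0.3, 1.7) == pytest.approx(1 + 0.3 * 1.7)
    assert zipper_partition(2, 0.001, 2.0) == pytest.approx(1.008)
    assert zipper_partition(9, 0.0, 3.0) == 1.0  # no nucleation
    # s = 1 exactly: 1 + sigma N(N+1)/2
    assert zipper_partition(40, 0.05, 1.0) == pytest.approx(1 + 0.05 * 40 * 41 / 2)
    # just off s = 1 the stable branch still matches the direct sum
    assert zipper_partition(40, 0.05, 1.0 + 1e-9) == pytest.approx(
        _zipper_direct(40, 0.05, 1.0 + 1e-9), rel=1e-11
    )


def test_zipper_never_exceeds_zimm_bragg():
    """The zipper allows at most one helical stretch, ZB any number."""
    for N, sigma, s in [(4, 0.1, 1.5), (10, 0.01, 2.0), (8, 0.9, 0.8)]:
        assert zipper_partition(N, sigma, s) <= zb_partition_finite(N, sigma, s) + 1e-12


def test_thermolimit_partition_special_cases():
    assert zb_partition_thermolimit(10, 1.0, 1.0) == pytest.approx(2.0**10)
    # sigma = 1: residues decouple, Z = (1+s)^N
    for s in (0.5, 2.0, 7.0):
        assert zb_partition_thermolimit(6, 1.0, s) == pytest.approx((1 + s) ** 6, rel=1e-12)


def test_thermolimit_dominates_finite_chain():
    """The finite-chain ratio approaches lambda_1^N at the spectral rate."""
    sigma, s = 0.02, 1.4
    lam1 = zb_lambda1(sigma, s)
    lam2 = 0.5 * (1 + s - math.sqrt((s - 1) ** 2 + 4 * s * sigma))
    # the boundary factor Z_N / lambda_1^N settles to a constant at the
    # spectral rate (lam2/lam1)^N
    r40 = zb_partition_finite(40, sigma, s) / zb_partition_thermolimit(40, sigma, s)
    r64 = zb_partition_finite(64, sigma, s) / zb_partition_thermolimit(64, sigma, s)
    r96 = zb_partition_finite(96, sigma, s) / zb_partition_thermolimit(96, sigma, s)
    assert abs(r96 - r64) < abs(r64 - r40)
    assert abs(r96 - r64) / r64 < 100 * abs(lam2 / lam1) ** 64


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    sigma=st.floats(min_value=1e-4, max_value=1.0),
    s=st.floats(min_value=0.05, max_value=20.0),
)
def test_helicity_closed_form_bounds_and_symmetry(sigma, s):
    th = helicity_closed(sigma, s)
    assert 0.0 <= th <= 1.0
    assert helicity_closed(sigma, 1.0) == pytest.approx(0.5)
    # monotone nondecreasing in s
    assert helicity_closed(sigma, s * 1.1) >= th - 1e-12


def test_helicity_closed_special_points():
    assert helicity_closed(1.0, 3.0) == pytest.approx(0.75)  # s/(s+1) at sigma=1
    assert helicity_closed(1e-12, 2.0) == pytest.approx(1.0, abs=1e-5)


def test_helicity_is_log_derivative_of_lambda1():
    """theta = d ln(lambda_1)/d ln s: analytic vs numeric to 1e-6."""
    for sigma, s in [(0.01, 1.3), (0.2, 0.7), (1.0, 3.0)]:
        numeric = log_derivative_scalar(lambda x: zb_lambda1(sigma, x), s)
        assert numeric == pytest.approx(helicity_closed(sigma, s), rel=1e-6)


def test_mean_helix_length_closed_special_points():
    assert mean_helix_length_closed(1.0, 1.0) == pytest.approx(2.0)
    assert mean_helix_length_closed(0.01, 1.0) == pytest.approx(11.0)  # 1 + 1/sqrt(sigma)
    assert mean_helix_length_closed(0.3, 1e-9) == pytest.approx(1.0, abs=1e-6)
    # vanishing nucleation with s>1: one giant helix
    assert mean_helix_length_closed(1e-14, 2.0) > 1e5


@pytest.mark.parametrize("N,sigma,s", [(6, 0.05, 1.6), (8, 0.5, 0.9), (7, 1.0, 1.0)])
def test_chain_averages_match_enumeration(N, sigma, s):
    _, nh, nseg = _zb_enumerate(N, sigma, s)
    obs = chain_averages(N, sigma, s)
    assert obs.theta == pytest.approx(nh / N, rel=1e-7)
    assert obs.nu == pytest.approx(nseg, rel=1e-7)
    # identity L*nu = N_H*theta
    assert obs.L * obs.nu == pytest.approx(N * obs.theta, rel=1e-8)


def test_chain_averages_symmetric_point_and_limit():
    assert chain_averages(9, 1.0, 1.0).theta == pytest.approx(0.5, rel=1e-8)
    # long chains converge (like 1/N at small sigma) to the closed form
    closed = helicity_closed(0.001, 1.2)
    errors = [abs(chain_averages(N, 0.001, 1.2).theta - closed) for N in (200, 800, 1600)]
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 0.01 * closed
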