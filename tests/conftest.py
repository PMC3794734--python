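"""Shared fixtures: seeded parameter draws for property-style tests."""

import numpy as np
import pytest

from fibrilstat import EnergyParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def draw_params(rng, q3: bool = False, gc: bool = False) -> EnergyParams:
    """A random but physically sane parameter set (free energies in RT)."""
    kw = dict(
        R1=rng.uniform(-1.5, 1.5),
        P1=rng.uniform(-1.5, 1.5),
        K=rng.uniform(-1.0, 1.0),
        B=rng.uniform(-1.0, 1.5),
    )
    if q3:
        kw.update(
            R2=rng.uniform(-1.5, 1.5),
            R3=rng.uniform(-1.5, 1.5),
            P2=rng.uniform(-1.5, 1.5),
        )
    if gc:
        kw.update(A=rng.uniform(0.0, 1.5), F=rng.uniform(-0.5, 1.5))
    return EnergyParams(**kw)
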