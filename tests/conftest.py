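"""Shared fixtures: small synthetic systems and force fields."""

import numpy as np
import pytest

from poresel.forcefield import default_forcefield
from poresel.frames import Frame
from poresel.synth import SystemSpec, gen_water_box


@pytest.fixture(scope="session")
def small_ff():
    """Force field with desk-scale cutoffs (fits a ~16 Å box)."""
    return default_forcefield(r_on=6.0, r_off=7.5)


@pytest.fixture(scope="session")
def water_box_frame():
    """~137-water periodic box on the jittered lattice."""
    return gen_water_box(SystemSpec(box=(16.0, 16.0, 16.0), density=1.0,
                                    seed=1))


def random_water_frame(rng: np.random.Generator, n: int = 50,
                       edge: float = 14.0) -> Frame:
    """Random (unphysical) water geometry for oracle comparisons: O's
    uniform in the box, H's on random rigid orientations."""
    from poresel.synth import _orient_waters
    sites = rng.uniform(0, edge, size=(n, 3))
    O, H1, H2 = _orient_waters(sites, rng)
    return Frame(box=np.array([edge] * 3), water_O=O, water_H1=H1,
                 water_H2=H2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
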