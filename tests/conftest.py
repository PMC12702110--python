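"""Shared fixtures: generated schemes and phantoms (session-scoped, seeded)."""

import numpy as np
import pytest

from cdtikit import phantom as ph
from cdtikit import schemes as sch


@pytest.fixture(scope="session")
def study_schemes():
    """The six study direction sets, generated once (seed 0)."""
    return sch.study_direction_schemes(seed=0)


@pytest.fixture(scope="session")
def incremental61():
    return sch.generate_incremental_scheme(61, seed=0)


@pytest.fixture(scope="session")
def study_plans(study_schemes):
    return sch.enumerate_study_plans(seed=0, schemes=study_schemes)


@pytest.fixture(scope="session")
def lv_phantom():
    """Default 64-grid phantom (~460 myocardial voxels)."""
    return ph.make_lv_phantom(ph.LVPhantomSpec())


@pytest.fixture(scope="session")
def small_phantom():
    """Scaled-down 32-grid phantom (~116 voxels) for heavier simulations."""
    return ph.make_lv_phantom(
        ph.LVPhantomSpec(grid_size=32, r_endo_mm=5.75, r_epi_mm=14.95)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
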