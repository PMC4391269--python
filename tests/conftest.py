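import numpy as np
import pytest

import rosettesim as rs
from rosettesim.config import PHASES, PartitionSet, PhaseCoefficients, PhaseSchedule
from rosettesim.drivers import OverlapRatioCurve, PhotosynthesisCurve


@pytest.fixture(scope="session")
def col0_config():
    return rs.fixture_config("col0", 1)


@pytest.fixture(scope="session")
def gi2_config():
    return rs.fixture_config("gi2", 1)


@pytest.fixture(scope="session")
def col0_result(col0_config):
    return rs.simulate(col0_config)


@pytest.fixture(scope="session")
def gi2_result(gi2_config):
    return rs.simulate(gi2_config)


def random_config(rng: np.random.Generator) -> rs.ModelConfig:
    """A random but valid model configuration (used for conservation and
    invariance properties)."""
    veg_end = int(rng.integers(40, 75))
    ev_end = 4 + int(round((veg_end - 4) * 2 / 3))
    schedule = PhaseSchedule(
        heterotrophic_days=(1, 4),
        early_vegetative_days=(5, ev_end),
        late_vegetative_days=(ev_end + 1, veg_end),
        reproductive_days=(veg_end + 1, 90),
        photoperiod_h=int(rng.integers(6, 17)),
    )
    phases = {}
    for name in PHASES:
        if name == "germination":
            ls, lt = rng.dirichlet([2, 1])
            phases[name] = PhaseCoefficients(0.0, 0.0, float(ls), float(lt))
        else:
            iota, rho, ls, lt = rng.dirichlet([1, 1, 4, 2])
            phases[name] = PhaseCoefficients(float(iota), float(rho), float(ls), float(lt))
    constants = rs.ModelConstants(
        sigma=float(rng.uniform(0.3, 0.8)),
        rL_maint=float(rng.uniform(0.1, 0.6)),
        exudation=float(rng.uniform(0.0, 5e-3)),
    )
    a0 = rng.uniform(4.0, 8.0)
    photo = PhotosynthesisCurve(
        (float(a0), float(-rng.uniform(0.01, 0.05)), 1e-4, -1e-6),
        das_range=(1.0, 90.0),
    )
    overlap = OverlapRatioCurve(
        a=float(rng.uniform(1.5, 3.5)), b=float(-rng.uniform(0.1, 0.4))
    )
    return rs.ModelConfig(
        schedule=schedule,
        constants=constants,
        partitions=PartitionSet(**phases),
        photosynthesis=photo,
        overlap=overlap,
    )
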