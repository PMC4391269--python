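"""Synthetic study generator.

The original gas-exchange and harvest data behind the model were never
deposited, so the package ships a generator that emulates what the study
measured: a declining cubic photosynthesis curve, a declining power-law
projected-to-total leaf-area ratio, and sparse harvests (4 time points,
n = 10 plants, mean +/- SD) of the logistic-shaped organ trajectories,
sampled from a known ground-truth coefficient set.  Fixtures are
shape-faithful, not value-faithful: they reproduce the qualitative structure
of the measurements, not the study's numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import MeasurementSeries, OBSERVABLES
from .config import PartitionSet, default_schedule, partition_table, ModelConstants
from .core import ModelConfig, simulate
from .drivers import OverlapRatioCurve, PhotosynthesisCurve

__all__ = ["SyntheticStudy", "fixture_drivers", "fixture_config", "generate_measurements"]

# Column keys of the simulated trajectory for each measured observable
_OBSERVABLE_COLUMNS = {
    "leaf_area": "leaf_area",
    "leaf_mass": "leaf_mass",
    "root_mass": "root_mass",
    "stem_mass": "infl_mass",
}

# declining cubic, ~6.8 -> ~3.1 umol m^-2 s^-1 over the life cycle
_PHOTO_CUBIC_COL0 = (7.0, -0.04, 1.0e-4, -1.5e-6)
#: area-based photosynthesis of the large-rosette profile is ~20% lower
_GI2_PHOTO_SCALE = 0.80
# power laws r = a * das^b fitted through (26, 0.95)-(86, 0.62) and, for the
# large-rosette profile with ~8-10% less overlap, (26, 0.955)-(86, 0.65)
_OVERLAP_COL0 = (3.038, -0.3568)
_OVERLAP_GI2 = (2.724, -0.3217)


def fixture_drivers(genotype: str = "col0"):
    """Packaged driver curves for a genotype profile.

    Returns (PhotosynthesisCurve, OverlapRatioCurve).  The "gi2" profile
    scales photosynthesis down 20% and reduces leaf overlap by ~8-10%
    relative to "col0", mirroring the reported contrasts between the two
    lines.
    """
    if genotype == "col0":
        photo = PhotosynthesisCurve(_PHOTO_CUBIC_COL0, das_range=(1.0, 90.0))
        ratio = OverlapRatioCurve(*_OVERLAP_COL0)
    elif genotype == "gi2":
        photo = PhotosynthesisCurve(
            _PHOTO_CUBIC_COL0, das_range=(1.0, 90.0), scale=_GI2_PHOTO_SCALE
        )
        ratio = OverlapRatioCurve(*_OVERLAP_GI2)
    else:
        raise KeyError(f"unknown genotype profile {genotype!r}")
    return photo, ratio


def fixture_config(
    genotype: str = "col0",
    simulation: int = 1,
    constants: ModelConstants | None = None,
) -> ModelConfig:
    """Complete packaged configuration: published constants and coefficient
    set plus the synthetic driver curves for a genotype profile."""
    photo, ratio = fixture_drivers(genotype)
    return ModelConfig(
        schedule=default_schedule(genotype),
        constants=constants or ModelConstants(),
        partitions=partition_table(genotype, simulation),
        photosynthesis=photo,
        overlap=ratio,
    )


@dataclass(frozen=True)
class SyntheticStudy:
    """Recipe for one synthetic growth study.

    A ground-truth coefficient set is simulated and noisy sparse harvests are
    drawn at the harvest days.  Noise is multiplicative (lognormal) by
    default, since organ masses are positive and measurement spread grows
    with the mean; set ``noise="normal"`` for additive Gaussian noise.  The
    reported SD is floored at ``sd_floor`` times the mean so that a noiseless
    study (cv=0) still carries a finite measurement uncertainty.
    """

    truth: PartitionSet = field(default_factory=lambda: partition_table("col0", 1))
    genotype: str = "col0"
    harvest_das: tuple[int, ...] = (26, 44, 66, 86)
    n_replicates: int = 10
    cv: float = 0.10
    noise: str = "lognormal"
    sd_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.sd_floor < 0:
            raise ValueError("cv and sd_floor must be non-negative")
        if self.cv == 0 and self.sd_floor == 0:
            raise ValueError("either cv or sd_floor must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates for an SD")
        if self.noise not in ("lognormal", "normal"):
            raise ValueError("noise must be 'lognormal' or 'normal'")


def generate_measurements(
    study: SyntheticStudy, config: ModelConfig | None = None
) -> dict[str, MeasurementSeries]:
    """Simulate the ground truth and draw sparse noisy harvests.

    Returns one MeasurementSeries per observable (leaf_area, leaf_mass,
    root_mass, stem_mass).  Deterministic for a fixed study seed.
    """
    if config is None:
        config = fixture_config(study.genotype)
    config = config.with_(partitions=study.truth)
    if max(study.harvest_das) > config.schedule.total_days or min(study.harvest_das) < 1:
        raise ValueError("harvest DAS outside the simulated range")
    result = simulate(config)
    rng = np.random.default_rng(study.seed)
    series: dict[str, MeasurementSeries] = {}
    for obs in OBSERVABLES:
        col = _OBSERVABLE_COLUMNS[obs]
        points = []
        for das in study.harvest_das:
            true = float(result.at(das)[col])
            if true <= 0.0:
                # the organ has not emerged yet (e.g. no inflorescence
                # before flowering): nothing to harvest, no point recorded
                continue
            if study.cv > 0:
                if study.noise == "lognormal":
                    sig = np.sqrt(np.log1p(study.cv**2))
                    reps = true * rng.lognormal(-0.5 * sig**2, sig, study.n_replicates)
                else:
                    reps = rng.normal(true, study.cv * true, study.n_replicates)
                mean = float(np.mean(reps))
                sd = float(np.std(reps, ddof=1))
            else:
                mean, sd = true, 0.0
            sd = max(sd, study.sd_floor * mean)
            points.append((das, mean, sd, study.n_replicates))
        if not points:
            raise ValueError(
                f"observable {obs!r} is zero at every harvest; nothing to measure"
            )
        series[obs] = MeasurementSeries(obs, tuple(points))
    return series
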