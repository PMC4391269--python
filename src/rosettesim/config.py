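"""Model configuration: growth-phase schedule, physiological constants and
carbon partition coefficients.

The simulator partitions the net assimilation rate (NAR) of each hour among
four sinks -- inflorescence/stem growth (``iota``), root growth (``rho``),
leaf area growth (``lambda_s``) and leaf thickening (``lambda_t``) -- with a
separate coefficient set per growth phase (germination, early vegetative,
late vegetative, reproductive).  The four coefficients of a phase live on the
unit simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "PHASES",
    "CARBON_FRACTION_DRY_MASS",
    "CARBON_MOLAR_MASS",
    "carbon_concentration",
    "PhaseSchedule",
    "PhaseCoefficients",
    "PartitionSet",
    "ModelConstants",
    "partition_table",
    "default_schedule",
]

PHASES = ("germination", "early_vegetative", "late_vegetative", "reproductive")

#: dry plant tissue is ~45% carbon by mass
CARBON_FRACTION_DRY_MASS = 0.45
#: g per mol of carbon
CARBON_MOLAR_MASS = 12.0


def carbon_concentration(
    carbon_fraction: float = CARBON_FRACTION_DRY_MASS,
    molar_mass: float = CARBON_MOLAR_MASS,
) -> float:
    """Carbon content of dry tissue in umol C per g dry mass.

    With the defaults (45% C at 12 g/mol) this is 37 500 umol g^-1, the
    conversion used between moles of assimilated C and grams of biomass.
    """
    return carbon_fraction / molar_mass * 1e6


@dataclass(frozen=True)
class PhaseSchedule:
    """Partition of the simulated life cycle [1, total_days] into phases.

    Each interval is an inclusive (first, last) pair in days after seeding
    (DAS).  Intervals must be contiguous, non-overlapping and cover the whole
    simulated span.
    """

    heterotrophic_days: tuple[int, int] = (1, 4)
    early_vegetative_days: tuple[int, int] = (5, 45)
    late_vegetative_days: tuple[int, int] = (46, 66)
    reproductive_days: tuple[int, int] = (67, 90)
    photoperiod_h: int = 8
    total_days: int = 90
    step_h: int = 1

    def __post_init__(self) -> None:
        ivals = [
            self.heterotrophic_days,
            self.early_vegetative_days,
            self.late_vegetative_days,
            self.reproductive_days,
        ]
        for lo, hi in ivals:
            if lo > hi:
                raise ValueError(f"empty phase interval {(lo, hi)}")
        if ivals[0][0] != 1 or ivals[-1][1] != self.total_days:
            raise ValueError("phase intervals must cover [1, total_days]")
        for (lo1, hi1), (lo2, hi2) in zip(ivals, ivals[1:]):
            if lo2 != hi1 + 1:
                raise ValueError("phase intervals must be contiguous")
        if not 0 < self.photoperiod_h < 24:
            raise ValueError("photoperiod must lie strictly inside (0, 24) h")
        if self.step_h <= 0 or 24 % self.step_h:
            raise ValueError("step_h must divide 24")

    @property
    def night_h(self) -> int:
        return 24 - self.photoperiod_h

    def phase_of(self, das: int) -> str:
        """Name of the growth phase containing day ``das``."""
        if self.heterotrophic_days[0] <= das <= self.heterotrophic_days[1]:
            return "germination"
        if self.early_vegetative_days[0] <= das <= self.early_vegetative_days[1]:
            return "early_vegetative"
        if self.late_vegetative_days[0] <= das <= self.late_vegetative_days[1]:
            return "late_vegetative"
        if self.reproductive_days[0] <= das <= self.reproductive_days[1]:
            return "reproductive"
        raise ValueError(f"DAS {das} outside simulated range [1, {self.total_days}]")

    def is_heterotrophic(self, das: int) -> bool:
        return self.heterotrophic_days[0] <= das <= self.heterotrophic_days[1]


@dataclass(frozen=True)
class PhaseCoefficients:
    """NAR partition coefficients of one growth phase (fractions, sum = 1)."""

    iota: float
    rho: float
    lambda_s: float
    lambda_t: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.as_tuple()) - 1.0) > 1e-9:
            raise ValueError(
                f"phase coefficients must sum to 1, got {sum(self.as_tuple())!r}"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.iota, self.rho, self.lambda_s, self.lambda_t)

    @property
    def lambda_leaf(self) -> float:
        """Total leaf-growth fraction (area growth + thickening)."""
        return self.lambda_s + self.lambda_t

    @staticmethod
    def normalized(
        iota: float, rho: float, lambda_s: float, lambda_t: float
    ) -> "PhaseCoefficients":
        """Project raw non-negative values onto the simplex."""
        total = iota + rho + lambda_s + lambda_t
        if total <= 0:
            raise ValueError("coefficients must have a positive sum")
        return PhaseCoefficients(
            iota / total, rho / total, lambda_s / total, lambda_t / total
        )


@dataclass(frozen=True)
class PartitionSet:
    """The 16 calibratable partition coefficients (4 per growth phase)."""

    germination: PhaseCoefficients
    early_vegetative: PhaseCoefficients
    late_vegetative: PhaseCoefficients
    reproductive: PhaseCoefficients

    def phase(self, name: str) -> PhaseCoefficients:
        return getattr(self, name)

    def as_vector(self) -> list[float]:
        """Flat 16-vector in phase order, (iota, rho, lambda_s, lambda_t) each."""
        out: list[float] = []
        for name in PHASES:
            out.extend(self.phase(name).as_tuple())
        return out

    @staticmethod
    def from_vector(vec) -> "PartitionSet":
        vals = list(vec)
        if len(vals) != 16:
            raise ValueError("expected 16 coefficients")
        phases = {
            name: PhaseCoefficients(*vals[4 * i : 4 * i + 4])
            for i, name in enumerate(PHASES)
        }
        return PartitionSet(**phases)


# Published per-phase coefficient sets for the two genotypes (two selected
# calibration solutions each).  Order: (iota, rho, lambda_t, lambda_s) as in
# the source table; germination-phase values were not published and default to
# cotyledon-only growth (no roots or inflorescence, 80/20 area/thickening).
_GERMINATION_DEFAULT = (0.0, 0.0, 0.2, 0.8)
_PARTITION_TABLE: dict[tuple[str, int], dict[str, tuple[float, float, float, float]]] = {
    ("col0", 1): {
        "early_vegetative": (0.01, 0.06, 0.18, 0.75),
        "late_vegetative": (0.06, 0.11, 0.13, 0.70),
        "reproductive": (0.34, 0.10, 0.23, 0.32),  # printed row sums to 0.99
    },
    ("gi2", 1): {
        "early_vegetative": (0.00, 0.08, 0.15, 0.77),
        "late_vegetative": (0.02, 0.12, 0.12, 0.74),
        "reproductive": (0.20, 0.14, 0.15, 0.51),
    },
    ("col0", 2): {
        "early_vegetative": (0.00, 0.05, 0.19, 0.76),
        "late_vegetative": (0.02, 0.11, 0.20, 0.67),
        "reproductive": (0.40, 0.10, 0.05, 0.45),
    },
    ("gi2", 2): {
        "early_vegetative": (0.00, 0.06, 0.16, 0.78),
        "late_vegetative": (0.02, 0.11, 0.12, 0.76),  # printed row sums to 1.01
        "reproductive": (0.25, 0.14, 0.07, 0.54),
    },
}


def partition_table(
    genotype: str = "col0", simulation: int = 1, *, raw: bool = False
):
    """Published partition-coefficient fixture for a genotype profile.

    Parameters
    ----------
    genotype : {"col0", "gi2"}
    simulation : {1, 2}
        Which of the two selected calibration solutions to use.
    raw : bool
        If True, return the printed values as a dict of
        ``{phase: (iota, rho, lambda_t, lambda_s)}`` without simplex
        renormalization (two printed rows sum to 0.99/1.01 from rounding).

    Returns
    -------
    PartitionSet (or dict when ``raw``)
    """
    key = (genotype, simulation)
    if key not in _PARTITION_TABLE:
        raise KeyError(f"no packaged coefficients for {key}")
    rows = dict(_PARTITION_TABLE[key])
    rows["germination"] = _GERMINATION_DEFAULT
    if raw:
        return rows
    phases = {}
    for name in PHASES:
        iota, rho, lt, ls = rows[name]
        phases[name] = PhaseCoefficients.normalized(iota, rho, ls, lt)
    return PartitionSet(**phases)


def default_schedule(genotype: str = "col0") -> PhaseSchedule:
    """Phase schedule for a genotype profile (8 h photoperiod, 90 days).

    Flower initiation was observed at 67 DAS in the wild type and 72 DAS in
    the large-rosette mutant; the early vegetative phase is the first 2/3 of
    the vegetative span.
    """
    if genotype == "col0":
        return PhaseSchedule()
    if genotype == "gi2":
        # vegetative 5-71; first 2/3 of the 67-day span ends at DAS 49
        return PhaseSchedule(
            heterotrophic_days=(1, 4),
            early_vegetative_days=(5, 49),
            late_vegetative_days=(50, 71),
            reproductive_days=(72, 90),
        )
    raise KeyError(f"unknown genotype profile {genotype!r}")


@dataclass(frozen=True)
class ModelConstants:
    """Physiological constants of the carbon-balance model.

    Defaults are the published input values: respiration coefficients from
    the crop-physiology literature, a 60% starch set-aside, and seed /
    cotyledon initial conditions for *Arabidopsis* Col-0.

    Units
    -----
    sigma : fraction of daytime fixed C stored as transient starch
    carbon_conc : umol C per g dry biomass (45% C at 12 g/mol)
    rL_maint : leaf maintenance respiration, umol m^-2 s^-1
    ri_maint_coeff, rr_maint_coeff : maintenance respiration per organ dry
        mass, umol g^-1 s^-1 (inflorescence/stem, root)
    gL_growth_coeff, gi_growth_coeff, gr_growth_coeff : growth respiration,
        g C respired per g new biomass (leaf, inflorescence, root)
    exudation : root C exudation, umol plant^-1 h^-1
    shaded_photo_fraction : photosynthesis of overlapped leaves relative to
        exposed leaves
    seed_mobilization_ratio : fraction of the initial seed reserve mobilized
        per day during the heterotrophic phase
    cotyledon_seed_fraction : cotyledon mass as a fraction of seed mass
    initial_leaf_area : m^2 (expanded cotyledons)
    initial_leaf_mass : g (cotyledons, 90% of seed weight)
    """

    sigma: float = 0.6
    carbon_conc: float = field(default_factory=carbon_concentration)
    rL_maint: float = 0.35
    ri_maint_coeff: float = 7.0e-3
    rr_maint_coeff: float = 1.6e-2
    gL_growth_coeff: float = 0.104
    gi_growth_coeff: float = 0.17
    gr_growth_coeff: float = 0.13
    exudation: float = 1.0e-3
    shaded_photo_fraction: float = 0.1
    seed_mobilization_ratio: float = 0.25
    cotyledon_seed_fraction: float = 0.9
    initial_leaf_area: float = 5.0e-6
    initial_leaf_mass: float = 1.8e-5

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name}={v} must be non-negative")
        if not 0.0 <= self.sigma < 1.0:
            raise ValueError("sigma must lie in [0, 1)")
        for name in ("gL_growth_coeff", "gi_growth_coeff", "gr_growth_coeff"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.shaded_photo_fraction <= 1.0:
            raise ValueError("shaded_photo_fraction must lie in [0, 1]")

    @property
    def initial_seed_reserve(self) -> float:
        """Mobilizable seed reserve in g (seed weight; cotyledons are 90%)."""
        if self.cotyledon_seed_fraction <= 0:
            raise ValueError("cotyledon_seed_fraction must be positive")
        return self.initial_leaf_mass / self.cotyledon_seed_fraction

    def with_(self, **kwargs) -> "ModelConstants":
        return replace(self, **kwargs)
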