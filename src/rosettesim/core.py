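"""Hourly whole-plant carbon-balance simulator.

The model follows carbon from seed reserves and photosynthesis into biomass
over a 90-day *Arabidopsis* life cycle at a fixed 1 h timestep.  During the
day a fraction sigma of fixed C is set aside as transient starch; the rest,
minus maintenance respiration and exudation, is the net assimilation rate
(NAR) available for growth.  At night the starch pool is drawn down at a
constant rate and leaf maintenance respiration (already netted out of the
daytime gas-exchange measurement of A) is charged explicitly.  Growth C is
partitioned among inflorescence/stem, roots, leaf area growth and leaf
thickening by per-phase coefficients; a growth-respiration tax (1 - r^g) is
paid on each gram of new tissue.  Leaf area gained per gram of new
area-directed leaf mass equals the current specific leaf area (SLA = s/M_L).

A full carbon ledger (fixed, mobilized, maintenance, growth respiration,
exudation, biomass C, starch, unmet deficit) is maintained every hour and
closes to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ModelConstants, PartitionSet, PhaseCoefficients, PhaseSchedule
from .drivers import OverlapRatioCurve, PhotosynthesisCurve

__all__ = [
    "ModelConfig",
    "PlantState",
    "HourFlux",
    "SimulationResult",
    "effective_photo_area",
    "nar_day",
    "starch_day_total",
    "nar_night",
    "allocate_growth",
    "heterotrophic_step",
    "optimal_sigma",
    "simulate",
]

SECONDS_PER_HOUR = 3600.0

DAILY_COLUMNS = [
    "das",
    "phase",
    "leaf_area",
    "leaf_mass",
    "infl_mass",
    "root_mass",
    "plant_mass",
    "sla",
    "starch_pool",
    "seed_reserve",
    "fixed_C",
    "mobilized_C",
    "maint_resp_C",
    "growth_resp_C",
    "exuded_C",
    "biomass_C",
    "deficit_C",
    "d_fixed_C",
    "d_mobilized_C",
    "d_maint_C",
    "d_growth_resp_C",
    "d_exuded_C",
    "d_deficit_C",
    "d_leaf_area_C",
    "d_leaf_thick_C",
    "d_infl_C",
    "d_root_C",
    "d_starch_in",
    "d_starch_out",
]


@dataclass(frozen=True)
class ModelConfig:
    """Everything one simulation needs: schedule, constants, partition
    coefficients and the two empirical driver curves."""

    schedule: PhaseSchedule
    constants: ModelConstants
    partitions: PartitionSet
    photosynthesis: PhotosynthesisCurve
    overlap: OverlapRatioCurve

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


@dataclass
class PlantState:
    """Simulator state at one hour, with the cumulative carbon ledger.

    Masses in g, areas in m^2, carbon quantities in umol C.
    """

    das: int = 1
    hour: int = 0
    leaf_area: float = 0.0
    leaf_mass: float = 0.0
    infl_mass: float = 0.0
    root_mass: float = 0.0
    starch_pool: float = 0.0
    seed_reserve: float = 0.0
    fixed_C: float = 0.0
    mobilized_C: float = 0.0
    maint_resp_C: float = 0.0
    growth_resp_C: float = 0.0
    exuded_C: float = 0.0
    biomass_C: float = 0.0
    deficit_C: float = 0.0

    @property
    def plant_mass(self) -> float:
        return self.leaf_mass + self.infl_mass + self.root_mass

    @classmethod
    def initial(cls, constants: ModelConstants) -> "PlantState":
        return cls(
            das=1,
            hour=0,
            leaf_area=constants.initial_leaf_area,
            leaf_mass=constants.initial_leaf_mass,
            seed_reserve=constants.initial_seed_reserve,
        )

    def ledger_residual(self) -> float:
        """Relative carbon-conservation residual of the cumulative ledger.

        Sources (fixed + mobilized + unmet deficit) must equal sinks
        (biomass C + maintenance + growth respiration + exudation + residual
        starch).  Initial biomass is not part of the ledger.
        """
        sources = self.fixed_C + self.mobilized_C + self.deficit_C
        sinks = (
            self.biomass_C
            + self.maint_resp_C
            + self.growth_resp_C
            + self.exuded_C
            + self.starch_pool
        )
        scale = max(sources, 1.0)
        return (sources - sinks) / scale


@dataclass(frozen=True)
class HourFlux:
    """Carbon fluxes and growth increments of a single hour."""

    assimilation: float = 0.0  # umol plant^-1 h^-1 (net of leaf respiration)
    starch_made: float = 0.0
    starch_used: float = 0.0
    nar: float = 0.0
    d_area: float = 0.0
    d_s_leaf_mass: float = 0.0
    d_t_leaf_mass: float = 0.0
    d_infl_mass: float = 0.0
    d_root_mass: float = 0.0
    maint_leaf: float = 0.0
    maint_infl: float = 0.0
    maint_root: float = 0.0
    growth_resp: float = 0.0
    exudation: float = 0.0
    deficit: float = 0.0

    @property
    def d_leaf_mass(self) -> float:
        return self.d_s_leaf_mass + self.d_t_leaf_mass


def effective_photo_area(
    s_total: float, r_proj: float, shaded_fraction: float
) -> float:
    """Photosynthetically effective leaf area.

    Exposed (projected) area works at full rate; the overlapped remainder at
    ``shaded_fraction`` of that rate.
    """
    if s_total < 0:
        raise ValueError("leaf area must be non-negative")
    if not 0.0 <= r_proj <= 1.0:
        raise ValueError("projected-to-total ratio must lie in [0, 1]")
    if not 0.0 <= shaded_fraction <= 1.0:
        raise ValueError("shaded fraction must lie in [0, 1]")
    return r_proj * s_total + shaded_fraction * (1.0 - r_proj) * s_total


def nar_day(
    A: float,
    s_eff: float,
    sigma: float,
    M_i: float,
    M_r: float,
    constants: ModelConstants,
) -> float:
    """Daytime NAR, umol C plant^-1 h^-1.

    Whole-plant assimilation minus the starch set-aside, inflorescence and
    root maintenance respiration, and exudation.  Leaf maintenance is already
    netted out of the gas-exchange measurement of A and is not charged here.
    May be negative (maintenance exceeding supply).
    """
    if A < 0:
        raise ValueError("net assimilation A must be non-negative")
    return (
        A * s_eff * (1.0 - sigma) * SECONDS_PER_HOUR
        - constants.ri_maint_coeff * M_i * SECONDS_PER_HOUR
        - constants.rr_maint_coeff * M_r * SECONDS_PER_HOUR
        - constants.exudation
    )


def starch_day_total(A_series, s_eff_series, sigma: float) -> float:
    """Starch accumulated over the light period (umol): sum of A*s_eff*sigma
    over the daylight hours."""
    A = np.asarray(A_series, dtype=float)
    s = np.asarray(s_eff_series, dtype=float)
    if A.size == 0 or A.shape != s.shape:
        raise ValueError("need equal-length, non-empty hourly series")
    return float(np.sum(A * s * sigma * SECONDS_PER_HOUR))


def nar_night(
    starch_pool: float,
    night_h: float,
    state: PlantState,
    constants: ModelConstants,
) -> float:
    """Nighttime NAR, umol C plant^-1 h^-1.

    Constant starch draw (pool / night length) minus maintenance respiration
    of all organs -- leaf maintenance IS charged at night -- and exudation.
    """
    if night_h <= 0:
        raise ValueError("night length must be positive")
    return (
        starch_pool / night_h
        - constants.rL_maint * state.leaf_area * SECONDS_PER_HOUR
        - constants.ri_maint_coeff * state.infl_mass * SECONDS_PER_HOUR
        - constants.rr_maint_coeff * state.root_mass * SECONDS_PER_HOUR
        - constants.exudation
    )


def allocate_growth(
    nar: float,
    coeffs: PhaseCoefficients,
    sla_current: float,
    constants: ModelConstants,
    is_day: bool = True,
) -> HourFlux:
    """Partition one hour's growth C among the four sinks.

    Growth C in grams is max(NAR, 0)/C; each sink keeps (1 - r^g) of its
    share, the rest is growth respiration.  New leaf area is SLA times the
    new area-directed leaf mass.  Negative NAR yields zero increments and the
    shortfall is recorded as a deficit.  The night-time formulation, in which
    the leaf-area share is written as (1 - lambda_t - iota - rho), is
    algebraically identical because the coefficients sum to 1.
    """
    if sla_current <= 0:
        raise ValueError("SLA must be positive")
    if not np.isfinite(nar):
        raise ValueError("NAR must be finite")
    if nar <= 0.0:
        return HourFlux(nar=nar, deficit=-min(nar, 0.0))
    C = constants.carbon_conc
    g = nar / C
    d_infl = g * coeffs.iota * (1.0 - constants.gi_growth_coeff)
    d_root = g * coeffs.rho * (1.0 - constants.gr_growth_coeff)
    d_s = g * coeffs.lambda_s * (1.0 - constants.gL_growth_coeff)
    d_t = g * coeffs.lambda_t * (1.0 - constants.gL_growth_coeff)
    growth_resp = (
        g
        * (
            coeffs.iota * constants.gi_growth_coeff
            + coeffs.rho * constants.gr_growth_coeff
            + coeffs.lambda_leaf * constants.gL_growth_coeff
        )
        * C
    )
    return HourFlux(
        nar=nar,
        d_area=sla_current * d_s,
        d_s_leaf_mass=d_s,
        d_t_leaf_mass=d_t,
        d_infl_mass=d_infl,
        d_root_mass=d_root,
        growth_resp=growth_resp,
    )


def heterotrophic_step(state: PlantState, constants: ModelConstants,
                       coeffs: PhaseCoefficients | None = None,
                       schedule: PhaseSchedule | None = None) -> PlantState:
    """Advance one full heterotrophic day (pre-photosynthetic growth).

    Each day a fixed fraction of the *initial* seed reserve is mobilized
    (linear depletion: zero at the end of the phase).  Mobilized C funds
    cotyledon maintenance first; the remainder grows cotyledon mass and area
    with the germination-phase coefficients, inflorescence and root
    allocation forced to zero.  Runs 24 hourly micro-steps.
    """
    sched = schedule or PhaseSchedule()
    if not sched.is_heterotrophic(state.das):
        raise ValueError(f"DAS {state.das} is not in the heterotrophic phase")
    if coeffs is None:
        coeffs = PhaseCoefficients(0.0, 0.0, 0.8, 0.2)
    lam = coeffs.lambda_s + coeffs.lambda_t
    if lam <= 0:
        raise ValueError("germination coefficients must allocate to leaves")
    # force iota = rho = 0, renormalize the leaf shares
    coeffs = PhaseCoefficients(0.0, 0.0, coeffs.lambda_s / lam, coeffs.lambda_t / lam)

    st = replace(state)
    C = constants.carbon_conc
    mobilize_g_h = constants.seed_mobilization_ratio * constants.initial_seed_reserve / 24.0
    for _ in range(24):
        m_g = min(mobilize_g_h, st.seed_reserve)
        st.seed_reserve -= m_g
        m_C = m_g * C
        st.mobilized_C += m_C
        maint = constants.rL_maint * st.leaf_area * SECONDS_PER_HOUR
        st.maint_resp_C += maint
        nar = m_C - maint
        flux = allocate_growth(nar, coeffs, st.leaf_area / st.leaf_mass, constants)
        st.leaf_mass += flux.d_leaf_mass
        st.leaf_area += flux.d_area
        st.growth_resp_C += flux.growth_resp
        st.biomass_C += flux.d_leaf_mass * C
        st.deficit_C += flux.deficit
    st.das += 1
    return st


def optimal_sigma(A: float, rm_day: float, rm_night: float, P: float) -> float:
    """Starch set-aside fraction equalizing day and night growth rates.

    sigma = (1 - (R^m_D - R^m_N)/A) / (1 + P/(24-P)), clipped to [0, 1].
    With equal day/night maintenance this reduces to (24-P)/24: an 8 h
    photoperiod would optimally store 2/3 of daytime fixed C as starch.
    """
    if A == 0:
        raise ValueError("assimilation A must be non-zero")
    if not 0 < P < 24:
        raise ValueError("photoperiod must lie in (0, 24)")
    sigma = (1.0 - (rm_day - rm_night) / A) / (1.0 + P / (24.0 - P))
    return float(min(max(sigma, 0.0), 1.0))


@dataclass
class SimulationResult:
    """Trajectory of a simulation: per-day summary (and optional per-hour
    table), final state and the configuration that produced them."""

    daily: pd.DataFrame
    final_state: PlantState
    config: ModelConfig
    hourly: pd.DataFrame | None = None

    def ledger_residual(self) -> float:
        return self.final_state.ledger_residual()

    def at(self, das: int) -> pd.Series:
        """End-of-day row for one DAS."""
        row = self.daily.loc[self.daily["das"] == das]
        if row.empty:
            raise KeyError(f"DAS {das} not in trajectory")
        return row.iloc[0]


def simulate(config: ModelConfig, record_hourly: bool = False) -> SimulationResult:
    """Run the hourly carbon-balance model over the configured life cycle.

    Deterministic explicit-Euler integration: drivers and state are evaluated
    at the start of each hour.  Daylight occupies hours [0, P); the starch
    pool accumulated by dusk is drawn at a constant rate over the night and
    empties exactly at dawn.  Returns end-of-day state rows plus per-day flux
    columns used by the partitioning summaries.
    """
    sched = config.schedule
    cons = config.constants
    parts = config.partitions
    photo = config.photosynthesis
    overlap = config.overlap

    # driver domain check up front (fail before any work)
    first_auto = sched.heterotrophic_days[1] + 1
    lo, hi = photo.das_range
    if lo > first_auto or hi < sched.total_days:
        raise ValueError(
            "photosynthesis curve domain does not cover the simulated range"
        )

    P = sched.photoperiod_h
    night_h = sched.night_h
    C = cons.carbon_conc
    rmi = cons.ri_maint_coeff * SECONDS_PER_HOUR
    rmr = cons.rr_maint_coeff * SECONDS_PER_HOUR
    rml = cons.rL_maint * SECONDS_PER_HOUR
    E = cons.exudation
    f_shade = cons.shaded_photo_fraction
    sigma = cons.sigma
    gL, gi, gr = cons.gL_growth_coeff, cons.gi_growth_coeff, cons.gr_growth_coeff

    state = PlantState.initial(cons)
    daily_rows: list[list] = []
    hourly_rows: list[list] = [] if record_hourly else None

    # local mutable copies for the fast loop
    s = state.leaf_area
    ML = state.leaf_mass
    Mi = state.infl_mass
    Mr = state.root_mass
    pool = state.starch_pool
    reserve = state.seed_reserve
    fixed = mobil = maint = gresp = exud = biom = defic = 0.0

    germ = parts.germination
    lam_g = germ.lambda_s + germ.lambda_t
    if lam_g <= 0:
        raise ValueError("germination coefficients must allocate to leaves")
    germ_ls, germ_lt = germ.lambda_s / lam_g, germ.lambda_t / lam_g

    mobilize_g_h = cons.seed_mobilization_ratio * cons.initial_seed_reserve / 24.0

    for das in range(1, sched.total_days + 1):
        phase = sched.phase_of(das)
        coeffs = parts.phase(phase)
        hetero = sched.is_heterotrophic(das)
        d_fixed = d_mobil = d_maint = d_gresp = d_exud = d_defic = 0.0
        d_sC = d_tC = d_iC = d_rC = 0.0
        starch_in = pool
        draw = 0.0
        if not hetero:
            A_das = photo(das)
            r_das = overlap(s if overlap.on_area else das)

        for hour in range(24):
            if hetero:
                m_g = min(mobilize_g_h, reserve)
                reserve -= m_g
                m_C = m_g * C
                mobil += m_C
                d_mobil += m_C
                m_leaf = rml * s
                maint += m_leaf
                d_maint += m_leaf
                nar = m_C - m_leaf
                i_c, r_c, ls, lt = 0.0, 0.0, germ_ls, germ_lt
                ap = 0.0
                made = used = 0.0
            elif hour < P:
                if overlap.on_area:
                    r_das = overlap(s)
                s_eff = r_das * s + f_shade * (1.0 - r_das) * s
                ap = A_das * s_eff * SECONDS_PER_HOUR
                made = ap * sigma
                used = 0.0
                pool += made
                fixed += ap
                d_fixed += ap
                m_h = rmi * Mi + rmr * Mr
                maint += m_h
                d_maint += m_h
                exud += E
                d_exud += E
                nar = ap * (1.0 - sigma) - m_h - E
                i_c, r_c, ls, lt = coeffs.iota, coeffs.rho, coeffs.lambda_s, coeffs.lambda_t
            else:
                if hour == P:
                    draw = pool / night_h
                used = pool if hour == 23 else draw  # exact empty at dawn
                made = 0.0
                pool -= used
                ap = 0.0
                m_h = rml * s + rmi * Mi + rmr * Mr
                maint += m_h
                d_maint += m_h
                exud += E
                d_exud += E
                nar = used - m_h - E
                i_c, r_c, ls, lt = coeffs.iota, coeffs.rho, coeffs.lambda_s, coeffs.lambda_t

            if nar > 0.0:
                g = nar / C
                dMi = g * i_c * (1.0 - gi)
                dMr = g * r_c * (1.0 - gr)
                dsM = g * ls * (1.0 - gL)
                dtM = g * lt * (1.0 - gL)
                dA = (s / ML) * dsM
                grsp = nar - (dMi + dMr + dsM + dtM) * C
                Mi += dMi
                Mr += dMr
                ML += dsM + dtM
                s += dA
                gresp += grsp
                d_gresp += grsp
                dbio = (dMi + dMr + dsM + dtM) * C
                biom += dbio
                d_iC += dMi * C
                d_rC += dMr * C
                d_sC += dsM * C
                d_tC += dtM * C
            else:
                defic += -nar
                d_defic += -nar

            if record_hourly:
                hourly_rows.append(
                    [das, hour, s, ML, Mi, Mr, ML + Mi + Mr, pool, reserve,
                     ap, made, used, nar]
                )

        daily_rows.append(
            [
                das, phase, s, ML, Mi, Mr, ML + Mi + Mr, s / ML, pool, reserve,
                fixed, mobil, maint, gresp, exud, biom, defic,
                d_fixed, d_mobil, d_maint, d_gresp, d_exud, d_defic,
                d_sC, d_tC, d_iC, d_rC, starch_in, pool,
            ]
        )

    daily = pd.DataFrame(daily_rows, columns=DAILY_COLUMNS)
    final = PlantState(
        das=sched.total_days,
        hour=23,
        leaf_area=s,
        leaf_mass=ML,
        infl_mass=Mi,
        root_mass=Mr,
        starch_pool=pool,
        seed_reserve=reserve,
        fixed_C=fixed,
        mobilized_C=mobil,
        maint_resp_C=maint,
        growth_resp_C=gresp,
        exuded_C=exud,
        biomass_C=biom,
        deficit_C=defic,
    )
    hourly = None
    if record_hourly:
        hourly = pd.DataFrame(
            hourly_rows,
            columns=[
                "das", "hour", "leaf_area", "leaf_mass", "infl_mass",
                "root_mass", "plant_mass", "starch_pool", "seed_reserve",
                "assimilation", "starch_made", "starch_used", "nar",
            ],
        )
    return SimulationResult(daily=daily, final_state=final, config=config, hourly=hourly)
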