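import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rosettesim as rs
from rosettesim.config import ModelConstants, PhaseCoefficients
from rosettesim.core import (
    PlantState,
    allocate_growth,
    effective_photo_area,
    heterotrophic_step,
    nar_day,
    nar_night,
    optimal_sigma,
    simulate,
    starch_day_total,
)
from rosettesim.drivers import PhotosynthesisCurve

from conftest import random_config

NO_EXUDATION = ModelConstants(exudation=0.0)


class TestEffectivePhotoArea:
    @pytest.mark.parametrize(
        "s,r,f,expected",
        [
            (0.01, 1.0, 0.1, 0.01),     # no overlap: full area photosynthesizes
            (0.01, 0.8, 0.1, 0.0082),   # shaded 20% works at 10%
            (0.01, 0.0, 0.1, 0.001),    # fully shaded limit
        ],
    )
    def test_examples(self, s, r, f, expected):
        assert effective_photo_area(s, r, f) == pytest.approx(expected)

    def test_never_exceeds_total_area(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s, r, f = rng.uniform(0, 0.1), rng.uniform(0, 1), rng.uniform(0, 1)
            assert effective_photo_area(s, r, f) <= s + 1e-15

    @pytest.mark.parametrize("args", [(-1e-3, 0.5, 0.1), (0.01, 1.2, 0.1), (0.01, 0.5, -0.1)])
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            effective_photo_area(*args)


class TestNarDay:
    def test_example_value(self):
        constants = ModelConstants(exudation=1e-3)
        # 5 umol/m2/s over 82 cm2 effective, 60% to starch, no other organs
        assert nar_day(5.0, 0.0082, 0.6, 0.0, 0.0, constants) == pytest.approx(59.039)

    def test_zero_assimilation_zero_masses(self):
        assert nar_day(0.0, 0.0082, 0.6, 0.0, 0.0, NO_EXUDATION) == 0.0

    def test_all_carbon_to_starch(self):
        assert nar_day(5.0, 0.0082, 1.0, 0.0, 0.0, NO_EXUDATION) == 0.0

    def test_negative_A_rejected(self):
        with pytest.raises(ValueError):
            nar_day(-1.0, 0.01, 0.6, 0.0, 0.0, NO_EXUDATION)


class TestStarchDayTotal:
    def test_constant_light_period(self):
        assert starch_day_total([5.0] * 8, [0.0082] * 8, 0.6) == pytest.approx(708.48)

    def test_no_starch_when_sigma_zero(self):
        assert starch_day_total([5.0] * 8, [0.0082] * 8, 0.0) == 0.0

    def test_single_hour(self):
        assert starch_day_total([1.0], [1.0], 0.5) == pytest.approx(1800.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            starch_day_total([], [], 0.6)


class TestNarNight:
    def test_example_value(self):
        state = PlantState(leaf_area=0.01)
        constants = ModelConstants(exudation=1e-3)
        # 708.48/16 - 0.35*0.01*3600 - 0.001
        assert nar_night(708.48, 16, state, constants) == pytest.approx(31.679)

    def test_zero_everything(self):
        assert nar_night(0.0, 16, PlantState(), NO_EXUDATION) == 0.0

    def test_negative_when_leaf_respiration_dominates(self):
        state = PlantState(leaf_area=1.0)  # huge canopy, small starch pool
        assert nar_night(708.48, 16, state, NO_EXUDATION) < 0

    def test_night_length_validated(self):
        with pytest.raises(ValueError):
            nar_night(100.0, 0, PlantState(), NO_EXUDATION)


class TestAllocateGrowth:
    def test_all_carbon_to_leaf_area(self):
        # 37 500 umol = 1 g of growth C, all to area growth
        coeffs = PhaseCoefficients(0.0, 0.0, 1.0, 0.0)
        flux = allocate_growth(37_500.0, coeffs, 0.02, ModelConstants())
        assert flux.d_leaf_mass == pytest.approx(0.896)
        assert flux.d_area == pytest.approx(0.01792)

    def test_zero_nar_zero_increments(self):
        coeffs = PhaseCoefficients(0.0, 0.0, 1.0, 0.0)
        flux = allocate_growth(0.0, coeffs, 0.02, ModelConstants())
        assert flux.d_leaf_mass == flux.d_area == flux.d_infl_mass == flux.d_root_mass == 0.0

    def test_published_early_vegetative_row(self):
        # wild-type early-vegetative coefficients
        coeffs = PhaseCoefficients(iota=0.01, rho=0.06, lambda_s=0.75, lambda_t=0.18)
        flux = allocate_growth(37_500.0, coeffs, 0.02, ModelConstants())
        assert flux.d_infl_mass == pytest.approx(0.0083)
        assert flux.d_root_mass == pytest.approx(0.0522)
        assert flux.d_leaf_mass == pytest.approx(0.833280)

    def test_negative_nar_clamps_growth_and_logs_deficit(self):
        coeffs = PhaseCoefficients(0.0, 0.0, 1.0, 0.0)
        flux = allocate_growth(-10.0, coeffs, 0.02, ModelConstants())
        assert flux.d_leaf_mass == 0.0 and flux.d_area == 0.0
        assert flux.deficit == pytest.approx(10.0)

    def test_invalid_sla(self):
        with pytest.raises(ValueError):
            allocate_growth(1.0, PhaseCoefficients(0, 0, 1, 0), 0.0, ModelConstants())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        nar=st.floats(1e-3, 1e5),
        sla=st.floats(1e-3, 0.5),
        w=st.tuples(*[st.floats(0.01, 1.0)] * 4),
    )
    def test_area_growth_formulations_agree(self, nar, sla, w):
        """The expanded day form (NAR minus the other sinks' C) and the
        night form with the leaf-area share written as 1 - lt - iota - rho
        both equal the direct coefficient form, and area growth is linear in
        area-directed leaf mass with slope SLA."""
        total = sum(w)
        coeffs = PhaseCoefficients(*(x / total for x in w))
        c = ModelConstants()
        flux = allocate_growth(nar, coeffs, sla, c)
        # subtraction form of the daytime area-growth equation
        expanded = sla * (1.0 - c.gL_growth_coeff) * (
            nar / c.carbon_conc
            - flux.d_t_leaf_mass / (1.0 - c.gL_growth_coeff)
            - flux.d_infl_mass / (1.0 - c.gi_growth_coeff)
            - flux.d_root_mass / (1.0 - c.gr_growth_coeff)
        )
        assert flux.d_area == pytest.approx(expanded, rel=1e-12, abs=1e-300)
        # night form: leaf-area share as the simplex complement
        night_share = 1.0 - coeffs.lambda_t - coeffs.iota - coeffs.rho
        night = sla * (1.0 - c.gL_growth_coeff) * (nar / c.carbon_conc) * night_share
        assert flux.d_area == pytest.approx(night, rel=1e-9)
        # SLA linearity
        if flux.d_s_leaf_mass > 0:
            assert flux.d_area / flux.d_s_leaf_mass == pytest.approx(sla, rel=1e-12)


class TestHeterotrophicPhase:
    def test_one_quarter_of_initial_reserve_mobilized_per_day(self):
        c = ModelConstants()
        state = PlantState.initial(c)
        after = heterotrophic_step(state, c)
        assert after.seed_reserve == pytest.approx(0.75 * c.initial_seed_reserve)
        assert after.das == 2

    def test_reserve_depleted_by_end_of_phase(self):
        c = ModelConstants()
        state = PlantState.initial(c)
        for _ in range(4):
            state = heterotrophic_step(state, c)
        assert state.seed_reserve <= 1e-12 * c.initial_seed_reserve
        # no roots or inflorescence before photosynthesis begins
        assert state.root_mass == 0.0
        assert state.infl_mass == 0.0
        assert state.leaf_mass > c.initial_leaf_mass

    def test_rejected_outside_phase(self):
        c = ModelConstants()
        state = PlantState.initial(c)
        state.das = 5
        with pytest.raises(ValueError):
            heterotrophic_step(state, c)


class TestOptimalSigma:
    def test_equal_day_night_maintenance(self):
        assert optimal_sigma(10.0, 1.0, 1.0, 8) == pytest.approx(2.0 / 3.0)
        assert optimal_sigma(10.0, 1.0, 1.0, 12) == pytest.approx(0.5)

    def test_night_heavier_maintenance_stores_more(self):
        # R_N - R_D = 0.2 A with an 8 h photoperiod -> 80% to starch
        assert optimal_sigma(10.0, 1.0, 3.0, 8) == pytest.approx(0.8)

    def test_short_photoperiod_limit(self):
        # P -> 0: sigma -> 1 - (R_D - R_N)/A
        assert optimal_sigma(10.0, 3.0, 1.0, 1e-9) == pytest.approx(0.8)

    def test_clipped_to_unit_interval(self):
        assert optimal_sigma(1.0, 100.0, 0.0, 8) == 0.0
        assert optimal_sigma(1.0, 0.0, 100.0, 20) == 1.0

    def test_zero_assimilation_rejected(self):
        with pytest.raises(ValueError):
            optimal_sigma(0.0, 1.0, 1.0, 8)


class TestSimulate:
    def test_no_carbon_no_growth(self, col0_config):
        dark = col0_config.with_(
            photosynthesis=PhotosynthesisCurve((0.0, 0.0, 0.0, 0.0), das_range=(1, 90))
        )
        res = simulate(dark)
        after = res.daily[res.daily.das >= 4]
        assert after["leaf_mass"].nunique() == 1
        assert after["infl_mass"].eq(0).all()
        assert after["root_mass"].eq(0).all()

    def test_plant_mass_strictly_increasing_in_vegetative_phase(self, col0_result):
        veg = col0_result.daily.query("phase in ('early_vegetative', 'late_vegetative')")
        assert np.all(np.diff(veg["plant_mass"]) > 0)

    def test_states_monotone_non_decreasing(self, col0_result):
        for col in ("leaf_area", "leaf_mass", "infl_mass", "root_mass"):
            assert np.all(np.diff(col0_result.daily[col]) >= 0)

    def test_starch_pool_empties_at_dawn(self, col0_result):
        assert np.all(col0_result.daily["starch_pool"].to_numpy() == 0.0)

    def test_daily_and_hourly_shapes(self, col0_config):
        res = simulate(col0_config, record_hourly=True)
        assert len(res.daily) == 90
        assert len(res.hourly) == 90 * 24

    def test_driver_domain_must_cover_simulation(self, col0_config):
        short = col0_config.with_(
            photosynthesis=PhotosynthesisCurve((5.0, 0, 0, 0), das_range=(20, 90))
        )
        with pytest.raises(ValueError):
            simulate(short)

    def test_carbon_ledger_closes(self, col0_result, gi2_result):
        assert abs(col0_result.ledger_residual()) < 1e-9
        assert abs(gi2_result.ledger_residual()) < 1e-9

    def test_ledger_closes_under_random_configurations(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            res = simulate(random_config(rng))
            assert abs(res.ledger_residual()) < 1e-9


def _per_second_oracle(row, das, cfg):
    """Independent brute-force per-second integration of one autotrophic day,
    written from the model equations rather than the package's step code."""
    c, sch = cfg.constants, cfg.schedule
    s, ML, Mi, Mr = (
        float(row[k]) for k in ("leaf_area", "leaf_mass", "infl_mass", "root_mass")
    )
    A, r = cfg.photosynthesis(das), cfg.overlap(das)
    coeffs = cfg.partitions.phase(sch.phase_of(das))
    pool, draw = 0.0, 0.0
    for sec in range(86_400):
        hour = sec // 3600
        if hour < sch.photoperiod_h:
            s_eff = r * s + c.shaded_photo_fraction * (1 - r) * s
            ap = A * s_eff  # umol per second
            pool += ap * c.sigma
            nar = ap * (1 - c.sigma) - (
                c.ri_maint_coeff * Mi + c.rr_maint_coeff * Mr
            ) - c.exudation / 3600
        else:
            if sec == sch.photoperiod_h * 3600:
                draw = pool / (sch.night_h * 3600)
            pool -= draw
            nar = draw - (
                c.rL_maint * s + c.ri_maint_coeff * Mi + c.rr_maint_coeff * Mr
            ) - c.exudation / 3600
        if nar > 0:
            g = nar / c.carbon_conc
            dsM = g * coeffs.lambda_s * (1 - c.gL_growth_coeff)
            s += (s / ML) * dsM
            ML += dsM + g * coeffs.lambda_t * (1 - c.gL_growth_coeff)
            Mi += g * coeffs.iota * (1 - c.gi_growth_coeff)
            Mr += g * coeffs.rho * (1 - c.gr_growth_coeff)
    return {"leaf_area": s, "leaf_mass": ML, "infl_mass": Mi, "root_mass": Mr}


def test_hourly_step_agrees_with_per_second_integration(col0_config, col0_result):
    """On a slow-growth day the 1 h explicit-Euler step matches a brute-force
    per-second integration to <0.1% on every state increment (the residual is
    the within-hour state-feedback error, which scales with hourly relative
    growth)."""
    das = 80
    prev, cur = col0_result.at(das - 1), col0_result.at(das)
    fine = _per_second_oracle(prev, das, col0_config)
    for col in ("leaf_area", "leaf_mass", "infl_mass", "root_mass"):
        inc_hourly = cur[col] - prev[col]
        inc_fine = fine[col] - prev[col]
        assert inc_fine > 0
        assert abs(inc_hourly - inc_fine) / inc_fine < 1e-3
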