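import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rosettesim as rs
from rosettesim.calibration import (
    MeasurementSeries,
    ObjectiveWeights,
    cluster_and_rank,
    constraint_box,
    decode_genome,
    evaluate,
    fit_nsga2,
    repair_simplex,
    weighted_diff,
)
from rosettesim.config import PHASES, PartitionSet
from rosettesim.nsga2 import crowding_distance, fast_non_dominated_sort


def one_point_series(mean=1.0, sd=0.1):
    return MeasurementSeries("leaf_area", ((44, mean, sd, 10),))


class TestWeightedDiff:
    def test_logistic_midpoint_at_half_sd(self):
        series = one_point_series(mean=1.0, sd=0.2)
        assert weighted_diff([1.1], series) == pytest.approx(0.5)

    def test_perfect_match_contributes_almost_nothing(self):
        series = one_point_series()
        assert weighted_diff([1.0], series) == pytest.approx(1 / (1 + math.e**5))

    def test_one_sd_off_nearly_saturates(self):
        series = one_point_series(mean=1.0, sd=0.1)
        assert weighted_diff([1.1], series) == pytest.approx(1 / (1 + math.e**-5))

    def test_sums_over_points(self):
        series = MeasurementSeries(
            "leaf_mass", ((26, 1.0, 0.1, 10), (44, 2.0, 0.2, 10))
        )
        # both points exactly one SD off
        expected = 2 / (1 + math.e**-5)
        assert weighted_diff([1.1, 1.8], series) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(d1=st.floats(0, 5), d2=st.floats(0, 5))
    def test_monotone_in_absolute_difference(self, d1, d2):
        series = one_point_series(mean=0.0, sd=1.0)
        lo, hi = sorted([d1, d2])
        assert weighted_diff([lo], series) <= weighted_diff([hi], series) + 1e-12

    def test_non_positive_sd_rejected(self):
        with pytest.raises(ValueError):
            MeasurementSeries("leaf_area", ((44, 1.0, 0.0, 10),))

    def test_misaligned_model_values_rejected(self):
        with pytest.raises(ValueError):
            weighted_diff([1.0, 2.0], one_point_series())


class TestConstraintBox:
    def test_no_inflorescence_before_flowering(self):
        assert constraint_box("early_vegetative")[0] == (0.0, 0.0)
        assert constraint_box("germination")[0] == (0.0, 0.0)

    def test_roots_always_get_some_carbon(self):
        assert constraint_box("late_vegetative")[1][0] == pytest.approx(0.01)
        assert constraint_box("reproductive")[1][0] == pytest.approx(0.01)

    def test_overrides_merge(self):
        box = constraint_box(
            "early_vegetative", {"early_vegetative": {"iota": (0.0, 0.05)}}
        )
        assert box[0] == (0.0, 0.05)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            constraint_box("reproductive", {"reproductive": {"rho": (0.5, 0.1)}})
        with pytest.raises(KeyError):
            constraint_box("flowering")


class TestRepairSimplex:
    def test_uniform_values_normalized(self):
        out = repair_simplex([0.2, 0.2, 0.2, 0.2], [(0, 1)] * 4)
        assert np.allclose(out, 0.25)

    def test_fixed_coordinates_pinned(self):
        box = constraint_box("early_vegetative")
        out = repair_simplex([0.5, 0.1, 0.6, 0.3], box)
        assert out[0] == 0.0
        assert out.sum() == pytest.approx(1.0)

    def test_rho_floor_enforced(self):
        box = constraint_box("late_vegetative")
        out = repair_simplex([0.5, 0.0, 0.4, 0.1], box)
        assert out[1] >= 0.01
        assert out.sum() == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(genome=st.lists(st.floats(0, 1), min_size=16, max_size=16))
    def test_decode_always_feasible(self, genome):
        ps = decode_genome(genome)
        for phase in PHASES:
            c = ps.phase(phase)
            assert sum(c.as_tuple()) == pytest.approx(1.0, abs=1e-9)
        assert ps.early_vegetative.iota == 0.0
        assert ps.late_vegetative.rho >= 0.01 - 1e-12


@pytest.fixture(scope="module")
def gi2_truth_study(gi2_config):
    truth = rs.partition_table("gi2", 1)
    study = rs.SyntheticStudy(truth=truth, genotype="gi2", cv=0.0, seed=1)
    return truth, rs.generate_measurements(study, gi2_config)


class TestEvaluate:
    def test_truth_scores_near_floor(self, gi2_config, gi2_truth_study):
        truth, meas = gi2_truth_study
        objs = evaluate(truth, gi2_config, meas)
        floor = 1 / (1 + math.e**5)
        for k, obs in enumerate(("leaf_area", "leaf_mass", "root_mass", "stem_mass")):
            assert objs[k] == pytest.approx(len(meas[obs].points) * floor, rel=1e-6)
            assert objs[k] < 0.03

    def test_no_leaf_area_allocation_saturates_leaf_area_objective(
        self, gi2_config, gi2_truth_study
    ):
        _, meas = gi2_truth_study
        starved = decode_genome(
            # lambda_s ~ 0 everywhere: all leaf C goes to thickening
            np.array([0.0, 0.0, 0.0, 1.0] * 4)
        )
        objs = evaluate(starved, gi2_config, meas)
        assert objs[0] >= 1.0

    def test_objective_vector_shape_and_finiteness(self, gi2_config, gi2_truth_study):
        truth, meas = gi2_truth_study
        objs = evaluate(truth, gi2_config, meas)
        assert objs.shape == (4,)
        assert np.isfinite(objs).all()


class TestFitNsga2:
    def test_same_seed_reproduces_front(self, gi2_config, gi2_truth_study):
        _, meas = gi2_truth_study
        runs = [
            fit_nsga2(gi2_config, meas, population=8, generations=4, seed=5,
                      refine_every=None)
            for _ in range(2)
        ]
        f0 = np.sort(runs[0].front_objectives, axis=0)
        f1 = np.sort(runs[1].front_objectives, axis=0)
        assert np.array_equal(f0, f1)

    def test_front_is_mutually_non_dominated(self, gi2_config, gi2_truth_study):
        _, meas = gi2_truth_study
        res = fit_nsga2(gi2_config, meas, population=8, generations=4, seed=5,
                        refine_every=None)
        F = res.front_objectives
        fronts = fast_non_dominated_sort(F)
        assert len(fronts[0]) == len(F)

    def test_missing_observable_rejected(self, gi2_config, gi2_truth_study):
        _, meas = gi2_truth_study
        incomplete = {k: v for k, v in meas.items() if k != "root_mass"}
        with pytest.raises(ValueError):
            fit_nsga2(gi2_config, incomplete, population=8, generations=2)


class TestNsga2Internals:
    def test_fronts_ordered_by_domination(self):
        F = np.array([[1.0, 1.0], [2.0, 2.0], [1.5, 0.5], [3.0, 3.0]])
        fronts = fast_non_dominated_sort(F)
        assert sorted(fronts[0].tolist()) == [0, 2]
        assert fronts[1].tolist() == [1]
        assert fronts[2].tolist() == [3]

    def test_boundary_points_have_infinite_crowding(self):
        F = np.array([[0.0, 3.0], [1.0, 2.0], [2.0, 1.0], [3.0, 0.0]])
        cd = crowding_distance(F)
        assert np.isinf(cd[0]) and np.isinf(cd[3])
        assert np.isfinite(cd[1]) and np.isfinite(cd[2])


def _settings_around(center_genome, n, spread, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        g = np.clip(center_genome + rng.normal(0, spread, 16), 0, 1)
        out.append(decode_genome(g))
    return out


class TestClusterAndRank:
    def test_planted_partition_recovered(self):
        # centres must differ after simplex normalization, so use distinct
        # coefficient mixes rather than scaled copies of one mix
        centre_a = np.tile([0.05, 0.1, 0.7, 0.15], 4)
        centre_b = np.tile([0.3, 0.3, 0.2, 0.2], 4)
        a = _settings_around(centre_a, 8, 0.01, seed=1)
        b = _settings_around(centre_b, 8, 0.01, seed=2)
        objs = np.full((16, 4), 0.5)
        report = cluster_and_rank(a + b, objs)
        assert report.n_clusters == 2
        labels = report.labels
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_ranking_prefers_leaf_fit(self):
        settings_ = _settings_around(np.full(16, 0.5), 2, 0.05, seed=3)
        objs = np.array([[0.5, 0.5, 0.0, 0.0], [0.1, 0.1, 0.9, 0.9]])
        report = cluster_and_rank(settings_, objs, n_clusters=1)
        assert report.ranked_indices[0] == 1
        assert report.top_two == [1, 0]

    def test_duplicates_collapse_to_one_cluster(self):
        s = decode_genome(np.full(16, 0.5))
        report = cluster_and_rank([s] * 5, np.full((5, 4), 0.2))
        assert report.n_clusters == 1

    def test_single_setting_passthrough_with_warning(self):
        s = decode_genome(np.full(16, 0.5))
        with pytest.warns(UserWarning):
            report = cluster_and_rank([s], np.array([[0.1, 0.1, 0.1, 0.1]]))
        assert report.top_two == [0]
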