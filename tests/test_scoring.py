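"""Unit and property tests for DAS28 scoring and the windowed statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtxresponse import (
    CoverageError,
    DoseInterval,
    ValidationError,
    Visit,
    ZeroDoseError,
    cumulative_dose,
    das28_auc,
    das28_crp,
    improved_area,
    index_r,
)

from conftest import flat_visits, score_visits


class TestDas28Formula:
    def test_all_zero_components_give_the_constant(self):
        assert das28_crp(0, 0, 0, 0) == 0.96

    def test_median_baseline_profile(self):
        # 4 tender + 4 swollen joints, VAS 50, CRP 1.26: direct evaluation
        # of the composite formula, frozen from high-precision arithmetic.
        assert das28_crp(4, 4, 50, 1.26) == pytest.approx(3.63353133278231, abs=1e-12)

    @pytest.mark.parametrize(
        "base, bumped",
        [
            ((4, 4, 50, 1.26), (5, 4, 50, 1.26)),
            ((4, 4, 50, 1.26), (4, 5, 50, 1.26)),
            ((4, 4, 50, 1.26), (4, 4, 51, 1.26)),
            ((4, 4, 50, 1.26), (4, 4, 50, 1.5)),
        ],
    )
    def test_strictly_increasing_in_each_component(self, base, bumped):
        assert das28_crp(*bumped) > das28_crp(*base)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(t28=-1, s28=0, vas=0, crp=0), "t28"),
            (dict(t28=0, s28=29, vas=0, crp=0), "s28"),
            (dict(t28=0, s28=0, vas=101, crp=0), "vas"),
            (dict(t28=0, s28=0, vas=0, crp=-0.1), "crp"),
        ],
    )
    def test_out_of_range_component_named_in_error(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            das28_crp(**kwargs)


class TestVisit:
    def test_score_recomputed_from_components(self):
        v = Visit(month=0, t28=4, s28=4, vas=50, crp=1.26)
        assert v.das28 == pytest.approx(das28_crp(4, 4, 50, 1.26))

    def test_inconsistent_injected_score_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            Visit(month=0, t28=4, s28=4, vas=50, crp=1.26, das28=5.0)

    def test_partial_components_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            Visit(month=0, t28=4, s28=4, vas=50)


class TestAuc:
    def test_reference_trajectory_areas(self):
        # a trajectory pinned at the reference level of 10 accumulates
        # exactly 30 score-months over 0-3 and 60 over 0-6
        visits = flat_visits(10.0)
        assert das28_auc(visits, (0, 3)) == 30.0
        assert das28_auc(visits, (0, 6)) == 60.0

    @pytest.mark.parametrize("level, horizon", [(2.5, 4.0), (7.0, 12.0)])
    def test_constant_trajectory_is_a_rectangle(self, level, horizon):
        visits = score_visits([0, horizon], [level, level])
        assert das28_auc(visits, (0, horizon)) == pytest.approx(level * horizon)

    def test_linear_decline_is_a_trapezoid(self):
        visits = score_visits([0, 6], [6, 2])
        assert das28_auc(visits, (0, 6)) == pytest.approx(24.0)

    def test_edge_values_interpolated_between_visits(self):
        # window edge at month 3 falls between visits at 2 and 4
        # value at month 3 is the interpolant 3.0; area = 8 + (4+3)/2
        visits = score_visits([0, 2, 4], [4, 4, 2])
        assert das28_auc(visits, (0, 3)) == pytest.approx(11.5)

    def test_additive_over_abutting_windows(self):
        visits = score_visits([0, 1, 2.5, 4, 6], [5.0, 4.2, 3.1, 2.0, 1.1])
        total = das28_auc(visits, (0, 6))
        assert das28_auc(visits, (0, 3)) + das28_auc(visits, (3, 6)) == pytest.approx(total)

    def test_uncovered_window_raises(self):
        visits = score_visits([0, 1, 2], [4, 4, 4])
        with pytest.raises(CoverageError):
            das28_auc(visits, (0, 6))

    @given(
        shift=st.floats(-2, 2),
        scores=st.lists(st.floats(2.01, 8), min_size=2, max_size=8),
    )
    def test_translation_moves_area_by_shift_times_length(self, shift, scores):
        months = list(range(len(scores)))
        window = (0, months[-1])
        base = das28_auc(score_visits(months, scores), window)
        moved = das28_auc(score_visits(months, [s + shift for s in scores]), window)
        assert moved - base == pytest.approx(shift * months[-1], abs=1e-9)


class TestImprovedArea:
    def test_reference_trajectory_has_zero_improvement(self):
        assert improved_area(flat_visits(10.0), (0, 6)) == 0.0

    def test_fully_suppressed_trajectory_recovers_reference_area(self):
        assert improved_area(flat_visits(0.0), (0, 6)) == 60.0

    def test_linear_decline_example(self):
        visits = score_visits([0, 6], [6, 2])
        assert improved_area(visits, (0, 6)) == pytest.approx(36.0)

    def test_trajectory_above_reference_warns_not_clips(self):
        visits = flat_visits(11.0, [0, 3])
        with pytest.warns(UserWarning, match="negative"):
            area = improved_area(visits, (0, 3))
        assert area == pytest.approx(-3.0)


class TestCumulativeDose:
    def test_constant_weekly_dose_four_weeks_per_month(self):
        doses = [DoseInterval(0, 12, 8.0)]
        assert cumulative_dose(doses, (0, 3)) == pytest.approx(96.0)
        assert cumulative_dose(doses, (0, 6)) == pytest.approx(192.0)

    def test_piecewise_schedule_sums_overlaps(self):
        doses = [DoseInterval(0, 1.5, 8.0), DoseInterval(1.5, 3, 10.0)]
        assert cumulative_dose(doses, (0, 3)) == pytest.approx(8 * 6 + 10 * 6)

    def test_calendar_weeks_factor_changes_scale(self):
        doses = [DoseInterval(0, 3, 8.0)]
        calendar = cumulative_dose(doses, (0, 3), weeks_per_month=365.25 / 12 / 7)
        assert calendar == pytest.approx(8 * 3 * 365.25 / 12 / 7)

    def test_gap_in_coverage_raises(self):
        doses = [DoseInterval(0, 1, 8.0), DoseInterval(2, 3, 8.0)]
        with pytest.raises(CoverageError):
            cumulative_dose(doses, (0, 3))


class TestIndexR:
    def test_arithmetic(self):
        # constant DAS28 = 5/3 gives improved area 30 - 5 = 25 over 0-3
        # months; on 100 mg cumulative dose, R = 0.25/mg
        visits = score_visits([0, 3], [5 / 3, 5 / 3])
        doses = [DoseInterval(0, 3, 100 / 12)]
        s = index_r(visits, doses, (0, 3))
        assert s.improved_area == pytest.approx(25.0)
        assert s.cumulative_dose_mg == pytest.approx(100.0)
        assert s.index_r == pytest.approx(0.25)

    @given(factor=st.floats(0.5, 4.0))
    def test_homogeneity_degree_minus_one_in_dose(self, factor):
        visits = score_visits([0, 1, 3, 6], [5, 4, 3, 2])
        doses = [DoseInterval(0, 6, 8.0)]
        scaled = [DoseInterval(0, 6, 8.0 * factor)]
        base = index_r(visits, doses, (0, 6)).index_r
        assert index_r(visits, scaled, (0, 6)).index_r == pytest.approx(base / factor)

    def test_reference_trajectory_gives_zero_index(self):
        s = index_r(flat_visits(10.0), [DoseInterval(0, 12, 8.0)], (0, 6))
        assert s.index_r == 0.0

    def test_zero_dose_is_undefined(self):
        with pytest.raises(ZeroDoseError):
            index_r(flat_visits(5.0), [DoseInterval(0, 12, 0.0)], (0, 3))

    def test_invariant_under_refining_dose_intervals(self):
        visits = score_visits([0, 3, 6], [5, 3, 2])
        whole = [DoseInterval(0, 12, 8.0)]
        split = [DoseInterval(0, 2, 8.0), DoseInterval(2, 5, 8.0), DoseInterval(5, 12, 8.0)]
        assert index_r(visits, whole, (0, 6)).index_r == pytest.approx(
            index_r(visits, split, (0, 6)).index_r
        )


def test_trapezoid_agrees_with_fine_riemann_oracle():
    """Trapezoidal AUC vs midpoint Riemann sum on random trajectories."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = rng.integers(3, 12)
        months = np.sort(rng.uniform(0, 12, size=n))
        months[0] = 0.0
        months = np.unique(months)
        scores = rng.uniform(0, 10, size=months.size)
        t0 = rng.uniform(0, months[-1] / 2)
        t1 = rng.uniform(t0 + 0.5, months[-1])
        visits = score_visits(months, scores)
        grid = np.linspace(t0, t1, 100_001)
        mid = (grid[:-1] + grid[1:]) / 2
        riemann = float(np.sum(np.interp(mid, months, scores)) * (t1 - t0) / 100_000)
        assert das28_auc(visits, (t0, t1)) == pytest.approx(riemann, rel=1e-6)
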