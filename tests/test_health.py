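"""Closed-form health metrics, the dose–response layer, and the weighted
fitness scalarisation."""

import math

import numpy as np
import pytest

from pesched import (FitnessWeights, HealthModelError, MetricNorms,
                     OutcomeVector, ResponseParams, Schedule, bmr,
                     calories_burned, cohort_fitness, effective_met,
                     optimal_pe_time, predict_outcomes, predict_outcomes_frame,
                     weighted_fitness)
from pesched.health import ACTIVITIES, INTENSITIES


def _schedule(n=3, t=1.0, act=(1, 0, 0, 0, 0), inten=(0, 0, 1)):
    return Schedule(n, t, np.array(act, dtype=float), np.array(inten, dtype=float))


class TestBmr:
    def test_hand_values(self):
        assert bmr(70, 175, 30, "male") == pytest.approx(1648.75, abs=1e-12)
        assert bmr(55, 160, 12, "female") == pytest.approx(1329.0, abs=1e-12)

    def test_sex_constant_difference(self):
        assert bmr(60, 165, 15, "male") - bmr(60, 165, 15, "female") == pytest.approx(166.0)

    def test_nonpositive_anthropometrics_error(self):
        with pytest.raises(HealthModelError):
            bmr(0, 170, 12, "male")

    def test_unknown_sex_error(self):
        with pytest.raises(HealthModelError):
            bmr(50, 160, 12, "other")


class TestCaloriesBurned:
    def test_hand_value(self):
        assert calories_burned(8, 50, 0.75, 1329) == pytest.approx(698.7, abs=1e-9)

    def test_zero_duration(self):
        assert calories_burned(8, 50, 0.0, 1329) == 0.0

    def test_zero_bmr_reduces_to_met_formula(self):
        assert calories_burned(6, 40, 1.0, 0.0) == pytest.approx(240.0)

    def test_negative_inputs_error(self):
        with pytest.raises(HealthModelError):
            calories_burned(-1, 50, 1, 1000)


def test_closed_forms_match_independent_reimplementation():
    """1,000 random inputs against formulas re-coded from scratch."""
    rng = np.random.default_rng(123)
    for _ in range(1000):
        w = rng.uniform(15, 120)
        h = rng.uniform(100, 200)
        a = rng.uniform(6, 18)
        sex = rng.choice(["male", "female"])
        expected_bmr = 10.0 * w + 6.25 * h - 5.0 * a + (5.0 if sex == "male" else -161.0)
        got_bmr = bmr(w, h, a, sex)
        assert got_bmr == pytest.approx(expected_bmr, abs=1e-9)
        met = rng.uniform(1, 15)
        t = rng.uniform(0, 3)
        assert calories_burned(met, w, t, got_bmr) == pytest.approx(
            met * w * t * (1.0 + expected_bmr / 1000.0), abs=1e-9)


class TestEffectiveMet:
    def test_degenerate_mix_returns_table_entry(self, default_params):
        s = _schedule(act=(1, 0, 0, 0, 0), inten=(0, 0, 1))
        assert effective_met(s, default_params) == default_params.met_table[("aerobic", "vigorous")]

    def test_uniform_mix_is_table_mean(self, default_params):
        s = _schedule(act=(0.2,) * 5, inten=(1 / 3,) * 3)
        table_mean = np.mean([default_params.met_table[(a, i)]
                              for a in ACTIVITIES for i in INTENSITIES])
        assert effective_met(s, default_params) == pytest.approx(table_mean)

    def test_bounded_by_table_extremes(self, default_params):
        rng = np.random.default_rng(7)
        vals = list(default_params.met_table.values())
        for _ in range(50):
            s = _schedule(act=rng.dirichlet(np.ones(5)), inten=rng.dirichlet(np.ones(3)))
            m = effective_met(s, default_params)
            assert min(vals) - 1e-12 <= m <= max(vals) + 1e-12


class TestOptimalPeTime:
    def test_products_and_quotients(self):
        weekly, daily = optimal_pe_time(5, 1.5, days_per_week=5)
        assert weekly == pytest.approx(7.5)
        assert daily == pytest.approx(1.5)

    def test_zero_sessions(self):
        assert optimal_pe_time(0, 1.0) == (0.0, 0.0)

    def test_linearity_in_session_length(self):
        w1, d1 = optimal_pe_time(4, 1.0, 6)
        w2, d2 = optimal_pe_time(4, 2.0, 6)
        assert w2 == pytest.approx(2 * w1)
        assert d2 == pytest.approx(2 * d1)

    def test_invalid_days_error(self):
        with pytest.raises(HealthModelError):
            optimal_pe_time(3, 1.0, days_per_week=4)


class TestPredictOutcomes:
    STUDENT = {"weight_kg": 50.0, "height_cm": 160.0, "age": 14.0, "sex": "female"}

    def test_no_activity_gives_zero_outcomes(self, default_params):
        s = Schedule(0, 0.0, np.full(5, 0.2), np.full(3, 1 / 3))
        out = predict_outcomes(self.STUDENT, s, default_params)
        assert out.as_array().tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_saturation_asymptotes(self):
        params = ResponseParams()
        s = Schedule(7, 1.5, np.array([1, 0, 0, 0, 0.]), np.array([0, 0, 1.]))
        big = ResponseParams(k_f=50.0, k_h=50.0)
        out = predict_outcomes(self.STUDENT, s, big)
        assert out.delta_f == pytest.approx(big.f_gain_max, rel=1e-6)
        assert out.delta_hr == pytest.approx(big.hr_drop_max, rel=1e-6)
        assert out.delta_bmi <= params.bmi_cap

    def test_matches_hand_evaluated_closed_form(self, default_params):
        """Independent spreadsheet-style evaluation of the stated formulas."""
        p = default_params
        s = Schedule(4, 1.25, np.array([0.5, 0.2, 0.1, 0.1, 0.1]),
                     np.array([0.2, 0.5, 0.3]))
        st = self.STUDENT
        bmr_v = 10 * 50 + 6.25 * 160 - 5 * 14 - 161          # 1269.0
        met_m = p.met_matrix()
        met = float(s.activity_mix @ met_m @ s.intensity_mix)
        cal = met * 50 * 1.25 * (1 + bmr_v / 1000)
        weekly_kcal = cal * 4
        d_bmi = min(p.bmi_cap, p.horizon_weeks * weekly_kcal / p.kcal_per_kg_fat / 1.6 ** 2)
        weekly = 4 * 1.25
        d_f = p.f_gain_max * (1 - math.exp(-p.k_f * weekly * 0.8))
        d_hr = p.hr_drop_max * (1 - math.exp(-p.k_h * weekly * 0.5))
        out = predict_outcomes(st, s, p)
        assert out.calories == pytest.approx(cal, abs=1e-9)
        assert out.delta_bmi == pytest.approx(d_bmi, abs=1e-9)
        assert out.delta_f == pytest.approx(d_f, abs=1e-9)
        assert out.delta_hr == pytest.approx(d_hr, abs=1e-9)

    def test_monotone_in_session_length(self, default_params):
        prev = None
        for t in np.linspace(0.25, 1.5, 6):
            out = predict_outcomes(self.STUDENT, _schedule(n=4, t=t), default_params)
            if prev is not None:
                assert out.calories >= prev.calories
                assert out.delta_f >= prev.delta_f
                assert out.delta_hr >= prev.delta_hr
                assert out.delta_bmi >= prev.delta_bmi or prev.delta_bmi == default_params.bmi_cap
            prev = out

    def test_frame_agrees_with_scalar_path(self, tiny_cohort, default_params):
        s = _schedule(n=5, t=1.2, act=(0.4, 0.3, 0.1, 0.1, 0.1), inten=(0.1, 0.6, 0.3))
        frame = predict_outcomes_frame(tiny_cohort, s, default_params)
        for pos in (0, 7, 29):
            row = tiny_cohort.iloc[pos]
            out = predict_outcomes(row, s, default_params)
            assert frame["calories"].iloc[pos] == pytest.approx(out.calories, abs=1e-9)
            assert frame["delta_bmi"].iloc[pos] == pytest.approx(out.delta_bmi, abs=1e-9)


class TestWeightedFitness:
    NORMS = MetricNorms(delta_bmi=(0, 1), delta_f=(0, 1), calories=(0, 1), delta_hr=(0, 1))

    def test_hand_arithmetic(self):
        out = OutcomeVector(0.5, 0.2, 1.0, 0.0)
        assert weighted_fitness(out, FitnessWeights(), self.NORMS) == pytest.approx(0.46)

    def test_boundaries(self, default_norms, default_weights):
        lo = OutcomeVector(0.0, 0.0, 0.0, 0.0)
        hi = OutcomeVector(default_norms.delta_bmi[1], default_norms.delta_f[1],
                           default_norms.calories[1], default_norms.delta_hr[1])
        assert weighted_fitness(lo, default_weights, default_norms) == 0.0
        assert weighted_fitness(hi, default_weights, default_norms) == pytest.approx(1.0)

    def test_weight_metric_permutation_symmetry(self):
        out = OutcomeVector(0.7, 0.1, 0.4, 0.9)
        w = FitnessWeights(0.4, 0.3, 0.2, 0.1)
        score = weighted_fitness(out, w, self.NORMS)
        out_p = OutcomeVector(0.1, 0.7, 0.9, 0.4)
        w_p = FitnessWeights(0.3, 0.4, 0.1, 0.2)
        assert weighted_fitness(out_p, w_p, self.NORMS) == pytest.approx(score)

    def test_invalid_weights_rejected(self):
        with pytest.raises(HealthModelError):
            FitnessWeights(0.5, 0.3, 0.2, 0.1)
        with pytest.raises(HealthModelError):
            FitnessWeights(-0.1, 0.5, 0.4, 0.2)


class TestCohortFitness:
    def test_single_student_equals_individual_score(self, tiny_cohort, default_params,
                                                    default_weights, default_norms):
        one = tiny_cohort.iloc[[3]]
        s = _schedule(n=4, t=1.0)
        expected = weighted_fitness(predict_outcomes(one.iloc[0], s, default_params),
                                    default_weights, default_norms)
        assert cohort_fitness(one, s, default_weights, default_params,
                              default_norms) == pytest.approx(expected)

    def test_duplication_invariance(self, tiny_cohort, default_params,
                                    default_weights, default_norms):
        import pandas as pd
        s = _schedule(n=4, t=1.0)
        once = cohort_fitness(tiny_cohort, s, default_weights, default_params, default_norms)
        twice = cohort_fitness(pd.concat([tiny_cohort, tiny_cohort]), s,
                               default_weights, default_params, default_norms)
        assert twice == pytest.approx(once)

    def test_two_student_hand_mean(self, tiny_cohort, default_params,
                                   default_weights, default_norms):
        pair = tiny_cohort.iloc[[0, 1]]
        s = _schedule(n=5, t=1.3)
        scores = [weighted_fitness(predict_outcomes(pair.iloc[i], s, default_params),
                                   default_weights, default_norms) for i in range(2)]
        assert cohort_fitness(pair, s, default_weights, default_params,
                              default_norms) == pytest.approx(np.mean(scores))

    def test_empty_cohort_errors(self, tiny_cohort, default_params,
                                 default_weights, default_norms):
        with pytest.raises(HealthModelError):
            cohort_fitness(tiny_cohort.iloc[[]], _schedule(), default_weights,
                           default_params, default_norms)


def test_calibration_median_adolescent_vigorous_hour(default_params):
    """A vigorous aerobic 1-hour session for a median-build 14-year-old
    should expend 250–450 kcal, bracketing reported per-session values."""
    s = Schedule(3, 1.0, np.array([1, 0, 0, 0, 0.]), np.array([0, 0, 1.]))
    for sex, height in (("male", 163.0), ("female", 160.0)):
        st = {"weight_kg": 19.5 * (height / 100) ** 2, "height_cm": height,
              "age": 14.0, "sex": sex}
        out = predict_outcomes(st, s, default_params)
        assert 250.0 <= out.calories <= 450.0
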