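"""Kinetics: closed-form solutions, fits, decay comparison, mechanism calls."""

import math

import numpy as np
import pytest

from rvbtools import (
    GeneratorConfig,
    InductionModel,
    TimeCourse,
    classify_mechanism,
    compare_decay,
    fit_decay,
    fit_induction,
    gen_timecourse,
    simulate_decay,
    simulate_induction,
)
from rvbtools.kinetics import induction_solution

LN2 = math.log(2.0)


def rk4_integrate(model, times, dt=0.001):
    """Independent fixed-step oracle for dX/dt = beta - alpha*X."""
    f = lambda x: model.beta - model.alpha * x
    x, t = model.x0, 0.0
    out, ti = [], 0
    times = list(times)
    if times and times[0] == 0.0:
        out.append(x)
        ti = 1
    while ti < len(times):
        h = min(dt, times[ti] - t)
        k1 = f(x)
        k2 = f(x + h / 2 * k1)
        k3 = f(x + h / 2 * k2)
        k4 = f(x + h * k3)
        x += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        if abs(t - times[ti]) < 1e-12:
            out.append(x)
            ti += 1
    return np.array(out)


class TestSimulate:
    def test_zero_source_zero_start_stays_zero(self):
        tc = simulate_induction(InductionModel(0.05, 0.0, 0.0), [0, 10, 20])
        assert np.all(tc.values == 0)

    def test_steady_state_from_start_is_constant(self):
        m = InductionModel(alpha=0.05, beta=0.05 * 3, x0=3.0)
        tc = simulate_induction(m, [0, 7, 30, 100])
        assert np.allclose(tc.values, 3.0)

    def test_half_saturation_at_one_half_life_from_zero(self):
        m = InductionModel(alpha=LN2 / 25, beta=(LN2 / 25) * 1.0, x0=0.0)
        tc = simulate_induction(m, [0, 25])
        oracle = rk4_integrate(m, [0, 25])
        assert abs(tc.values[1, 0] - 0.5) < 1e-9
        assert abs(tc.values[1, 0] - oracle[1]) < 1e-6

    def test_alpha_zero_limit_is_linear_accumulation(self):
        tc = simulate_induction(InductionModel(0.0, 2.0, 1.0), [0, 5, 10])
        assert np.allclose(tc.values.ravel(), [1, 11, 21])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            simulate_induction(InductionModel(0.1, 1.0), [-5, 0, 5])

    def test_decay_without_alpha_is_flat(self):
        tc = simulate_decay(InductionModel(0.0, 0.0, 5.0), [0, 10, 20])
        assert np.allclose(tc.values, 5.0)

    def test_decay_exact_halvings(self):
        tc = simulate_decay(InductionModel(LN2 / 10, 0.0, 8.0), [0, 10, 20, 30])
        assert np.allclose(tc.values.ravel(), [8, 4, 2, 1])

    def test_decay_requires_positive_x0(self):
        with pytest.raises(ValueError, match="x0"):
            simulate_decay(InductionModel(0.1, 0.0, 0.0), [0, 10])

    def test_half_life_point_property(self):
        # X(ln2/alpha) - X0 == (beta/alpha - X0) / 2 exactly
        for alpha, beta, x0 in [(0.02, 0.5, 0.0), (0.1, 2.0, 3.0), (0.4, 0.1, 0.1)]:
            m = InductionModel(alpha, beta, x0)
            x = induction_solution(m, np.array([LN2 / alpha]))[0]
            assert abs((x - x0) - 0.5 * (beta / alpha - x0)) < 1e-12

    def test_monotone_increase_bounded_by_steady_state(self):
        m = InductionModel(0.05, 0.05 * 10, 1.0)  # beta > alpha*x0
        t = np.linspace(0, 20 * m.half_life, 400)
        x = induction_solution(m, t)
        assert np.all(np.diff(x) > 0)
        assert np.all(x <= m.steady_state + 1e-12)
        assert abs(x[-1] - m.steady_state) / m.steady_state < 1e-6


class TestFitInduction:
    def test_noiseless_round_trip(self):
        m = InductionModel(alpha=0.1, beta=0.1 * 16, x0=1.0)
        tc = simulate_induction(m, [0, 5, 10, 15, 30, 45]).to_fold()
        fit = fit_induction(tc)
        assert fit.converged
        assert abs(fit.alpha_hat - 0.1) < 1e-4
        assert abs(fit.fss_hat - 16.0) < 0.01

    def test_flat_course_unidentifiable(self):
        tc = TimeCourse("flat", [0, 5, 10, 20], np.ones((4, 2)), "fold_over_t0")
        fit = fit_induction(tc)
        assert not fit.converged
        assert fit.fss_hat == 1.0

    def test_requires_four_time_points(self):
        tc = TimeCourse("short", [0, 5, 10], np.ones((3, 1)) * 2, "fold_over_t0")
        with pytest.raises(ValueError, match="4 distinct"):
            fit_induction(tc)

    def test_noisy_recovery_within_ten_percent(self):
        m = InductionModel(alpha=0.1, beta=0.1 * 16, x0=1.0)
        errs = []
        for seed in range(30):
            cfg = GeneratorConfig(seed=seed, noise_cv=0.05, n_replicates=4)
            fit = fit_induction(gen_timecourse(cfg, m, "induction"))
            errs.append(abs(fit.alpha_hat - 0.1) / 0.1)
        assert np.median(errs) < 0.10


class TestFitDecay:
    def test_recovers_25_min_half_life(self):
        m = InductionModel(alpha=LN2 / 25, beta=0.0, x0=1.0)
        tc = simulate_decay(m, np.arange(0, 50, 5))
        fit = fit_decay(tc)
        assert abs(fit.half_life - 25.0) < 1e-9
        assert fit.r_squared > 1 - 1e-12

    def test_one_log2_unit_per_10_min_gives_half_life_10(self):
        t = np.array([0, 10, 20, 30], dtype=float)
        tc = TimeCourse("d", t, (2.0 ** (-t / 10))[:, None])
        assert abs(fit_decay(tc).half_life - 10.0) < 1e-9

    def test_constant_series_reports_infinite_half_life(self):
        tc = TimeCourse("c", [0, 10, 20], np.full((3, 2), 7.0))
        fit = fit_decay(tc)
        assert fit.slope_log2 == 0
        assert fit.half_life == math.inf

    def test_nonpositive_value_names_offender(self):
        tc = TimeCourse("bad", [0, 10, 20], np.array([[4.0], [0.0], [1.0]]))
        with pytest.raises(ValueError, match="time 10"):
            fit_decay(tc)


class TestCompareDecay:
    def test_identical_data_gives_null_interaction(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 50, 5, dtype=float)
        vals = 2.0 ** (-t / 25)[:, None] * np.exp(rng.normal(0, 0.05, (t.size, 3)))
        a = TimeCourse("ctrl", t, vals)
        b = TimeCourse("treated", t, vals)
        cmp = compare_decay(a, b)
        assert abs(cmp.interaction_log2_per_min) < 1e-12
        assert cmp.interaction_p > 1 - 1e-9

    def test_interaction_equals_slope_difference(self):
        t = np.arange(0, 50, 5, dtype=float)
        a = simulate_decay(InductionModel(LN2 / 25, 0, 1.0), t)
        b = simulate_decay(InductionModel(LN2 / 12.5, 0, 1.0), t)
        b.condition = "fast"
        cmp = compare_decay(a, b)
        assert abs(cmp.interaction_log2_per_min - (-0.04)) < 1e-9
        assert abs(cmp.half_life_a - 25.0) < 1e-9
        assert abs(cmp.half_life_b - 12.5) < 1e-9

    def test_same_condition_label_rejected(self):
        t = np.arange(0, 30, 5, dtype=float)
        a = simulate_decay(InductionModel(0.05, 0, 1.0), t)
        with pytest.raises(ValueError, match="distinct"):
            compare_decay(a, a)

    def test_type_one_error_calibration(self):
        # equal decay rates: interaction p should be ~uniform
        m = InductionModel(LN2 / 25, 0.0, 1.0)
        ps = []
        for seed in range(120):
            cfg = GeneratorConfig(
                seed=seed, noise_cv=0.1, n_replicates=3,
                time_grid=tuple(np.arange(0, 50, 5.0)),
            )
            a = gen_timecourse(cfg, m, "decay")
            b = gen_timecourse(
                GeneratorConfig(seed=seed + 5000, noise_cv=0.1, n_replicates=3,
                                time_grid=tuple(np.arange(0, 50, 5.0))),
                m, "decay")
            a.condition, b.condition = "a", "b"
            ps.append(compare_decay(a, b).interaction_p)
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= frac < 0.15  # ~5% expected; loose binomial band


BASE_ALPHA = LN2 / 25
GRID = [0, 5, 10, 15, 30, 45]


def _fold_course(alpha, fss, label):
    tc = simulate_induction(InductionModel(alpha, alpha * fss, 1.0), GRID)
    tc.condition = label
    return tc.to_fold()


class TestClassifyMechanism:
    def test_beta_scaling_called_transcription_shift(self):
        ctrl = _fold_course(BASE_ALPHA, 1e4, "ctrl")
        trt = _fold_course(BASE_ALPHA, 4e4, "trt")  # beta x4, same alpha
        call = classify_mechanism(ctrl, trt, t_min=10)
        assert call.call == "transcription_shift"
        assert abs(call.mean_shift_log2 - 2.0) < 0.1

    def test_alpha_halving_called_decay_shift(self):
        ctrl = _fold_course(BASE_ALPHA, 200, "ctrl")
        trt = _fold_course(BASE_ALPHA / 2, 400, "trt")  # alpha/2, same beta
        call = classify_mechanism(ctrl, trt)
        assert call.call == "decay_shift"
        # offset strictly increases over the assessed grid
        d = trt.log2_mean() - ctrl.log2_mean()
        assert np.all(np.diff(d[1:]) > 0)

    def test_identical_courses_indistinguishable(self):
        ctrl = _fold_course(BASE_ALPHA, 200, "ctrl")
        call = classify_mechanism(ctrl, ctrl)
        assert call.call == "indistinguishable"
        assert call.mean_shift_log2 == 0.0

    def test_too_few_late_points_rejected(self):
        ctrl = _fold_course(BASE_ALPHA, 200, "ctrl")
        with pytest.raises(ValueError, match=">= 3"):
            classify_mechanism(ctrl, ctrl, t_min=40)

    def test_interpolation_onto_control_grid(self):
        ctrl = _fold_course(BASE_ALPHA, 1e4, "ctrl")
        trt = simulate_induction(
            InductionModel(BASE_ALPHA, BASE_ALPHA * 2e4, 1.0), [0, 4, 12, 16, 28, 46]
        ).to_fold()
        call = classify_mechanism(ctrl, trt, t_min=10)
        assert call.call == "transcription_shift"
        assert abs(call.mean_shift_log2 - 1.0) < 0.05
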