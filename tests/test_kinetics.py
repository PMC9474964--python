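"""Core 2T3k forward model, frame schedule, and nonlinear fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from dtwpet import (
    FrameSchedule,
    InputFunction,
    KineticParams,
    TimeActivityCurve,
    build_frame_schedule,
    feng_input,
    fit_2t3k,
    frame_average,
    model_tac,
    net_influx_rate,
    solve_2t3k,
)
from dtwpet.io import read_frame_sidecar, write_frame_sidecar

from conftest import CORTEX


class TestFrameSchedule:
    def test_standard_66_frame_schedule(self):
        sched = build_frame_schedule()
        assert len(sched) == 66
        assert sched.span == (0.0, 60.0)
        # contiguous, sorted, nonnegative
        assert np.allclose(sched.start[1:], sched.end[:-1])
        assert np.all(sched.durations > 0)

    def test_single_block(self):
        sched = build_frame_schedule([(1, 60)])
        assert len(sched) == 1
        assert sched.span == (0.0, 1.0)

    @pytest.mark.parametrize("bad", [[], [(0, 5)], [(3, -1)]])
    def test_invalid_specs_raise(self, bad):
        with pytest.raises(ValueError):
            build_frame_schedule(bad)

    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 0.5]), np.array([1.0, 1.5]))

    def test_sidecar_roundtrip(self, tmp_path, schedule):
        path = tmp_path / "frames.json"
        write_frame_sidecar(schedule, path)
        back = read_frame_sidecar(path)
        assert np.allclose(back.start, schedule.start)
        assert np.allclose(back.end, schedule.end)


class TestInputFunction:
    def test_integral_is_exact_trapezoid(self):
        f = InputFunction(np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0, 2.0]))
        assert f.integral(1.0) == pytest.approx(1.0)
        assert f.integral(2.0) == pytest.approx(3.0)
        assert f.integral(1.5) == pytest.approx(2.0)

    def test_integral_monotone_in_upper_limit(self, input_fn):
        t = np.linspace(0, 60, 500)
        assert np.all(np.diff(input_fn.integral(t)) >= 0)

    def test_zero_before_support(self, input_fn):
        assert input_fn(-1.0) == 0.0
        assert input_fn.integral(0.0) == 0.0

    def test_shift_roundtrip(self, input_fn):
        shifted = input_fn.shifted(0.5)
        t = np.linspace(2, 50, 100)
        assert np.allclose(shifted(t), input_fn(t - 0.5), rtol=1e-9, atol=1e-9)

    def test_exp_conv_matches_quadrature(self, input_fn):
        theta = 0.37
        t = np.array([0.5, 1.0, 5.0, 20.0, 60.0])
        fine = np.linspace(0, 60, 120001)
        vals = input_fn(fine)
        for ti in t:
            sel = fine <= ti
            ref = np.trapezoid(
                np.exp(-theta * (ti - fine[sel])) * vals[sel], fine[sel]
            )
            assert input_fn.exp_conv(theta, np.array([ti]))[0] == pytest.approx(
                ref, rel=1e-5, abs=1e-8
            )

    def test_exp_conv_large_theta_stable(self, input_fn):
        out = input_fn.exp_conv(10.0, np.linspace(0, 60, 200))
        assert np.all(np.isfinite(out))
        assert np.all(out >= 0)


class TestForwardModel:
    def test_pure_blood_term(self, input_fn):
        grid = np.linspace(0, 60, 301)
        p = KineticParams(0.0, 0.0, 0.0, 0.05)
        assert np.allclose(solve_2t3k(input_fn, p, grid), 0.05 * input_fn(grid))

    def test_theta_zero_limit_is_integral(self, input_fn):
        grid = np.linspace(0, 60, 301)
        p = KineticParams(0.1, 0.0, 0.0, 0.0)
        assert np.allclose(
            solve_2t3k(input_fn, p, grid), 0.1 * input_fn.integral(grid)
        )

    def test_matches_stiff_ode_oracle(self, input_fn):
        """Analytic solution vs an independent ODE integration, 0.1% rtol."""
        p = CORTEX
        grid = np.linspace(0.0, 60.0, 601)

        def rhs(t, y):
            c = float(input_fn(t))
            return [p.K1 * c - (p.k2 + p.k3) * y[0], p.k3 * y[0]]

        sol = solve_ivp(
            rhs, (0, 60), [0.0, 0.0], t_eval=grid, method="LSODA",
            rtol=1e-10, atol=1e-12, max_step=0.02,
        )
        ref = p.Vb * input_fn(grid) + (1 - p.Vb) * (sol.y[0] + sol.y[1])
        mine = solve_2t3k(input_fn, p, grid)
        mask = ref > 1e-6
        assert np.max(np.abs(mine[mask] - ref[mask]) / ref[mask]) < 1e-3

    def test_linearity_in_input(self, input_fn):
        grid = np.linspace(0, 60, 101)
        p = CORTEX
        scaled = InputFunction(input_fn.times, 3.0 * input_fn.values)
        assert np.allclose(
            solve_2t3k(scaled, p, grid), 3.0 * solve_2t3k(input_fn, p, grid)
        )

    def test_monotone_when_no_efflux(self, input_fn):
        grid = np.linspace(0, 60, 301)
        p = KineticParams(0.1, 0.0, 0.05, 0.0)
        assert np.all(np.diff(solve_2t3k(input_fn, p, grid)) >= -1e-12)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(-0.1, 0.1, 0.1, 0.05)


class TestFrameAverage:
    def test_constant_curve(self, schedule):
        tac = frame_average(lambda t: np.full_like(t, 7.0), schedule)
        assert np.allclose(tac.values, 7.0)

    def test_linear_curve_analytic_mean(self):
        sched = build_frame_schedule([(1, 60)])  # one frame on [0, 1] min
        tac = frame_average(lambda t: 3.0 * t, sched)
        assert tac.values[0] == pytest.approx(1.5, rel=1e-6)

    def test_refinement_converged(self, schedule, input_fn):
        coarse = model_tac(input_fn, CORTEX, schedule, n_sub=8)
        fine = model_tac(input_fn, CORTEX, schedule, n_sub=80)
        assert np.allclose(coarse.values, fine.values, rtol=2e-3, atol=1e-4)


class TestNetInfluxRate:
    @pytest.mark.parametrize(
        "k, expected",
        [
            ((0.1, 0.1, 0.1), 0.05),
            ((0.1, 0.1, 0.0), 0.0),  # no trapping
            ((0.1, 0.0, 0.1), 0.1),  # full trapping: Ki = K1
            ((0.0, 0.0, 0.0), 0.0),  # degenerate: defined as 0
        ],
    )
    def test_arithmetic(self, k, expected):
        assert net_influx_rate(K1=k[0], k2=k[1], k3=k[2]) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None)
    @given(
        K1=st.floats(0, 5), k2=st.floats(0, 5), k3=st.floats(0, 5),
    )
    def test_ki_bounded_by_k1(self, K1, k2, k3):
        ki = net_influx_rate(K1=K1, k2=k2, k3=k3)
        assert 0.0 <= ki <= K1 + 1e-12


class TestFit2T3k:
    def test_noise_free_roundtrip_within_1pct(self, schedule, input_fn):
        truth = CORTEX
        tac = model_tac(input_fn, truth, schedule)
        fit = fit_2t3k(tac, input_fn)
        for name in ("K1", "k2", "k3", "Vb"):
            est, tru = getattr(fit.params, name), getattr(truth, name)
            assert est == pytest.approx(tru, rel=0.01)
        assert fit.params.Ki == pytest.approx(truth.Ki, rel=0.01)
        assert fit.converged

    def test_blood_only_tissue(self, schedule, input_fn):
        tac = frame_average(lambda t: 0.05 * input_fn(t), schedule)
        fit = fit_2t3k(tac, input_fn)
        assert fit.params.Vb == pytest.approx(0.05, abs=0.005)
        assert fit.params.Ki == pytest.approx(0.0, abs=1e-4)

    def test_all_zero_tac_flagged_zero_params(self, schedule, input_fn):
        tac = TimeActivityCurve(schedule, np.zeros(len(schedule)))
        fit = fit_2t3k(tac, input_fn)
        assert fit.params.as_array().tolist() == [0, 0, 0, 0]
        assert fit.weighted_rss == 0.0

    def test_objective_beats_all_starts(self, schedule, input_fn):
        """Returned fit is at least as good as every initial point."""
        from dtwpet.kinetics import _MULTISTART_INITS, frame_weights

        tac = model_tac(input_fn, CORTEX, schedule)
        fit = fit_2t3k(tac, input_fn)
        w = frame_weights(schedule)
        for x0 in _MULTISTART_INITS:
            start = model_tac(input_fn, KineticParams(*x0), schedule)
            rss0 = float(np.sum(w * (tac.values - start.values) ** 2))
            assert fit.weighted_rss <= rss0 + 1e-12

    def test_noisy_ki_recovery_unbiased(self, schedule, input_fn):
        """Mean recovered Ki over noisy replicates brackets the truth."""
        from dtwpet.synthetic import NoiseModel

        truth = CORTEX
        clean = model_tac(input_fn, truth, schedule)
        noise = NoiseModel(0.3)
        rng = np.random.default_rng(42)
        kis = []
        for _ in range(30):
            noisy = noise.apply(clean, rng)
            kis.append(fit_2t3k(noisy, input_fn).params.Ki)
        kis = np.array(kis)
        se = kis.std(ddof=1) / np.sqrt(kis.size)
        assert abs(kis.mean() - truth.Ki) < 3 * se + 0.005 * truth.Ki
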