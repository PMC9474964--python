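"""IDIF extraction, population curves, hybrid assembly, delay search."""

import numpy as np
import pytest

from dtwpet import (
    InputFunction,
    KineticParams,
    build_pb_idif,
    correct_delay,
    extract_roi_tac,
    feng_input,
    frame_average,
    hybrid_if_dtw,
    model_tac,
    scale_pbif_static,
    simulate_subject,
)
from dtwpet.parametric import DynamicImage
from dtwpet.synthetic import FengIFParams, simulate_cohort

from conftest import CORTEX


def _idif_as_if(tac):
    return InputFunction(tac.midpoints, tac.values)


class TestExtractRoiTac:
    def test_constant_image(self, schedule):
        data = np.full((4, 4, 2, len(schedule)), 3.5)
        img = DynamicImage(data, (3, 3, 3), schedule)
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[1:3, 1:3, :] = True
        tac = extract_roi_tac(img, mask)
        assert np.allclose(tac.values, 3.5)

    def test_two_voxel_mean(self, schedule):
        data = np.zeros((2, 1, 1, len(schedule)))
        data[0, 0, 0] = 2.0
        data[1, 0, 0] = 6.0
        img = DynamicImage(data, (3, 3, 3), schedule)
        tac = extract_roi_tac(img, np.ones((2, 1, 1), dtype=bool))
        assert np.allclose(tac.values, 4.0)

    def test_empty_mask_raises(self, schedule):
        img = DynamicImage(np.zeros((2, 2, 1, len(schedule))), (3, 3, 3), schedule)
        with pytest.raises(ValueError):
            extract_roi_tac(img, np.zeros((2, 2, 1), dtype=bool))

    def test_phantom_blood_pool_recovers_input(self, schedule):
        from dtwpet.synthetic import simulate_phantom

        img, masks, _ = simulate_phantom(0, dims=(8, 8, 2), schedule=schedule)
        tac = extract_roi_tac(img, masks["blood"])
        expected = frame_average(feng_input(), schedule)
        assert np.allclose(tac.values, expected.values, rtol=1e-9)


class TestBuildPbIdif:
    def test_identical_normalised_curves(self, schedule, input_fn):
        tac = frame_average(input_fn, schedule)
        pb = build_pb_idif([tac, tac], np.array([200.0, 200.0]),
                           np.array([60.0, 60.0]))
        assert np.allclose(pb(tac.midpoints), tac.values / (200.0 / 60.0))

    def test_scaled_pair_averages(self, schedule, input_fn):
        tac = frame_average(input_fn, schedule)
        from dtwpet import TimeActivityCurve

        tac3 = TimeActivityCurve(schedule, 3.0 * tac.values)
        pb = build_pb_idif([tac, tac3], np.array([100.0, 100.0]),
                           np.array([50.0, 50.0]))
        assert np.allclose(pb(tac.midpoints), 2.0 * tac.values / 2.0)

    def test_population_mean_recovery(self):
        """PB-IDIF from 15 jittered subjects tracks the base bolus shape."""
        cohort = simulate_cohort(15, 123)
        pb = build_pb_idif(
            [s.idif_tac for s in cohort],
            np.array([s.dose_mbq for s in cohort]),
            np.array([s.weight_kg for s in cohort]),
        )
        base = frame_average(feng_input(), cohort[0].idif_tac.schedule)
        t = cohort[0].idif_tac.midpoints
        scale = np.mean(base.values[t > 10]) / np.mean(pb(t[t > 10]))
        # tail shape agreement within Monte-Carlo scatter of 15 subjects
        rel = (scale * pb(t[t > 5]) - base.values[t > 5]) / base.values[t > 5]
        assert np.abs(rel).max() < 0.15

    def test_too_few_subjects_raise(self, schedule, input_fn):
        tac = frame_average(input_fn, schedule)
        with pytest.raises(ValueError):
            build_pb_idif([tac], np.array([200.0]), np.array([60.0]))


class TestHybridIfDtw:
    def test_identity_bridge(self):
        s = simulate_subject(11)
        tac = s.idif_tac
        pb = _idif_as_if(tac)
        early = tac.subset(tac.midpoints <= 10)
        late = tac.subset(tac.midpoints >= 55)
        hyb, hp = hybrid_if_dtw(early, late, pb, 10, 55)
        assert hp.mu == pytest.approx(1.0, abs=1e-12)
        assert hp.gamma == pytest.approx(0.0, abs=1e-12)
        t = np.linspace(1, 59, 200)
        assert np.allclose(hyb(t), pb(t), rtol=1e-9, atol=1e-9)

    def test_pure_scaling(self):
        s = simulate_subject(11)
        tac = s.idif_tac
        pb2 = InputFunction(tac.midpoints, 2.0 * tac.values)
        early = tac.subset(tac.midpoints <= 10)
        late = tac.subset(tac.midpoints >= 55)
        _, hp = hybrid_if_dtw(early, late, pb2, 10, 55)
        assert hp.mu == pytest.approx(0.5, abs=1e-12)
        assert hp.gamma == pytest.approx(0.0, abs=1e-12)

    def test_continuity_at_joins(self):
        """Bridge joins the measured segments to machine tolerance."""
        cohort = simulate_cohort(16, 7)
        pb = build_pb_idif(
            [s.idif_tac for s in cohort[:15]],
            np.array([s.dose_mbq for s in cohort[:15]]),
            np.array([s.weight_kg for s in cohort[:15]]),
        )
        tac = cohort[15].idif_tac
        early = tac.subset(tac.midpoints <= 10)
        late = tac.subset(tac.midpoints >= 55)
        hyb, hp = hybrid_if_dtw(early, late, pb, 10, 55)
        eps = 1e-9
        for tj in (hp.t1, hp.t2):
            jump = abs(float(hyb(tj + eps)) - float(hyb(tj - eps)))
            assert jump < 1e-6 * max(float(hyb(tj)), 1.0)

    def test_nonnegative_and_auc_close(self):
        """Hybrid AUC lands within a few percent of the true IDIF AUC."""
        cohort = simulate_cohort(20, 31)
        pb = build_pb_idif(
            [s.idif_tac for s in cohort[:15]],
            np.array([s.dose_mbq for s in cohort[:15]]),
            np.array([s.weight_kg for s in cohort[:15]]),
        )
        for s in cohort[15:]:
            tac = s.idif_tac
            early = tac.subset(tac.midpoints <= 10)
            late = tac.subset(tac.midpoints >= 55)
            hyb, _ = hybrid_if_dtw(early, late, pb, 10, 55)
            assert np.all(hyb.values >= 0)
            true_auc = _idif_as_if(tac).auc(0, 60)
            assert hyb.auc(0, 60) == pytest.approx(true_auc, rel=0.07)


class TestScalePbifStatic:
    def test_alpha_identity(self):
        s = simulate_subject(11)
        tac = s.idif_tac
        pb = _idif_as_if(tac)
        _, hp = scale_pbif_static(tac.subset(tac.midpoints >= 50), pb)
        assert hp.alpha == pytest.approx(1.0, rel=1e-9)

    def test_alpha_inverse_scaling(self):
        s = simulate_subject(11)
        tac = s.idif_tac
        half = InputFunction(tac.midpoints, tac.values / 2.0)
        _, hp = scale_pbif_static(tac.subset(tac.midpoints >= 50), half)
        assert hp.alpha == pytest.approx(2.0, rel=1e-9)

    def test_fur_robust_to_pbif_shape(self):
        """FUR with the alpha-scaled curve stays close to FUR with the truth."""
        from dtwpet import fur

        cohort = simulate_cohort(18, 77)
        pb = build_pb_idif(
            [s.idif_tac for s in cohort[:15]],
            np.array([s.dose_mbq for s in cohort[:15]]),
            np.array([s.weight_kg for s in cohort[:15]]),
        )
        for s in cohort[15:]:
            static_if, _ = scale_pbif_static(s.idif_tac, pb)
            tac = model_tac(s.input_fn, CORTEX, s.idif_tac.schedule)
            f_true = fur(tac, _idif_as_if(s.idif_tac)).value
            f_est = fur(tac, static_if).value
            assert f_est == pytest.approx(f_true, rel=0.10)


class TestCorrectDelay:
    def test_zero_delay_recovered(self, schedule, input_fn):
        tac = model_tac(input_fn, CORTEX, schedule)
        res = correct_delay(tac, input_fn, range_s=30, step_s=10,
                            inits=[(0.1, 0.1, 0.05, 0.05)])
        assert res.delay_s == 0.0

    def test_known_shift_recovered(self, schedule, input_fn):
        shifted = input_fn.shifted(20 / 60)
        tac = model_tac(shifted, CORTEX, schedule)
        res = correct_delay(tac, input_fn, range_s=60, step_s=10,
                            inits=[(0.1, 0.1, 0.05, 0.05)])
        assert res.delay_s == pytest.approx(20.0, abs=10.0)
        assert res.objectives.min() == res.best_fit.weighted_rss

    def test_best_objective_on_grid(self, schedule, input_fn):
        tac = model_tac(input_fn.shifted(15 / 60), CORTEX, schedule)
        res = correct_delay(tac, input_fn, range_s=30, step_s=15,
                            inits=[(0.1, 0.1, 0.05, 0.05)])
        assert np.all(res.best_fit.weighted_rss <= res.objectives)

    def test_step_must_divide_range(self, schedule, input_fn):
        tac = model_tac(input_fn, CORTEX, schedule)
        with pytest.raises(ValueError):
            correct_delay(tac, input_fn, range_s=60, step_s=13)
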