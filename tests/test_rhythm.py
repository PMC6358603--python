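"""Ensemble-trace metrics: detrending, damped-cosine fits, peak estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhythmkit import rhythm, synthetic
from rhythmkit.rhythm import EstimationError, Trace


def _cosine_trace(period=24.0, phase=12.0, amp=100.0, baseline=200.0,
                  drift=0.0, duration=240.0, dt=0.1, **kw):
    t = np.arange(0, duration, dt)
    y = baseline + drift * t + amp * np.cos(2 * np.pi * (t - phase) / period)
    return Trace(t, y, **kw)


class TestDetrendRolling:
    def test_constant_trace_gives_zeros(self):
        tr = Trace(np.arange(0, 48, 0.1), np.full(480, 7.0))
        out = rhythm.detrend_rolling(tr)
        assert np.allclose(out.y, 0.0)

    def test_cosine_interior_preserved_vs_bruteforce(self):
        """A 24 h cosine survives 24 h baseline removal; the baseline matches
        a brute-force moving average."""
        tr = _cosine_trace(baseline=0.0)
        out = rhythm.detrend_rolling(tr, 24.0)
        inner = slice(240, -240)
        resid = out.y[inner] - tr.y[inner]
        assert np.sqrt(np.mean(resid ** 2)) < 0.01 * np.sqrt(np.mean(tr.y[inner] ** 2))
        # brute-force oracle for the centred moving average
        n = 240
        i = 1000
        lo, hi = i - n // 2, i - n // 2 + n
        assert tr.y[i] - np.mean(tr.y[lo:hi]) == pytest.approx(out.y[i], abs=1e-9)

    def test_linear_drift_removed(self):
        tr = _cosine_trace(baseline=0.0, drift=2.0)
        pure = _cosine_trace(baseline=0.0, drift=0.0)
        out = rhythm.detrend_rolling(tr, 24.0)
        inner = slice(240, -240)
        resid = out.y[inner] - pure.y[inner]
        assert np.sqrt(np.mean(resid ** 2)) < 0.02 * np.sqrt(np.mean(pure.y[inner] ** 2))

    def test_window_longer_than_trace_errors(self):
        tr = Trace(np.arange(0, 10, 0.1), np.zeros(100))
        with pytest.raises(ValueError):
            rhythm.detrend_rolling(tr, 24.0)


class TestFitFftnlls:
    def test_noiseless_cosine_recovered(self):
        tr = _cosine_trace(period=24.5, amp=100.0, duration=120.0)
        fit = rhythm.fit_fftnlls(tr)
        assert fit.period_h == pytest.approx(24.5, abs=0.01)
        assert fit.amplitude == pytest.approx(100.0, abs=0.1)
        assert fit.rae < 0.01
        assert not fit.arrhythmic

    def test_noiseless_agrees_with_grid_search_oracle(self):
        """Independent oracle: linear least squares of cos+sin+line on a dense
        period grid."""
        tr = _cosine_trace(period=24.5, duration=120.0)
        t, y = tr.t, tr.y
        best = (np.inf, None)
        for T in np.arange(23.5, 25.5, 0.005):
            X = np.column_stack([np.ones_like(t), t,
                                 np.cos(2 * np.pi * t / T),
                                 np.sin(2 * np.pi * t / T)])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(res[0]) if len(res) else float(
                np.sum((y - X @ beta) ** 2))
            if rss < best[0]:
                best = (rss, T)
        fit = rhythm.fit_fftnlls(tr)
        assert abs(fit.period_h - best[1]) < 0.05

    def test_noisy_period_within_tenth_hour(self):
        errs = []
        for seed in range(25):
            spec = synthetic.EnsembleSpec(noise_sd=20.0, period_h=24.5,
                                          duration_h=120.0, damping_rate=0.0,
                                          seed=seed)
            tr = synthetic.gen_ensemble_trace(spec).trace
            errs.append(rhythm.fit_fftnlls(tr).period_h - 24.5)
        assert np.max(np.abs(errs)) < 0.1

    def test_white_noise_flagged_arrhythmic(self):
        for seed in range(10):
            t = np.arange(0, 120, 0.1)
            y = np.random.default_rng(seed).normal(0, 20, len(t))
            fit = rhythm.fit_fftnlls(Trace(t, y))
            assert fit.rae >= 0.9 or fit.arrhythmic

    @settings(deadline=None, max_examples=20)
    @given(a=st.floats(0.5, 20.0), b=st.floats(-500.0, 500.0))
    def test_affine_invariance(self, a, b):
        """Period is invariant under y -> a*y + b (a > 0); amplitude scales."""
        tr = _cosine_trace(period=23.7, duration=120.0)
        fit0 = rhythm.fit_fftnlls(tr)
        fit1 = rhythm.fit_fftnlls(tr.replace(y=a * tr.y + b))
        assert fit1.period_h == pytest.approx(fit0.period_h, abs=1e-3)
        assert fit1.amplitude == pytest.approx(a * fit0.amplitude, rel=1e-3)

    def test_short_window_rejected(self):
        tr = _cosine_trace(duration=30.0)
        with pytest.raises(ValueError):
            rhythm.fit_fftnlls(tr)


class TestDetectPeaks:
    def test_matches_generator_ground_truth(self):
        spec = synthetic.EnsembleSpec(noise_sd=0.0, damping_rate=0.005,
                                      duration_h=240.0)
        res = synthetic.gen_ensemble_trace(spec)
        found = np.array([t for t, _ in rhythm.detect_peaks(res.trace)])
        truth = res.truth.peak_times_h
        # compare interior peaks (edges are biased by the baseline window)
        for pt in truth[1:-1]:
            assert np.min(np.abs(found - pt)) < 0.1

    def test_monotone_trace_has_no_peaks(self):
        t = np.arange(0, 100, 0.1)
        assert rhythm.detect_peaks(Trace(t, 2.0 * t)) == []
        assert rhythm.detect_peaks(Trace(t, np.exp(t / 40))) == []

    def test_two_cycles_give_two_peaks(self):
        tr = _cosine_trace(duration=48.0)
        assert len(rhythm.detect_peaks(tr)) == 2


class TestPhaseShift:
    def test_arithmetic_example_minus_four(self):
        """Observed peaks 4 h later than predicted read as a -4 h delay."""
        spec = synthetic.EnsembleSpec(noise_sd=0.0, treatment_time_h=106.0,
                                      d_phase_h=-4.0, duration_h=240.0)
        tr = synthetic.gen_ensemble_trace(spec).trace
        assert rhythm.phase_shift(tr) == pytest.approx(-4.0, abs=0.2)

    def test_null_shift_near_zero(self):
        spec = synthetic.EnsembleSpec(noise_sd=0.0, treatment_time_h=106.0,
                                      duration_h=240.0)
        tr = synthetic.gen_ensemble_trace(spec).trace
        assert abs(rhythm.phase_shift(tr)) < 0.2

    def test_recovery_under_noise(self):
        errs = []
        for seed in range(25):
            spec = synthetic.EnsembleSpec(noise_sd=10.0, treatment_time_h=106.0,
                                          d_phase_h=-4.0, duration_h=240.0,
                                          seed=seed)
            tr = synthetic.gen_ensemble_trace(spec).trace
            errs.append(rhythm.phase_shift(tr) + 4.0)
        assert np.mean(np.abs(errs)) < 0.3

    def test_equivariant_under_post_segment_shift(self):
        """Delaying every post-treatment sample by delta shifts the estimate
        by exactly -delta."""
        spec = synthetic.EnsembleSpec(noise_sd=0.0, treatment_time_h=106.0,
                                      duration_h=264.0)
        tr = synthetic.gen_ensemble_trace(spec).trace
        base = rhythm.phase_shift(tr)
        delta = 1.7
        f, _ = synthetic._ensemble_model(spec)
        y2 = np.where(tr.t < 106.0, tr.y, f(np.maximum(tr.t - delta, 106.0)))
        shifted = rhythm.phase_shift(Trace(tr.t, y2, treatment_time_h=106.0))
        assert shifted - base == pytest.approx(-delta, abs=0.02)

    def test_insufficient_peaks_error_names_side(self):
        spec = synthetic.EnsembleSpec(noise_sd=0.0, treatment_time_h=30.0,
                                      duration_h=120.0)
        tr = synthetic.gen_ensemble_trace(spec).trace
        with pytest.raises(EstimationError, match="pre"):
            rhythm.phase_shift(tr)


class TestFoldInduction:
    def test_geometric_worked_example(self):
        """Pre-peaks 100/90/81 extrapolate to 72.9; observed 109.35 is a
        1.5-fold induction."""
        t = np.arange(0, 240, 0.1)
        y = np.zeros_like(t)
        for pt, pv in [(12, 50), (36, 100), (60, 90), (84, 81),
                       (108, 109.35), (132, 60)]:
            y += pv * np.exp(-(t - pt) ** 2 / (2 * 2.5 ** 2))
        fold = rhythm.fold_induction(Trace(t, y, treatment_time_h=96.0))
        assert fold == pytest.approx(1.5, abs=0.01)

    def test_no_treatment_effect_is_unity(self):
        spec = synthetic.EnsembleSpec(noise_sd=0.0, damping_rate=0.0,
                                      treatment_time_h=106.0, duration_h=240.0)
        tr = synthetic.gen_ensemble_trace(spec).trace
        assert rhythm.fold_induction(tr) == pytest.approx(1.0, abs=0.01)

    def test_planted_fold_recovered_under_damping_and_noise(self):
        folds = []
        for seed in range(25):
            spec = synthetic.EnsembleSpec(noise_sd=10.0, damping_rate=0.01,
                                          treatment_time_h=106.0,
                                          induction_fold=1.5,
                                          duration_h=240.0, seed=seed)
            folds.append(rhythm.fold_induction(
                synthetic.gen_ensemble_trace(spec).trace))
        assert np.mean(folds) == pytest.approx(1.5, abs=0.1)

    def test_nonpositive_peak_rejected(self):
        t = np.arange(0, 240, 0.1)
        y = -50 + 10 * np.cos(2 * np.pi * (t - 12) / 24)
        with pytest.raises(EstimationError):
            rhythm.fold_induction(Trace(t, y, treatment_time_h=100.0))


class TestAcuteInductionArrhythmic:
    def test_constant_trace_is_zero(self):
        t = np.arange(0, 48, 0.1)
        tr = Trace(t, np.full_like(t, 5.0), treatment_time_h=24.0)
        assert rhythm.acute_induction_arrhythmic(tr) == pytest.approx(0.0)

    def test_step_on_normalised_scale(self):
        t = np.arange(0, 48, 0.1)
        y = np.where(t > 24.0, 1.0, 0.7)
        tr = Trace(t, y, treatment_time_h=24.0)
        assert rhythm.acute_induction_arrhythmic(tr) == pytest.approx(0.3)

    def test_monotone_in_planted_fold(self):
        vals = []
        for fold in (1.2, 1.5, 2.0):
            spec = synthetic.EnsembleSpec(amplitude=0.0, noise_sd=5.0,
                                          baseline=200.0, induction_fold=fold,
                                          treatment_time_h=106.0,
                                          duration_h=240.0, seed=2)
            tr = synthetic.gen_ensemble_trace(spec).trace
            vals.append(rhythm.acute_induction_arrhythmic(tr))
        assert vals[0] > 0
        assert vals[0] < vals[1] < vals[2]


class TestRmsChange:
    @staticmethod
    def _half_post_trace():
        spec = synthetic.EnsembleSpec(noise_sd=0.0, damping_rate=0.0,
                                      duration_h=240.0)
        tr = synthetic.gen_ensemble_trace(spec).trace
        y = np.where(tr.t < 106.0, tr.y, 200.0 + 0.5 * (tr.y - 200.0))
        return Trace(tr.t, y, treatment_time_h=106.0)

    def test_halving_post_oscillation_reads_minus_fifty(self):
        assert rhythm.rms_change(self._half_post_trace()) == pytest.approx(
            -50.0, abs=1.0)

    def test_unchanged_signal_reads_zero(self):
        spec = synthetic.EnsembleSpec(noise_sd=0.0, damping_rate=0.0,
                                      duration_h=240.0)
        tr = synthetic.gen_ensemble_trace(spec).trace
        tr = tr.replace(treatment_time_h=106.0)
        assert rhythm.rms_change(tr) == pytest.approx(0.0, abs=1.0)

    def test_invariant_to_overall_scaling(self):
        tr = self._half_post_trace()
        a = rhythm.rms_change(tr)
        b = rhythm.rms_change(tr.replace(y=3.5 * tr.y))
        assert a == pytest.approx(b, abs=1e-9)

    def test_noise_amplitude_loss_detected(self):
        """On an arrhythmic noisy trace, scaling down the noise after
        treatment lowers the RMS, more so for stronger scaling."""
        rng = np.random.default_rng(0)
        t = np.arange(0, 240, 0.1)
        base = rng.normal(0, 1.0, len(t))
        out = []
        for scale in (0.5, 0.1):
            y = 200.0 + np.where(t < 106.0, base, scale * base)
            out.append(rhythm.rms_change(Trace(t, y, treatment_time_h=106.0)))
        assert out[0] < 0 and out[1] < out[0]


class TestChanges:
    def test_identical_fits_zero_change(self):
        spec = synthetic.EnsembleSpec(noise_sd=0.0, duration_h=240.0)
        tr = synthetic.gen_ensemble_trace(spec).trace
        fit = rhythm.fit_fftnlls(tr, (0.0, 120.0))
        assert rhythm.amplitude_change(fit, fit) == pytest.approx(0.0)
        assert rhythm.period_change(fit, fit) == 0.0

    def test_planted_amplitude_scale_recovered(self):
        changes = []
        for seed in range(15):
            spec = synthetic.EnsembleSpec(noise_sd=10.0, amp_scale=0.1,
                                          treatment_time_h=106.0,
                                          duration_h=240.0, seed=seed)
            tr = synthetic.gen_ensemble_trace(spec).trace
            pre = rhythm.fit_fftnlls(tr, (10.0, 106.0))
            post = rhythm.fit_fftnlls(tr, (142.0, 238.0))
            changes.append(rhythm.amplitude_change(pre, post, 106.0))
        assert np.mean(changes) == pytest.approx(-90.0, abs=5.0)

    def test_planted_period_change_recovered(self):
        changes = []
        for seed in range(15):
            spec = synthetic.EnsembleSpec(noise_sd=10.0, d_period_h=1.5,
                                          treatment_time_h=106.0,
                                          duration_h=240.0, seed=seed)
            tr = synthetic.gen_ensemble_trace(spec).trace
            pre = rhythm.fit_fftnlls(tr, (10.0, 106.0))
            post = rhythm.fit_fftnlls(tr, (142.0, 238.0))
            changes.append(rhythm.period_change(pre, post))
        assert np.mean(changes) == pytest.approx(1.5, abs=0.1)


class TestCorrelateResponses:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = rhythm.correlate_responses(x, 2 * x)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_independent_vectors_uncorrelated(self):
        rng = np.random.default_rng(3)
        res = rhythm.correlate_responses(rng.normal(size=1000),
                                         rng.normal(size=1000))
        assert abs(res.pearson_r) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rhythm.correlate_responses(np.ones(5), np.arange(5.0))


class TestAnalyzeTreatment:
    def test_full_response_on_planted_effects(self):
        spec = synthetic.EnsembleSpec(noise_sd=5.0, treatment_time_h=106.0,
                                      d_phase_h=-4.0, d_period_h=1.5,
                                      amp_scale=0.5, induction_fold=1.5,
                                      duration_h=240.0, seed=11)
        tr = synthetic.gen_ensemble_trace(spec).trace
        resp = rhythm.analyze_treatment(tr)
        assert resp.phase_shift_h is not None
        assert resp.d_period_h == pytest.approx(1.5, abs=0.3)
        assert resp.fold_induction is not None and resp.fold_induction > 1.1
        assert resp.amplitude_change_pct == pytest.approx(-50.0, abs=10.0)
        d = resp.to_dict()
        assert set(d) >= {"phase_shift_h", "fold_induction", "d_period_h",
                          "amplitude_change_pct", "pre_fit", "post_fit"}
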