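"""Contrast computation, VEP averaging, peak/slope, transfer-function fit."""

import numpy as np
import pytest

from lfpstates.signals import TrialMatrix
from lfpstates.synth import vep_template
from lfpstates.vep import (DegenerateFitError, LuminancePair,
                           MichaelisMentenRegressor, NoCrossingError,
                           average_vep, fit_contrast_response,
                           gamma_response_ratio, michaelis_menten,
                           stimulus_contrast, vep_peak, vep_slope)

FS = 2000.0
SIX = np.array([100.0, 28.0, 5.7, 2.3, 1.8])  # nonzero standard contrasts


def tm_of(trials, contrasts=None, fs=FS):
    trials = np.asarray(trials, float)
    return TrialMatrix(trials, fs, (0.0, trials.shape[1] / fs),
                       np.arange(trials.shape[0], dtype=float), contrasts)


class TestStimulusContrast:
    anchors = dict(L_max=80.0, l_max=2.0, L_min=42.0, l_min=40.0)

    def test_highest_stimulus_scores_100(self):
        p = LuminancePair(L=80.0, l=2.0, **self.anchors)
        assert stimulus_contrast(p) == pytest.approx(100.0)

    def test_lowest_stimulus_scores_0(self):
        p = LuminancePair(L=42.0, l=40.0, **self.anchors)
        assert stimulus_contrast(p) == pytest.approx(0.0)

    def test_midway_ratio_scores_50(self):
        r_mid = 0.5 * (80.0 / 2.0 + 42.0 / 40.0)
        p = LuminancePair(L=r_mid * 10.0, l=10.0, **self.anchors)
        assert stimulus_contrast(p) == pytest.approx(50.0)

    def test_degenerate_calibration(self):
        with pytest.raises(ZeroDivisionError):
            stimulus_contrast(LuminancePair(L=4, l=2, L_max=4, l_max=2,
                                            L_min=8, l_min=4))


class TestAverageVEP:
    def test_identical_trials_average_is_any_trial(self):
        w = vep_template(FS, 1.0)
        tm = tm_of(np.tile(w, (130, 1)))
        v = average_vep(tm)
        assert np.allclose(v.waveform, w, rtol=0, atol=1e-13)
        assert v.n_trials == 130

    def test_low_trial_count_warns(self):
        tm = tm_of(np.zeros((100, 1000)))
        with pytest.warns(UserWarning, match="recommended"):
            average_vep(tm)

    def test_noise_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(0)
        w = -0.3 * vep_template(FS, 1.0)
        big = tm_of(w + rng.standard_normal((150, w.size)) * 0.1)
        small = tm_of(w + rng.standard_normal((10, w.size)) * 0.1)
        with pytest.warns(UserWarning):
            dev_small = np.std(average_vep(small).waveform - w)
        dev_big = np.std(average_vep(big).waveform - w)
        assert dev_big / dev_small == pytest.approx(np.sqrt(10 / 150), rel=0.3)

    def test_missing_contrast_rejected(self):
        tm = tm_of(np.zeros((4, 1000)), contrasts=[100.0] * 4)
        with pytest.raises(ValueError, match="no trials"):
            average_vep(tm, contrast=28.0)


class TestVepPeak:
    def test_flat_zero(self):
        amp, _, base = vep_peak(np.zeros(int(FS)), FS)
        assert amp == 0.0 and base == 0.0

    def test_known_trough_recovered(self):
        # the template's main lobe is negative; ×0.30 puts the trough at
        # −0.30 mV, 115 ms
        w = 0.30 * vep_template(FS, 1.0)
        amp, t_peak, base = vep_peak(w, FS)
        assert amp == pytest.approx(-0.30, abs=1e-9)
        assert t_peak == pytest.approx(0.115, abs=1.0 / FS)
        assert base == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_removed(self):
        amp, _, base = vep_peak(np.full(int(FS), 0.7), FS)
        assert amp == pytest.approx(0.0, abs=1e-12)
        assert base == pytest.approx(0.7)

    def test_short_waveform_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            vep_peak(np.zeros(400), FS)


class TestVepSlope:
    def test_pure_ramp_exact(self):
        # linear rise 0 -> peak between 80 and 200 ms, then plateau
        w = np.zeros(int(FS))
        i0, i1 = int(0.080 * FS), int(0.200 * FS)
        w[i0:i1] = np.linspace(0, -0.24, i1 - i0)
        w[i1:] = -0.24
        slope, t_half = vep_slope(w, FS)
        expected = -0.24 / 0.120
        assert slope == pytest.approx(expected, rel=0.02)

    def test_raised_cosine_half_peak_slope(self):
        # slow raised-cosine trough: -A/2·(1 − cos(2π(t−t0)/T)) with a
        # 200 ms rise, so the whole 80 ms window sits on the flank.  The
        # flank is odd-symmetric about the half-peak point, so the fitted
        # slope approaches the analytic derivative −Aπ/T there.
        A, t0_, T = 0.3, 0.085, 0.200
        t = np.arange(int(FS)) / FS
        w = np.zeros_like(t)
        m = (t >= t0_) & (t < t0_ + 2 * T)
        w[m] = -A / 2 * (1 - np.cos(np.pi * (t[m] - t0_) / T))
        slope, t_half = vep_slope(w, FS)
        assert t_half == pytest.approx(t0_ + T / 2, abs=2 / FS)
        assert slope == pytest.approx(-A * np.pi / (2 * T), rel=0.05)

    def test_flat_waveform_no_crossing(self):
        with pytest.raises(NoCrossingError):
            vep_slope(np.zeros(int(FS)), FS)


class TestContrastFit:
    def test_noiseless_exact_recovery(self):
        a = michaelis_menten(SIX, 0.30, 10.0)
        cr = fit_contrast_response(SIX, a)
        assert cr.A_max == pytest.approx(0.30, rel=1e-6)
        assert cr.K_50 == pytest.approx(10.0, rel=1e-6)
        assert cr.fit_rss < 1e-12

    def test_half_saturation_identity(self):
        cr = fit_contrast_response(SIX, michaelis_menten(SIX, 0.2, 7.0))
        assert cr.predict(np.array([cr.K_50]))[0] == pytest.approx(
            cr.A_max / 2, rel=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        a = michaelis_menten(SIX, 0.3, 12.0) * (1 + 0.05 * rng.standard_normal(5))
        c1 = fit_contrast_response(SIX, a)
        c2 = fit_contrast_response(SIX, 4.0 * a)
        assert c2.A_max == pytest.approx(4.0 * c1.A_max, rel=1e-6)
        assert c2.K_50 == pytest.approx(c1.K_50, rel=1e-6)

    def test_fitted_curve_monotone_through_origin(self):
        rng = np.random.default_rng(2)
        a = michaelis_menten(SIX, 0.3, 10.0) * (1 + 0.1 * rng.standard_normal(5))
        cr = fit_contrast_response(SIX, np.abs(a))
        k = np.linspace(0, 100, 300)
        y = cr.predict(k)
        assert y[0] == 0.0
        assert np.all(np.diff(y) >= 0)

    def test_noisy_k50_median_error(self):
        # 10% multiplicative noise: median relative K_50 error stays small
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(100):
            a = michaelis_menten(SIX, 0.3, 10.0) * (
                1 + 0.10 * rng.standard_normal(5))
            cr = fit_contrast_response(SIX, np.abs(a))
            errs.append(abs(cr.K_50 - 10.0) / 10.0)
        assert np.median(errs) <= 0.15

    def test_zero_amplitudes_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_contrast_response(SIX, np.zeros(5))

    def test_too_few_contrasts(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_contrast_response([10.0, 20.0], [0.1, 0.15])

    def test_estimator_api(self):
        reg = MichaelisMentenRegressor()
        assert "k50_starts" in reg.get_params()
        reg.fit(SIX, michaelis_menten(SIX, 0.3, 10.0))
        assert reg.predict([10.0])[0] == pytest.approx(0.15, rel=1e-6)
        assert reg.score(SIX, michaelis_menten(SIX, 0.3, 10.0)) > 0.999999


class TestGammaRatio:
    def _gamma_noise(self, rng, n):
        from scipy import signal as sps
        sos = sps.butter(4, (25, 80), btype="bandpass", fs=FS, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(n))
        return x / np.std(x)

    def test_tenfold_envelope_gives_ratio_one(self):
        rng = np.random.default_rng(0)
        n = int(FS)
        trials = []
        for _ in range(30):
            g = self._gamma_noise(rng, n)
            env = np.ones(n)
            env[int(0.090 * FS):int(0.500 * FS)] = 10.0
            trials.append(env * g)
        ratio = gamma_response_ratio(tm_of(np.array(trials)), band=None)
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_refiltering_smears_only_slightly(self):
        # same construction through the filtering path: the envelope step
        # bleeds a little into the baseline window, the ratio stays close
        rng = np.random.default_rng(10)
        n = int(FS)
        trials = []
        for _ in range(30):
            g = self._gamma_noise(rng, n)
            env = np.ones(n)
            env[int(0.090 * FS):int(0.500 * FS)] = 10.0
            trials.append(env * g)
        ratio = gamma_response_ratio(tm_of(np.array(trials)))
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_matched_windows_ratio_near_zero(self):
        rng = np.random.default_rng(1)
        trials = np.array([self._gamma_noise(rng, int(FS)) for _ in range(100)])
        ratio = gamma_response_ratio(tm_of(trials))
        assert abs(ratio) < 0.05

    def test_homogeneity_in_response_scale(self):
        rng = np.random.default_rng(2)
        n = int(FS)
        base = np.array([self._gamma_noise(rng, n) for _ in range(20)])
        scaled = base.copy()
        scaled[:, int(0.090 * FS):int(0.500 * FS)] *= 3.0
        r0 = gamma_response_ratio(tm_of(base), band=None)
        r1 = gamma_response_ratio(tm_of(scaled), band=None)
        assert r1 - r0 == pytest.approx(np.log10(3.0), abs=1e-9)

    def test_zero_baseline_trials_excluded(self):
        rng = np.random.default_rng(3)
        n = int(FS)
        good = self._gamma_noise(rng, n)
        bad = good.copy()
        bad[:int(0.080 * FS) + 1] = 0.0  # kill the baseline window
        with pytest.warns(UserWarning, match="excluding"):
            gamma_response_ratio(tm_of(np.array([good, bad])), band=None)
        with pytest.raises(ValueError, match="every trial"):
            gamma_response_ratio(tm_of(np.array([bad, bad])), band=None)
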