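"""Visual-evoked-potential averaging and contrast-gain analysis.

Trials are reversals of a contrast-reversing checkerboard; the VEP is the
trial average, its amplitude the extremum of the baseline-corrected
waveform in the 90–500 ms post-stimulus window (baseline = mean over
30–80 ms).  The contrast transfer function — amplitude versus stimulus
contrast — is fitted with the saturating Michaelis–Menten (Naka–Rushton,
exponent 1) form

    A(k) = A_max · k / (K_50 + k),

where A_max is the saturated amplitude and K_50 the half-saturating
contrast; a lower K_50 means the response saturates at lower contrast,
i.e. higher contrast gain.  Two further readouts quantify response
dynamics: the slope of a line fitted over an 80-ms window centered on the
half-peak crossing, and the mean log10 ratio of response-window to
baseline-window gamma RMS power across trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import signal as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .signals import TrialMatrix

__all__ = [
    "LuminancePair",
    "VEPResult",
    "ContrastResponse",
    "MichaelisMentenRegressor",
    "stimulus_contrast",
    "average_vep",
    "vep_peak",
    "vep_slope",
    "fit_contrast_response",
    "gamma_response_ratio",
    "michaelis_menten",
]

#: the standard six stimulus contrasts (%), maximum to blank
STANDARD_CONTRASTS = (100.0, 28.0, 5.7, 2.3, 1.8, 0.0)

BASELINE_WINDOW = (0.030, 0.080)   # s after the stimulus
RESPONSE_WINDOW = (0.090, 0.500)
SLOPE_WINDOW = 0.080
RECOMMENDED_TRIALS = (120, 180)


class NoCrossingError(ValueError):
    """No half-peak crossing exists on the rising flank."""


class DegenerateFitError(ValueError):
    """Contrast-response data cannot constrain the saturating model."""


@dataclass(frozen=True)
class LuminancePair:
    """Max/min luminance (cd/m²) of a stimulus plus calibration anchors.

    ``L``/``l`` describe the stimulus being scored; ``L_max``/``l_max``
    are the luminances of the highest-contrast stimulus of the session and
    ``L_min``/``l_min`` of the lowest (typically the blank).
    """

    L: float
    l: float  # noqa: E741 - field notation of the contrast formula
    L_max: float
    l_max: float
    L_min: float
    l_min: float

    def __post_init__(self) -> None:
        vals = (self.L, self.l, self.L_max, self.l_max, self.L_min, self.l_min)
        if any(v <= 0 for v in vals):
            raise ValueError("luminances must be positive")
        if self.L < self.l:
            raise ValueError("L must be the larger luminance of the pair")


@dataclass
class VEPResult:
    """Trial-averaged evoked waveform and its scalar readouts."""

    waveform: np.ndarray
    fs: float
    n_trials: int
    peak_amp: float = np.nan     # signed, baseline-corrected (mV)
    peak_time: float = np.nan    # s after stimulus
    baseline: float = np.nan     # mV
    slope: float = np.nan        # mV/s
    half_peak_time: float = np.nan


@dataclass
class ContrastResponse:
    """Per-contrast amplitudes with the fitted transfer function."""

    contrasts: np.ndarray
    amplitudes: np.ndarray
    A_max: float
    K_50: float
    fit_rss: float
    gamma_ratio: np.ndarray | None = None

    def predict(self, k: np.ndarray) -> np.ndarray:
        return michaelis_menten(np.asarray(k, dtype=float), self.A_max, self.K_50)


def michaelis_menten(k, a_max, k50):
    """Saturating contrast transfer function A(k) = A_max·k/(K_50 + k)."""
    k = np.asarray(k, dtype=float)
    return a_max * k / (k50 + k)


def stimulus_contrast(p: LuminancePair) -> float:
    """Session-normalized stimulus contrast K in percent.

    K = (L/l − L_min/l_min) / (L_max/l_max − L_min/l_min) · 100 %, i.e. the
    stimulus luminance ratio rescaled linearly so the session's lowest-
    contrast stimulus scores 0 % and the highest 100 %.
    """
    r = p.L / p.l
    r_min = p.L_min / p.l_min
    r_max = p.L_max / p.l_max
    denom = r_max - r_min
    if abs(denom) < 1e-12:
        raise ZeroDivisionError(
            "degenerate calibration: highest and lowest stimuli have the "
            "same luminance ratio")
    k = (r - r_min) / denom * 100.0
    if k < -1e-9 or k > 100.0 + 1e-9:
        warnings.warn(f"contrast {k:.3f}% outside [0, 100]; clipping",
                      stacklevel=2)
    return float(np.clip(k, 0.0, 100.0))


def average_vep(tm: TrialMatrix, contrast: float | None = None) -> VEPResult:
    """Point-wise trial average, optionally restricted to one contrast."""
    sel = tm if contrast is None else tm.select(contrast)
    if sel.n_trials == 0:
        raise ValueError(f"no trials at contrast {contrast}%")
    if sel.n_trials < 2:
        raise ValueError("need at least 2 trials to average")
    lo, hi = RECOMMENDED_TRIALS
    if not (lo <= sel.n_trials <= hi):
        warnings.warn(
            f"{sel.n_trials} trials is outside the recommended "
            f"{lo}–{hi} range", stacklevel=2)
    return VEPResult(sel.trials.mean(axis=0), fs=sel.fs,
                     n_trials=sel.n_trials)


def _win_slice(fs: float, lo: float, hi: float, n: int) -> slice:
    i0, i1 = int(round(lo * fs)), int(round(hi * fs))
    if i1 > n:
        raise ValueError(f"waveform too short: needs {hi} s post-stimulus")
    return slice(i0, i1)


def vep_peak(waveform: np.ndarray, fs: float) -> tuple[float, float, float]:
    """Baseline-corrected peak of an evoked waveform.

    Returns ``(peak_amp, peak_time, baseline)``: baseline is the mean over
    30–80 ms, the peak is the extremum of the absolute baseline-corrected
    deflection over 90–500 ms, and ``peak_amp`` is signed (mouse VEPs at
    layer II/III depth are typically negative); its magnitude is the
    amplitude.  Times are seconds after the stimulus.
    """
    w = np.asarray(waveform, dtype=float)
    base = float(w[_win_slice(fs, *BASELINE_WINDOW, n=w.size)].mean())
    rsl = _win_slice(fs, *RESPONSE_WINDOW, n=w.size)
    seg = w[rsl] - base
    i = int(np.argmax(np.abs(seg)))
    return float(seg[i]), (rsl.start + i) / fs, base


def vep_slope(waveform: np.ndarray, fs: float,
              peak_amp: float | None = None, peak_time: float | None = None,
              baseline: float | None = None) -> tuple[float, float]:
    """Slope of the VEP at half-peak, in mV/s.

    A line is least-squares fitted over an 80-ms window centered on the
    first crossing of ``baseline + peak_amp/2`` on the flank rising toward
    the peak (crossing time linearly interpolated between samples); the
    window is clipped at the peak time when it would extend past it.
    Returns ``(slope, half_peak_time)``.
    """
    w = np.asarray(waveform, dtype=float)
    if peak_amp is None or peak_time is None or baseline is None:
        peak_amp, peak_time, baseline = vep_peak(w, fs)
    if peak_amp == 0:
        raise NoCrossingError("flat waveform: no half-peak crossing")
    level = baseline + peak_amp / 2.0
    i0 = int(round(BASELINE_WINDOW[1] * fs))
    i1 = int(round(peak_time * fs))
    seg = w[i0:i1 + 1]
    sign = np.sign(peak_amp)
    above = sign * (seg - level) >= 0
    cross = np.nonzero(~above[:-1] & above[1:])[0]
    if above[0]:
        t_half = i0 / fs
    elif cross.size == 0:
        raise NoCrossingError(
            "no half-peak crossing between baseline window and peak")
    else:
        j = int(cross[0])
        y0, y1 = seg[j], seg[j + 1]
        frac = (level - y0) / (y1 - y0)
        t_half = (i0 + j + frac) / fs
    lo = t_half - SLOPE_WINDOW / 2.0
    hi = t_half + SLOPE_WINDOW / 2.0
    if hi > peak_time:
        warnings.warn("half-peak window clipped at the peak time",
                      stacklevel=2)
        hi = peak_time
    j0 = max(int(round(lo * fs)), 0)
    j1 = min(int(round(hi * fs)) + 1, w.size)
    if j1 - j0 < 2:
        raise NoCrossingError("slope window collapsed to fewer than 2 samples")
    t = np.arange(j0, j1) / fs
    slope = float(np.polyfit(t, w[j0:j1], 1)[0])
    return slope, float(t_half)


class MichaelisMentenRegressor(RegressorMixin, BaseEstimator):
    """Fit the saturating contrast transfer function A(k)=A_max·k/(K_50+k).

    Nonlinear least squares with bounds ``A_max ∈ (0, 10·max(A)]``,
    ``K_50 ∈ (0, 500]`` and five deterministic K_50 initializations; the
    start with the lowest residual sum of squares wins.  Zero-contrast
    points are excluded (the model forces A(0) = 0).  Fitted attributes:
    ``a_max_``, ``k50_``, ``rss_``.
    """

    def __init__(self, k50_starts: tuple = (1.0, 5.0, 15.0, 50.0, 150.0),
                 weights: np.ndarray | None = None):
        self.k50_starts = k50_starts
        self.weights = weights

    def fit(self, X, y) -> "MichaelisMentenRegressor":
        k = np.asarray(X, dtype=float).reshape(-1)
        a = np.asarray(y, dtype=float).reshape(-1)
        if k.shape != a.shape:
            raise ValueError("contrasts and amplitudes must align")
        nz = k > 0
        k, a = k[nz], a[nz]
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float).reshape(-1)[nz]
        else:
            w = np.ones_like(a)
        if np.unique(k).size < 3:
            raise ValueError("need >= 3 distinct nonzero contrasts")
        if (a < 0).any():
            raise ValueError("amplitudes must be nonnegative magnitudes")
        if np.max(a) <= 0:
            raise DegenerateFitError("all amplitudes are zero")

        def resid(theta):
            return (michaelis_menten(k, *theta) - a) * w

        a_hi = 10.0 * float(np.max(a))
        best = None
        for k50_0 in self.k50_starts:
            a0 = min(float(np.max(a)) * (1.0 + k50_0 / 100.0), a_hi)
            try:
                sol = optimize.least_squares(
                    resid, x0=[a0, k50_0],
                    bounds=([1e-12, 1e-9], [a_hi, 500.0]))
            except Exception:
                continue
            if sol.success or sol.status > 0:
                rss = float(np.sum(sol.fun ** 2))
                if best is None or rss < best[0]:
                    best = (rss, sol.x)
        if best is None:
            raise RuntimeError(
                "contrast-response fit failed from every initialization")
        self.rss_ = best[0]
        self.a_max_, self.k50_ = float(best[1][0]), float(best[1][1])
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "a_max_"):
            raise RuntimeError("regressor is not fitted")
        return michaelis_menten(np.asarray(X, dtype=float), self.a_max_,
                                self.k50_)


def fit_contrast_response(contrasts: np.ndarray, amplitudes: np.ndarray,
                          gamma_ratio: np.ndarray | None = None,
                          weights: np.ndarray | None = None
                          ) -> ContrastResponse:
    """Fit the Michaelis–Menten transfer function to per-contrast amplitudes.

    Returns the data together with (A_max, K_50) and the residual sum of
    squares of the best of five deterministic starts.
    """
    reg = MichaelisMentenRegressor(weights=weights).fit(contrasts, amplitudes)
    return ContrastResponse(
        contrasts=np.asarray(contrasts, dtype=float),
        amplitudes=np.asarray(amplitudes, dtype=float),
        A_max=reg.a_max_, K_50=reg.k50_, fit_rss=reg.rss_,
        gamma_ratio=None if gamma_ratio is None
        else np.asarray(gamma_ratio, dtype=float))


def gamma_response_ratio(tm: TrialMatrix,
                         band: tuple[float, float] | None = (25.0, 80.0),
                         order: int = 4) -> float:
    """Mean log10 ratio of response to baseline gamma RMS power.

    Per trial the gamma-band (25–80 Hz) filtered signal is reduced to its
    RMS inside the response (90–500 ms) and baseline (30–80 ms) windows;
    the base-10 log of their ratio is averaged across trials.  Trials with
    zero baseline RMS are excluded with a warning.

    Pass ``band=None`` when the trials were epoched from an already
    gamma-band-filtered recording: filtering the continuous trace once and
    epoching afterwards avoids the per-trial edge transients (and the
    backward smearing of response power into the baseline window) that
    zero-phase filtering of short trials introduces.
    """
    if tm.trials.shape[1] < int(round(RESPONSE_WINDOW[1] * tm.fs)):
        raise ValueError("trials must cover 0.5 s after the stimulus")
    if band is None:
        g = tm.trials
    else:
        sos = sps.butter(order, band, btype="bandpass", fs=tm.fs, output="sos")
        g = sps.sosfiltfilt(sos, tm.trials, axis=1)
    bsl = _win_slice(tm.fs, *BASELINE_WINDOW, n=g.shape[1])
    rsl = _win_slice(tm.fs, *RESPONSE_WINDOW, n=g.shape[1])
    rms_b = np.sqrt(np.mean(g[:, bsl] ** 2, axis=1))
    rms_r = np.sqrt(np.mean(g[:, rsl] ** 2, axis=1))
    ok = rms_b > 0
    if not ok.all():
        warnings.warn(f"excluding {np.count_nonzero(~ok)} trial(s) with zero "
                      "baseline gamma power", stacklevel=2)
    if not ok.any():
        raise ValueError("every trial has zero baseline gamma power")
    return float(np.mean(np.log10(rms_r[ok] / rms_b[ok])))
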