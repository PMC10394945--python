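"""Synthetic LFP and VEP sessions with known ground truth.

The slow-wave generator emulates the urethane-anesthesia resting state: an
alternating semi-Markov sequence of up and down states (gamma-distributed
durations), a state-locked slow deflection, amplitude-modulated band-
limited gamma noise (up-state gamma amplitude = ``gamma_gain`` × the
down-state level), a 1/f background, and optional 50 Hz line and
high-frequency (>100 Hz) contamination.

The VEP generator emulates a contrast-reversal session: back-to-back 1-s
trials (0.5 Hz checkerboard, one reversal per second) in shuffled contrast
order, each carrying a biphasic raised-cosine evoked template scaled by
the Michaelis–Menten transfer function A(k) = A_max·k/(K_50 + k) with
latency jitter, broadband 1/f noise, and a gamma-band component whose
response-window amplitude grows with the evoked response.

Genotype- and treatment-like presets encode only directions of effect
(e.g. longer up states, higher gamma gain, lower K_50 for the KO-like
preset); their magnitudes are testing conventions, not measured effect
sizes.  All outputs are pure functions of (config, seed): one global seed
is split into per-component child streams via ``numpy`` SeedSequence
spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .signals import Recording
from .vep import michaelis_menten

__all__ = [
    "SlowWaveConfig",
    "VEPConfig",
    "SlowWaveTruth",
    "VEPTruth",
    "simulate_slow_wave",
    "simulate_vep_session",
    "preset",
    "PRESETS",
    "vep_template",
    "boundary_match_fraction",
]


@dataclass(frozen=True)
class SlowWaveConfig:
    """Parameters of a synthetic slow-wave (resting-state) session."""

    fs: float = 2000.0
    span: float = 90.0
    us_dur: tuple[float, float] = (1.0, 4.0)   # (mean s, gamma shape)
    ds_dur: tuple[float, float] = (1.5, 4.0)
    gamma_gain: float = 3.0        # US gamma amplitude / DS gamma amplitude
    gamma_amp: float = 0.03        # DS-level gamma amplitude, mV RMS
    gamma_band: tuple[float, float] = (25.0, 80.0)
    slow_amp: float = 0.30         # state-locked slow deflection, mV
    pink_noise_amp: float = 0.05   # 1/f background, mV RMS
    hf_noise_amp: float = 0.0      # >100 Hz contamination, mV RMS
    line_50hz_amp: float = 0.0     # mains sinusoid amplitude, mV
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gamma_gain", "gamma_amp", "slow_amp",
                     "pink_noise_amp", "hf_noise_amp", "line_50hz_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.us_dur[0] <= 0 or self.ds_dur[0] <= 0:
            raise ValueError("state duration means must be positive")


@dataclass(frozen=True)
class VEPConfig:
    """Parameters of a synthetic contrast-reversal VEP session."""

    fs: float = 2000.0
    n_trials_per_contrast: int = 140
    contrasts: tuple[float, ...] = (100.0, 28.0, 5.7, 2.3, 1.8, 0.0)
    A_max: float = 0.30            # saturated VEP amplitude, mV
    K_50: float = 10.0             # half-saturating contrast, %
    trial_dur: float = 1.0         # s per reversal (0.5 Hz checkerboard)
    template_onset: float = 0.085  # s; evoked complex start
    template_width: float = 0.120  # s; full biphasic width
    latency_jitter_sd: float = 0.005
    noise_amp: float = 0.06        # broadband 1/f noise, mV RMS
    gamma_response_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A_max <= 0 or self.K_50 <= 0:
            raise ValueError("A_max and K_50 must be positive")
        if any(not (0.0 <= c <= 100.0) for c in self.contrasts):
            raise ValueError("contrasts must lie in [0, 100]%")


@dataclass
class SlowWaveTruth:
    """Ground truth of a slow-wave session."""

    intervals: list[tuple[float, float, str]]
    config: SlowWaveConfig

    def durations(self, label: str) -> np.ndarray:
        return np.array([e - s for s, e, lab in self.intervals if lab == label])

    def boundaries(self) -> np.ndarray:
        return np.array([s for s, _, _ in self.intervals[1:]])


@dataclass
class VEPTruth:
    """Ground truth of a VEP session."""

    event_times: np.ndarray
    contrasts: np.ndarray
    amplitudes: np.ndarray       # true per-trial evoked amplitude, mV
    latency_shifts: np.ndarray   # s, per trial
    config: VEPConfig


def _pink_noise(n: int, fs: float, rms: float, rng: np.random.Generator,
                f_min: float = 0.1) -> np.ndarray:
    """1/f-amplitude noise scaled to a target RMS."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    nz = f >= f_min
    shape[nz] = 1.0 / np.sqrt(f[nz])
    shape[~nz & (f > 0)] = 1.0 / np.sqrt(f_min)
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / np.sqrt(np.mean(x**2)))


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator, order: int = 4) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (Butterworth-shaped white noise).

    The shaping is applied in the frequency domain with the squared
    Butterworth magnitude — the spectrum of zero-phase (forward–backward)
    filtering — which is much faster than time-domain filtering on long
    traces and free of edge transients.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=f, fs=fs)
    x = np.fft.irfft(spec * np.abs(h) ** 2, n)
    return x / np.sqrt(np.mean(x**2))


def _cosine_gate(labels: np.ndarray, fs: float, ramp: float = 0.025
                 ) -> np.ndarray:
    """Smooth a 0/1 state indicator with short cosine ramps."""
    rn = int(round(ramp * fs))
    if rn < 2:
        return labels.astype(float)
    kern = 0.5 * (1 - np.cos(np.linspace(0, 2 * np.pi, 2 * rn + 1)))
    kern /= kern.sum()
    return np.convolve(labels.astype(float), kern, mode="same")


def simulate_slow_wave(cfg: SlowWaveConfig) -> tuple[Recording, SlowWaveTruth]:
    """Generate one resting-state session and its true state intervals.

    The trace starts in a down state; durations are drawn from gamma
    distributions (mean, shape) per state and the final interval is
    truncated so the intervals tile the span exactly.
    """
    cycle = cfg.us_dur[0] + cfg.ds_dur[0]
    if cfg.span < 5 * cycle:
        raise ValueError(
            f"span {cfg.span}s too short: need at least 5 mean cycles "
            f"({5 * cycle:.1f}s)")
    ss = np.random.SeedSequence(cfg.seed)
    rng_dur, rng_gamma, rng_pink, rng_hf = (
        np.random.default_rng(s) for s in ss.spawn(4))

    intervals: list[tuple[float, float, str]] = []
    t, label = 0.0, "DS"
    while t < cfg.span:
        mean, shape = cfg.ds_dur if label == "DS" else cfg.us_dur
        d = float(rng_dur.gamma(shape, mean / shape))
        end = min(t + d, cfg.span)
        intervals.append((t, end, label))
        t = end
        label = "US" if label == "DS" else "DS"

    n = int(round(cfg.span * cfg.fs))
    state = np.zeros(n)
    for s, e, lab in intervals:
        if lab == "US":
            state[int(round(s * cfg.fs)):int(round(e * cfg.fs))] = 1.0
    gate = _cosine_gate(state, cfg.fs)

    gamma_env = cfg.gamma_amp * (1.0 + (cfg.gamma_gain - 1.0) * gate)
    x = gamma_env * _band_noise(n, cfg.fs, cfg.gamma_band, rng_gamma)
    x += -cfg.slow_amp * gate          # up states are depolarized (negative)
    x += _pink_noise(n, cfg.fs, cfg.pink_noise_amp, rng_pink)
    if cfg.hf_noise_amp > 0:
        x += cfg.hf_noise_amp * _band_noise(
            n, cfg.fs, (100.0, min(500.0, 0.49 * cfg.fs)), rng_hf)
    if cfg.line_50hz_amp > 0:
        x += cfg.line_50hz_amp * np.sin(2 * np.pi * 50.0 * np.arange(n) / cfg.fs)

    rec = Recording(x, fs=cfg.fs, t0=0.0,
                    meta={"kind": "synthetic_slow_wave", "seed": cfg.seed})
    return rec, SlowWaveTruth(intervals, cfg)


def vep_template(fs: float, dur: float, onset: float = 0.085,
                 width: float = 0.120, after_lobe: float = 0.35) -> np.ndarray:
    """Biphasic raised-cosine evoked template with unit peak magnitude.

    A negative raised-cosine lobe over ``[onset, onset + width/2]`` (trough
    at ``onset + width/4``) followed by a smaller positive lobe over the
    second half-width.  Support sits inside the 90–500 ms response window
    and clear of the 30–80 ms baseline window at the default geometry.
    """
    t = np.arange(int(round(dur * fs))) / fs
    half = width / 2.0
    y = np.zeros_like(t)
    in1 = (t >= onset) & (t < onset + half)
    y[in1] = -0.5 * (1 - np.cos(2 * np.pi * (t[in1] - onset) / half))
    in2 = (t >= onset + half) & (t < onset + width)
    y[in2] = after_lobe * 0.5 * (1 - np.cos(2 * np.pi * (t[in2] - onset - half) / half))
    return y


def simulate_vep_session(cfg: VEPConfig
                         ) -> tuple[Recording, np.ndarray, np.ndarray, VEPTruth]:
    """Generate one VEP session.

    Returns ``(recording, event_times, contrasts, truth)``: a trace of
    back-to-back 1-s reversal trials in shuffled contrast order, the
    stimulus log (reversal time and contrast per trial), and the ground
    truth.  Per trial the template is scaled by A(contrast), shifted by
    Gaussian latency jitter, and embedded in 1/f noise plus a gamma-band
    component whose response-window amplitude is multiplied by
    ``1 + gamma_response_gain · A(k)/A_max``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_order, rng_jit, rng_noise, rng_gamma = (
        np.random.default_rng(s) for s in ss.spawn(4))

    order = np.repeat(np.asarray(cfg.contrasts, dtype=float),
                      cfg.n_trials_per_contrast)
    rng_order.shuffle(order)
    n_trials = order.size
    nt = int(round(cfg.trial_dur * cfg.fs))
    n = n_trials * nt
    amps = michaelis_menten(order, cfg.A_max, cfg.K_50)
    shifts = (rng_jit.standard_normal(n_trials) * cfg.latency_jitter_sd
              if cfg.latency_jitter_sd > 0 else np.zeros(n_trials))

    base = vep_template(cfg.fs, cfg.trial_dur, cfg.template_onset,
                        cfg.template_width)
    shift_n = np.round(shifts * cfg.fs).astype(int)
    trials = amps[:, None] * base[None, :]
    for s in np.unique(shift_n):
        if s != 0:
            rows = shift_n == s
            trials[rows] = np.roll(trials[rows], s, axis=1)
    x = trials.reshape(-1)

    if cfg.noise_amp > 0:
        x = x + _pink_noise(n, cfg.fs, cfg.noise_amp, rng_noise)
        # gamma-band component, response window scaled with the response
        g = _band_noise(n, cfg.fs, (25.0, 80.0), rng_gamma)
        env = np.full((n_trials, nt), 0.3 * cfg.noise_amp)
        r0, r1 = int(round(0.090 * cfg.fs)), int(round(0.500 * cfg.fs))
        env[:, r0:r1] *= (1.0 + cfg.gamma_response_gain
                          * amps[:, None] / cfg.A_max)
        x = x + env.reshape(-1) * g

    events = np.arange(n_trials) * cfg.trial_dur
    rec = Recording(x, fs=cfg.fs, t0=0.0,
                    meta={"kind": "synthetic_vep", "seed": cfg.seed})
    truth = VEPTruth(events, order, amps, shifts, cfg)
    return rec, events, order, truth


#: named parameter bundles; magnitudes are testing conventions that encode
#: only the direction of the corresponding physiological effects
PRESETS = ("wt", "shank3_ko_like", "pv_cko_like",
           "midazolam_like", "ganaxolone_like")


def preset(name: str, seed: int = 0) -> tuple[SlowWaveConfig, VEPConfig]:
    """Parameter bundle for a genotype- or treatment-like condition.

    ``wt`` is the reference.  ``shank3_ko_like``: up states 1.5× longer,
    gamma gain ×1.3, K_50 halved (faster saturation).  ``pv_cko_like``:
    slow deflection ×1.4 (larger up-state amplitude) with added >100 Hz
    noise.  ``midazolam_like``/``ganaxolone_like``: reverted to the
    reference values (treatment-like rescue).
    """
    sw = SlowWaveConfig(seed=seed)
    vp = VEPConfig(seed=seed)
    if name in ("wt", "midazolam_like", "ganaxolone_like"):
        return sw, vp
    if name == "shank3_ko_like":
        return (replace(sw, us_dur=(sw.us_dur[0] * 1.5, sw.us_dur[1]),
                        gamma_gain=sw.gamma_gain * 1.3),
                replace(vp, K_50=vp.K_50 * 0.5))
    if name == "pv_cko_like":
        return (replace(sw, slow_amp=sw.slow_amp * 1.4, hf_noise_amp=0.03),
                vp)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")


def boundary_match_fraction(true_bounds: np.ndarray,
                            detected_bounds: np.ndarray,
                            tol: float) -> float:
    """Fraction of true state boundaries with a detected one within ±tol."""
    true_bounds = np.asarray(true_bounds, dtype=float)
    detected_bounds = np.sort(np.asarray(detected_bounds, dtype=float))
    if true_bounds.size == 0:
        return 1.0
    if detected_bounds.size == 0:
        return 0.0
    idx = np.searchsorted(detected_bounds, true_bounds)
    best = np.full(true_bounds.size, np.inf)
    for off in (-1, 0):
        j = np.clip(idx + off, 0, detected_bounds.size - 1)
        best = np.minimum(best, np.abs(detected_bounds[j] - true_bounds))
    return float(np.mean(best <= tol))
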