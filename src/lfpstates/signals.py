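"""Core signal containers and operations shared by every analysis stage.

The unit conventions follow common practice for cortical LFP work: voltages
are millivolts, times are seconds, and the default acquisition rate is
2 kHz.  Time-resolved gamma power is the sliding-window RMS of the
band-passed trace; the default geometry (250 ms windows advancing by
100 ms, i.e. 150 ms shared between consecutive windows) is the standard
setting for slow-wave up/down-state work under urethane anesthesia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "PowerTrace",
    "TrialMatrix",
    "bandpass",
    "highpass_lowpass",
    "notch",
    "sliding_rms",
    "epoch",
]

GAMMA_BAND = (25.0, 80.0)
BROADBAND = (0.1, 200.0)


class InvalidBandError(ValueError):
    """Requested filter band is outside (0, Nyquist)."""


class TooShortError(ValueError):
    """Trace too short for the requested operation."""


class WindowGeometryError(ValueError):
    """Sliding-window width/overlap combination is impossible."""


class EventBoundsError(ValueError):
    """One or more epoching events fall outside the recording."""


@dataclass
class Recording:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples : array of float
        Voltage samples in mV.
    fs : float
        Sampling rate in Hz (default 2000).
    t0 : float
        Time of the first sample in seconds.
    meta : dict
        Free-form metadata (subject id, condition label, units...).
    """

    samples: np.ndarray
    fs: float = 2000.0
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise TooShortError("a recording needs at least 2 samples")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, ``n / fs`` seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "Recording":
        return Recording(samples, fs=self.fs, t0=self.t0, meta=dict(self.meta))


@dataclass
class PowerTrace:
    """Time-resolved RMS power with its window geometry.

    ``values[i]`` is the RMS (mV) of the source trace over the window
    centered at ``centers[i]``; consecutive windows are ``step`` seconds
    apart and ``width`` seconds wide.
    """

    values: np.ndarray
    centers: np.ndarray
    width: float
    step: float
    band: tuple[float, float] = GAMMA_BAND

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.values.shape != self.centers.shape:
            raise ValueError("values and centers must align")
        if (self.values < 0).any():
            raise ValueError("RMS values must be nonnegative")
        if not (self.step > 0):
            raise WindowGeometryError("step must be positive")
        if self.centers.size > 1:
            d = np.diff(self.centers)
            if (d <= 0).any() or not np.allclose(d, self.step, rtol=1e-6):
                raise ValueError("centers must increase in uniform steps")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def span(self) -> tuple[float, float]:
        """Half-open time span tiled by the windows, boundary at step/2."""
        return (self.centers[0] - self.step / 2.0,
                self.centers[-1] + self.step / 2.0)


@dataclass
class TrialMatrix:
    """Event-aligned trial slices of a recording (rows = trials)."""

    trials: np.ndarray
    fs: float
    window: tuple[float, float]
    event_times: np.ndarray
    contrasts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=np.float64))
        self.event_times = np.asarray(self.event_times, dtype=np.float64)
        if self.trials.shape[0] != self.event_times.size:
            raise ValueError("one event time per trial row required")
        if self.contrasts is not None:
            self.contrasts = np.asarray(self.contrasts, dtype=np.float64)
            if self.contrasts.size != self.trials.shape[0]:
                raise ValueError("one contrast per trial required")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def rel_times(self) -> np.ndarray:
        """Sample times relative to the aligning event."""
        pre, _post = self.window
        return -pre + np.arange(self.trials.shape[1]) / self.fs

    def select(self, contrast: float, atol: float = 1e-6) -> "TrialMatrix":
        if self.contrasts is None:
            raise ValueError("trial matrix carries no contrast labels")
        mask = np.isclose(self.contrasts, contrast, atol=atol)
        return TrialMatrix(self.trials[mask], self.fs, self.window,
                           self.event_times[mask], self.contrasts[mask])


def _check_band(low: float, high: float, fs: float) -> None:
    if not (0.0 < low < high < fs / 2.0):
        raise InvalidBandError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )


def bandpass(rec: Recording, low: float = GAMMA_BAND[0],
             high: float = GAMMA_BAND[1], order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of a recording.

    Forward–backward (``filtfilt``) filtering preserves the timing of
    state transitions; the effective magnitude response is the squared
    response of a Butterworth of the given order.
    """
    _check_band(low, high, rec.fs)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if rec.n <= 3 * padlen:
        raise TooShortError(
            f"trace of {rec.n} samples too short for filter warm-up ({3 * padlen})"
        )
    return rec.replace_samples(sps.sosfiltfilt(sos, rec.samples))


def highpass_lowpass(rec: Recording, low: float = BROADBAND[0],
                     high: float = BROADBAND[1], order: int = 4) -> Recording:
    """Broadband conditioning filter (default 0.1–200 Hz), zero phase."""
    return bandpass(rec, low, high, order=order)


def notch(rec: Recording, freq: float = 50.0, q: float = 30.0) -> Recording:
    """Optional 50 Hz line-noise notch (second-order IIR), zero phase.

    Off by default in the pipeline: bench hardware normally removes mains
    interference before digitization.
    """
    if not (0.0 < freq < rec.fs / 2.0):
        raise InvalidBandError("notch frequency outside (0, Nyquist)")
    b, a = sps.iirnotch(freq, q, fs=rec.fs)
    return rec.replace_samples(sps.filtfilt(b, a, rec.samples))


def sliding_rms(rec: Recording, width: float = 0.250,
                overlap: float = 0.150) -> PowerTrace:
    """Short-time RMS power on a moving window.

    ``overlap`` is the stretch shared by consecutive windows, so the hop is
    ``width − overlap`` (100 ms by default).  Windows are fully interior:
    a trailing partial window is discarded, no padding is applied.
    """
    if not (width > overlap >= 0.0):
        raise WindowGeometryError("need width > overlap >= 0")
    wn = int(round(width * rec.fs))
    hop = int(round((width - overlap) * rec.fs))
    if wn < 1 or hop < 1:
        raise WindowGeometryError("window or step below one sample")
    if rec.n < wn:
        raise TooShortError("recording shorter than one window")
    n_win = (rec.n - wn) // hop + 1
    starts = np.arange(n_win) * hop
    idx = starts[:, None] + np.arange(wn)[None, :]
    vals = np.sqrt(np.mean(rec.samples[idx] ** 2, axis=1))
    centers = rec.t0 + (starts + wn / 2.0) / rec.fs
    band = rec.meta.get("band", GAMMA_BAND)
    return PowerTrace(vals, centers, width=wn / rec.fs, step=hop / rec.fs,
                      band=tuple(band))


def epoch(rec: Recording, events: np.ndarray, pre: float, post: float,
          contrasts: np.ndarray | None = None,
          on_out_of_bounds: str = "raise") -> TrialMatrix:
    """Slice event-aligned trials ``[event − pre, event + post)`` from a trace.

    Parameters
    ----------
    on_out_of_bounds : {"raise", "drop"}
        What to do with events whose window leaves the recording: fail with
        the offending list, or drop them (a note is stored on the result).
    """
    events = np.asarray(events, dtype=np.float64)
    if contrasts is not None:
        contrasts = np.asarray(contrasts, dtype=np.float64)
        if contrasts.size != events.size:
            raise ValueError("one contrast per event required")
    if pre < 0 or post <= 0:
        raise ValueError("need pre >= 0 and post > 0")
    n_samp = int(round((pre + post) * rec.fs))
    start_idx = np.round((events - pre - rec.t0) * rec.fs).astype(int)
    ok = (start_idx >= 0) & (start_idx + n_samp <= rec.n)
    if not ok.all():
        bad = events[~ok]
        if on_out_of_bounds == "raise":
            raise EventBoundsError(
                f"{bad.size} event(s) out of bounds: {bad[:10].tolist()}"
            )
        events, start_idx = events[ok], start_idx[ok]
        if contrasts is not None:
            contrasts = contrasts[ok]
    idx = start_idx[:, None] + np.arange(n_samp)[None, :]
    return TrialMatrix(rec.samples[idx], rec.fs, (pre, post), events, contrasts)
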