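"""Up/down-state segmentation from time-resolved gamma power.

Under urethane anesthesia the cortical LFP alternates between up states
(depolarized, rich in 25–80 Hz gamma activity) and quiescent down states.
The log10 of the sliding-window gamma RMS power is therefore bimodal; a
two-component Gaussian mixture is fitted to it and the classification
threshold is placed where the expected misclassification under the fitted
mixture — false positives plus false negatives, i.e. the point a ROC
analysis of the two fitted densities selects at equal costs — is minimal.
Threshold crossings are turned into alternating intervals and runs shorter
than a minimum duration (100 ms by default) are absorbed into the ongoing
opposite state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture

from .signals import PowerTrace, Recording, bandpass, highpass_lowpass

__all__ = [
    "BimodalFit",
    "StateSegmentation",
    "StateMetrics",
    "UpStateDetector",
    "fit_bimodal",
    "histogram_bimodal_fit",
    "refine_boundaries",
    "roc_threshold",
    "segment_states",
    "state_metrics",
    "UnimodalDistributionError",
    "LowSeparationWarning",
]

US, DS = "US", "DS"

#: below this mixture separation the distribution is treated as unimodal
MIN_SEPARATION = 1.0
#: below this separation the fit converges but segmentation is unreliable
WARN_SEPARATION = 2.0


class UnimodalDistributionError(ValueError):
    """Log-power distribution is effectively unimodal; segmentation unsafe."""


class NonConvergenceError(RuntimeError):
    """Mixture EM failed to converge."""


class LowSeparationWarning(UserWarning):
    """Modes are distinguishable but poorly separated."""


@dataclass
class BimodalFit:
    """Two-component Gaussian fit of log10 gamma power plus its threshold.

    The low component describes down states, the high component up states.
    ``separation`` is |mu_hi − mu_lo| over the weight-pooled standard
    deviation; values below ~2 mean the modes overlap substantially.
    """

    mu_lo: float
    sigma_lo: float
    w_lo: float
    mu_hi: float
    sigma_hi: float
    w_hi: float
    threshold: float
    separation: float
    converged: bool
    sse: float

    def __post_init__(self) -> None:
        if self.sigma_lo <= 0 or self.sigma_hi <= 0:
            raise ValueError("component sigmas must be positive")
        if abs(self.w_lo + self.w_hi - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if self.mu_lo > self.mu_hi:
            raise ValueError("components must be ordered by mean")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.w_lo * stats.norm.pdf(x, self.mu_lo, self.sigma_lo)
                + self.w_hi * stats.norm.pdf(x, self.mu_hi, self.sigma_hi))

    def misclassification(self, t: np.ndarray) -> np.ndarray:
        """Expected error rate of threshold t under the fitted mixture."""
        t = np.asarray(t, dtype=float)
        fp = self.w_lo * stats.norm.sf(t, self.mu_lo, self.sigma_lo)
        fn = self.w_hi * stats.norm.cdf(t, self.mu_hi, self.sigma_hi)
        return fp + fn


@dataclass
class StateSegmentation:
    """Alternating, gap-free US/DS intervals tiling the analyzed span."""

    intervals: list[tuple[float, float, str]]
    min_dur: float = 0.100
    source_step: float = 0.100

    def __post_init__(self) -> None:
        labels = [lab for _, _, lab in self.intervals]
        for a, b in zip(labels, labels[1:]):
            if a == b:
                raise ValueError("interval labels must alternate")
        for s, e, _ in self.intervals:
            if e <= s:
                raise ValueError("intervals must have positive length")

    @property
    def span(self) -> tuple[float, float]:
        return (self.intervals[0][0], self.intervals[-1][1])

    def durations(self, label: str) -> np.ndarray:
        return np.array([e - s for s, e, lab in self.intervals if lab == label])

    def boundaries(self) -> np.ndarray:
        """Interior state-transition times."""
        return np.array([s for s, _, _ in self.intervals[1:]])


@dataclass
class StateMetrics:
    """Per-recording up/down-state summary statistics."""

    us_durations: np.ndarray
    ds_durations: np.ndarray
    us_frequency: float
    us_amplitude_median: float
    us_gamma_rms: np.ndarray
    span: float
    n_us: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_us = int(np.size(self.us_durations))


def _mixture_n_modes(fit: BimodalFit, n_grid: int = 2001) -> int:
    """Count local maxima of the fitted mixture density on a fine grid."""
    lo = fit.mu_lo - 4 * fit.sigma_lo
    hi = fit.mu_hi + 4 * fit.sigma_hi
    x = np.linspace(lo, hi, n_grid)
    y = fit.pdf(x)
    interior = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    return int(np.count_nonzero(interior))


class UpStateDetector(ClassifierMixin, BaseEstimator):
    """Classify power-trace samples into up/down states.

    ``fit`` learns a two-component Gaussian mixture on the log10 RMS power
    and places the equal-cost ROC threshold between the component means;
    ``predict`` labels samples (1 = up state, 0 = down state).  Use
    :func:`segment_states` (or :meth:`segment`) to turn labels into
    duration-filtered intervals.

    Parameters
    ----------
    min_dur : float
        Minimum state duration in seconds; shorter runs are merged into
        the ongoing opposite state.
    n_init : int
        Number of EM restarts (k-means++-style initialization).
    check_unimodal : bool
        If True (default), refuse to fit effectively unimodal
        distributions instead of returning a meaningless split.
    random_state : int or None
        Seed for the EM restarts.
    """

    def __init__(self, min_dur: float = 0.100, n_init: int = 5,
                 check_unimodal: bool = True, random_state: int | None = 0):
        self.min_dur = min_dur
        self.n_init = n_init
        self.check_unimodal = check_unimodal
        self.random_state = random_state

    # -- sklearn plumbing ------------------------------------------------
    def _log_values(self, X) -> np.ndarray:
        if isinstance(X, PowerTrace):
            vals = X.values
        else:
            vals = np.asarray(X, dtype=float).reshape(-1)
        if vals.size < 200:
            raise ValueError("need at least 200 power values to fit")
        if (vals <= 0).any():
            raise ValueError("power values must be positive (log10 is taken)")
        return np.log10(vals)

    def fit(self, X, y=None) -> "UpStateDetector":
        """Fit the bimodal model on RMS power values (or a PowerTrace)."""
        logx = self._log_values(X)[:, None]
        gm = GaussianMixture(n_components=2, n_init=self.n_init,
                             random_state=self.random_state)
        gm.fit(logx)
        if not gm.converged_:
            raise NonConvergenceError(
                f"EM did not converge after {gm.n_iter_} iterations "
                f"(lower bound {gm.lower_bound_:.4g})"
            )
        mus = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        ws = gm.weights_.ravel()
        order = np.argsort(mus)
        mu_lo, mu_hi = mus[order]
        sd_lo, sd_hi = sds[order]
        w_lo, w_hi = ws[order]
        pooled = np.sqrt(w_lo * sd_lo**2 + w_hi * sd_hi**2)
        separation = (mu_hi - mu_lo) / pooled
        # residual of the fitted density against a histogram, as a fit
        # quality diagnostic (EM itself maximizes likelihood)
        hist, edges = np.histogram(logx.ravel(), bins=50, density=True)
        mids = 0.5 * (edges[:-1] + edges[1:])
        fit = BimodalFit(mu_lo, sd_lo, w_lo, mu_hi, sd_hi, w_hi,
                         threshold=0.5 * (mu_lo + mu_hi),
                         separation=float(separation), converged=True,
                         sse=float(np.sum((hist - _mix_pdf(mids, mu_lo, sd_lo, w_lo,
                                                           mu_hi, sd_hi, w_hi)) ** 2)))
        if self.check_unimodal:
            gm1 = GaussianMixture(n_components=1).fit(logx)
            bic_prefers_one = gm1.bic(logx) <= gm.bic(logx)
            if (separation < MIN_SEPARATION or bic_prefers_one
                    or _mixture_n_modes(fit) < 2):
                raise UnimodalDistributionError(
                    "log-power distribution is effectively unimodal "
                    f"(separation {separation:.2f}); up/down segmentation "
                    "would be arbitrary — do not segment this trace"
                )
        if separation < WARN_SEPARATION:
            warnings.warn(
                f"mixture separation {separation:.2f} < {WARN_SEPARATION}: "
                "modes overlap, state boundaries will be noisy",
                LowSeparationWarning, stacklevel=2)
        fit.threshold = roc_threshold(fit)
        self.fit_ = fit
        self.threshold_ = fit.threshold
        self.separation_ = fit.separation
        return self

    def predict(self, X) -> np.ndarray:
        """Label power samples: 1 for up state, 0 for down state."""
        if not hasattr(self, "fit_"):
            raise RuntimeError("detector is not fitted")
        if isinstance(X, PowerTrace):
            logx = np.log10(X.values)
        else:
            logx = np.log10(np.asarray(X, dtype=float).reshape(-1))
        return (logx >= self.threshold_).astype(int)

    def segment(self, p: PowerTrace) -> StateSegmentation:
        if not hasattr(self, "fit_"):
            raise RuntimeError("detector is not fitted")
        return segment_states(p, self.threshold_, min_dur=self.min_dur)


def _mix_pdf(x, mu1, sd1, w1, mu2, sd2, w2):
    return (w1 * stats.norm.pdf(x, mu1, sd1) + w2 * stats.norm.pdf(x, mu2, sd2))


def fit_bimodal(p: PowerTrace | np.ndarray, n_init: int = 5,
                random_state: int | None = 0,
                check_unimodal: bool = True) -> BimodalFit:
    """Fit a two-Gaussian mixture to log10 RMS power and set its threshold.

    Returns the ordered component parameters, the equal-cost ROC threshold,
    and a separation diagnostic.  Raises
    :class:`UnimodalDistributionError` when the distribution has no usable
    second mode (unless ``check_unimodal=False``).
    """
    det = UpStateDetector(n_init=n_init, random_state=random_state,
                          check_unimodal=check_unimodal)
    det.fit(p)
    return det.fit_


def histogram_bimodal_fit(p: PowerTrace | np.ndarray, bins: int = 50,
                          random_state: int | None = 0) -> BimodalFit:
    """Least-squares double-Gaussian fit to the log-power histogram.

    Diagnostic cross-check for :func:`fit_bimodal`: fits the sum of two
    Gaussian densities to a normalized histogram instead of maximizing the
    likelihood.  Bin-width sensitive; the EM fit is the primary method.
    """
    from scipy.optimize import curve_fit

    if isinstance(p, PowerTrace):
        vals = p.values
    else:
        vals = np.asarray(p, dtype=float).reshape(-1)
    logx = np.log10(vals)
    hist, edges = np.histogram(logx, bins=bins, density=True)
    mids = 0.5 * (edges[:-1] + edges[1:])

    def model(x, w1, m1, s1, m2, s2):
        return _mix_pdf(x, m1, abs(s1), w1, m2, abs(s2), 1.0 - w1)

    lo, hi = np.percentile(logx, [10, 90])
    sd0 = np.std(logx) / 2
    popt, _ = curve_fit(model, mids, hist, p0=[0.5, lo, sd0, hi, sd0],
                        bounds=([0.01, mids[0], 1e-4, mids[0], 1e-4],
                                [0.99, mids[-1], 5.0, mids[-1], 5.0]),
                        maxfev=20_000)
    w1, m1, s1, m2, s2 = popt
    s1, s2 = abs(s1), abs(s2)
    if m1 > m2:
        m1, m2, s1, s2, w1 = m2, m1, s2, s1, 1.0 - w1
    pooled = np.sqrt(w1 * s1**2 + (1 - w1) * s2**2)
    resid = hist - model(mids, *popt)
    fit = BimodalFit(m1, s1, w1, m2, s2, 1.0 - w1,
                     threshold=0.5 * (m1 + m2),
                     separation=float((m2 - m1) / pooled), converged=True,
                     sse=float(np.sum(resid**2)))
    fit.threshold = roc_threshold(fit)
    return fit


def roc_threshold(fit: BimodalFit) -> float:
    """Equal-cost ROC threshold of a fitted bimodal model.

    Minimizes ``w_lo·P(X_lo > t) + w_hi·P(X_hi < t)`` — the sum of false
    positives and false negatives under the fitted mixture — by a fine
    grid sweep over [mu_lo, mu_hi] followed by bounded polishing.  For
    equal weights and sigmas this is exactly the midpoint of the means.
    """
    if fit.sigma_lo < 1e-12 or fit.sigma_hi < 1e-12:
        raise FloatingPointError("degenerate fit: component sigma ~ 0")
    if fit.mu_hi - fit.mu_lo < 1e-12:
        return 0.5 * (fit.mu_lo + fit.mu_hi)
    grid = np.linspace(fit.mu_lo, fit.mu_hi, 4001)
    cost = fit.misclassification(grid)
    i = int(np.argmin(cost))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(fit.misclassification, bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    t = float(res.x)
    return float(np.clip(t, fit.mu_lo, fit.mu_hi))


def _runs(labels: np.ndarray) -> list[list]:
    """Maximal runs of equal labels as mutable [label, count] pairs."""
    runs: list[list] = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([int(lab), 1])
    return runs


def _merge_short_runs(runs: list[list], min_samples_dur: float,
                      step: float) -> list[list]:
    """Absorb runs shorter than the cutoff into the ongoing opposite state.

    Chronological scan, repeated to a fixed point: the earliest run with
    duration strictly below the cutoff flips to its neighbours' label and
    is fused (edge runs take their single neighbour's label).
    """
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        for i, (lab, cnt) in enumerate(runs):
            if cnt * step < min_samples_dur:
                runs[i][0] = runs[i - 1][0] if i > 0 else runs[i + 1][0]
                merged: list[list] = []
                for r in runs:
                    if merged and merged[-1][0] == r[0]:
                        merged[-1][1] += r[1]
                    else:
                        merged.append(r)
                runs = merged
                break
        else:
            break
    return runs


def segment_states(p: PowerTrace, threshold: float,
                   min_dur: float = 0.100) -> StateSegmentation:
    """Binarize a power trace at a log10 threshold and build state intervals.

    Samples with log10 power at or above the threshold are up-state;
    maximal runs shorter than ``min_dur`` (strict comparison, duration =
    run length × step) are reassigned to the ongoing opposite state,
    chronologically and repeatedly until stable.  The resulting intervals
    alternate, tile the span of the power trace, and are half-open
    ``[start, end)`` in seconds.
    """
    logx = np.log10(p.values)
    labels = (logx >= threshold).astype(int)
    if labels.min() == labels.max():
        warnings.warn("all samples on one side of the threshold: "
                      "returning a single full-span state", stacklevel=2)
    runs = _merge_short_runs(_runs(labels), min_dur, p.step)
    start, _ = p.span
    intervals = []
    for lab, cnt in runs:
        end = start + cnt * p.step
        intervals.append((start, end, US if lab else DS))
        start = end
    return StateSegmentation(intervals, min_dur=min_dur, source_step=p.step)


def refine_boundaries(seg: StateSegmentation, p: PowerTrace) -> StateSegmentation:
    """Sub-step refinement of state-transition times.

    Threshold crossings of windowed RMS power are systematically early at
    state onsets and late at offsets: with a window of width w the log-power
    threshold (≈ the geometric mean of the two state levels) is crossed when
    only a fraction 1/(1+g) of the window overlaps the up state (g = the
    RMS ratio of the states), not half of it.  Each transition is therefore
    re-located at the interpolated crossing of the *arithmetic* midpoint of
    the two neighbouring plateau power levels (in RMS², where the windowed
    power is linear in the overlap fraction, making the midpoint crossing
    unbiased).  Refined boundaries are kept ordered and each interval keeps
    at least ``min_dur``; the refinement never moves a boundary by more
    than the window width.
    """
    if len(seg.intervals) < 2:
        return seg
    pw = p.values ** 2
    centers = p.centers
    # window indices per interval
    idx_of = [np.nonzero((centers >= s) & (centers < e))[0]
              for s, e, _ in seg.intervals]
    plateaus = []
    for ix in idx_of:
        if ix.size == 0:
            plateaus.append(np.nan)
            continue
        inner = ix[1:-1] if ix.size > 2 else ix
        plateaus.append(float(np.median(pw[inner])))
    bounds = [iv[0] for iv in seg.intervals[1:]]  # original transition times
    refined: list[float] = []
    max_shift = p.width
    k_search = int(np.ceil(p.width / p.step)) + 1
    for b_i, t_orig in enumerate(bounds):
        lvl_a, lvl_b = plateaus[b_i], plateaus[b_i + 1]
        t_new = t_orig
        if np.isfinite(lvl_a) and np.isfinite(lvl_b) and lvl_a != lvl_b:
            level = 0.5 * (lvl_a + lvl_b)
            j0 = int(np.searchsorted(centers, t_orig)) - 1
            cand = []
            for j in range(max(j0 - k_search, 0),
                           min(j0 + k_search, centers.size - 1)):
                y0, y1 = pw[j] - level, pw[j + 1] - level
                if y0 == 0.0:
                    cand.append(centers[j])
                elif y0 * y1 < 0:
                    frac = y0 / (y0 - y1)
                    cand.append(centers[j] + frac * p.step)
            cand = [t for t in cand if abs(t - t_orig) <= max_shift]
            if cand:
                t_new = min(cand, key=lambda t: abs(t - t_orig))
        lo = (refined[-1] if refined else seg.intervals[0][0]) + seg.min_dur
        hi = seg.intervals[b_i + 1][1] - seg.min_dur
        refined.append(float(np.clip(t_new, lo, min(hi, t_orig + max_shift))))
    edges = [seg.intervals[0][0]] + refined + [seg.intervals[-1][1]]
    intervals = [(edges[i], edges[i + 1], seg.intervals[i][2])
                 for i in range(len(seg.intervals))]
    return StateSegmentation(intervals, min_dur=seg.min_dur,
                             source_step=seg.source_step)


def state_metrics(seg: StateSegmentation, rec: Recording,
                  p: PowerTrace | None = None,
                  gamma_band: tuple[float, float] = (25.0, 80.0),
                  broadband: tuple[float, float] = (0.1, 200.0)) -> StateMetrics:
    """Per-up-state durations, rate, gamma RMS, and peak-to-peak amplitude.

    Per up state: the RMS of the gamma-band-filtered LFP inside the state
    and the peak-to-peak excursion of the broadband (0.1–200 Hz) LFP; the
    amplitude summary is the median across up states.  Up-state frequency
    is the count divided by the analyzed span.
    """
    t_lo, t_hi = seg.span
    span = t_hi - t_lo
    gamma = bandpass(rec, *gamma_band).samples
    broad = highpass_lowpass(rec, *broadband).samples
    us_dur, ds_dur, us_rms, us_p2p = [], [], [], []
    for s, e, lab in seg.intervals:
        if lab == DS:
            ds_dur.append(e - s)
            continue
        us_dur.append(e - s)
        i0 = max(int(round((s - rec.t0) * rec.fs)), 0)
        i1 = min(int(round((e - rec.t0) * rec.fs)), rec.n)
        if i1 > i0:
            us_rms.append(float(np.sqrt(np.mean(gamma[i0:i1] ** 2))))
            us_p2p.append(float(np.ptp(broad[i0:i1])))
    return StateMetrics(
        us_durations=np.array(us_dur),
        ds_durations=np.array(ds_dur),
        us_frequency=len(us_dur) / span,
        us_amplitude_median=float(np.median(us_p2p)) if us_p2p else 0.0,
        us_gamma_rms=np.array(us_rms),
        span=span,
    )
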