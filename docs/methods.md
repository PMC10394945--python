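# Methods

This note documents the models, conventions and numerical choices behind
`lfpstates`, in the order the pipeline applies them.

## Signal conventions

Recordings are uniformly sampled single-channel voltages in mV (default
2 kHz; acquisition bandwidth assumed 0.1–1000 Hz). Times are seconds from
the trace origin; all interval outputs are half-open `[start, end)`.
Filtering is zero-phase (forward–backward) Butterworth, order 4 per pass —
the paperless standard for LFP work because it preserves the timing of
state transitions; the effective magnitude response is the squared
Butterworth response. An optional 50 Hz notch (second-order IIR,
configurable Q) is off by default: bench hardware usually removes mains
interference before digitization.

Time-resolved gamma power is the RMS of the 25–80 Hz band-passed trace on
a 250 ms moving window whose consecutive positions share 150 ms, i.e. a
100 ms hop; window centers time-stamp the values. Windows are fully
interior (no padding; a trailing partial window is discarded). RMS is
computed on the band-passed — hence essentially zero-mean — signal, so
mean subtraction inside the window is immaterial.

## Up/down-state detection

**Mixture model.** The log₁₀ of the windowed gamma RMS is fitted with a
two-component Gaussian mixture by maximum-likelihood EM
(`sklearn.mixture.GaussianMixture`, 5 seeded k-means++ restarts), rather
than a least-squares fit to a histogram, to avoid bin-width sensitivity.
Components are ordered by mean (low = down states, high = up states). The
*separation* diagnostic is |μ_hi − μ_lo| divided by the weight-pooled
standard deviation.

**Unimodality gate.** A two-component EM fit of genuinely unimodal data
does not collapse onto one component — it splits the sample into two
overlapping halves with apparent separation ≈ 1.5 — so separation alone
cannot detect the degenerate case. The fit is therefore rejected as
unimodal when any of: the fitted mixture density has a single mode, BIC
prefers a one-component model, or separation < 1. Callers can force the
fit (`check_unimodal=False`); a separation below 2 always triggers a
warning because boundaries become unreliable when the modes overlap.
Consequence worth knowing: a strongly unbalanced, barely separated mixture
(e.g. weights 0.9/0.1 with means 1.2 σ apart) *is* unimodal as a density
and is rejected by default — which is the right call for segmentation,
since no threshold separates such states usefully.

**Threshold.** The classification threshold minimizes the expected total
misclassification under the fitted mixture,
w_lo·P(X_lo > t) + w_hi·P(X_hi < t) — the equal-cost operating point of
the ROC between the two fitted densities. It is located by a 4001-point
grid sweep over [μ_lo, μ_hi] polished with bounded scalar minimization
(tolerance 1e-10), and clamped to [μ_lo, μ_hi]. For equal weights and
sigmas this is exactly the midpoint of the means; a heavier low component
pushes it toward the high mean.

**Segmentation.** Power samples at or above the threshold are up-state.
Runs shorter than 100 ms (strict comparison; duration = run length × step,
so the rule is exactly representable at the default 100 ms step) are
reassigned to the ongoing opposite state: chronologically, earliest short
run first, fused, and repeated to a fixed point. Edge runs take their
single neighbour's label. The resulting intervals alternate, tile the
span, and are all ≥ 100 ms. If every sample falls on one side of the
threshold a single full-span state is returned with a warning.

**Boundary refinement.** The threshold crossing of windowed RMS power is
systematically early at up-state onsets and late at offsets: with window
width w and state RMS ratio g, the (log-scale, ≈ geometric-mean) threshold
is crossed when only a fraction 1/(1+g) of the window overlaps the up
state — a ~56 ms bias at the default settings and g ≈ 2.6. An explicit
refinement step relocates each transition at the interpolated crossing of
the *arithmetic* midpoint of the two neighbouring plateau power levels (in
RMS², where windowed power is linear in the overlap fraction, the midpoint
crossing is unbiased). Refinement never moves a boundary by more than one
window width, preserves ordering and the minimum duration, and leaves the
merge rule untouched. On 90-s synthetic sessions it takes the pooled
fraction of true boundaries recovered within one step from ~83% to ~94%
and removes a ~10% inflation of mean up-state duration.

**Per-state metrics.** Per up state: RMS of the gamma-band trace within
the state, and peak-to-peak excursion of the broadband (0.1–200 Hz) LFP
within the state, summarized by the median across up states. "Up-state
amplitude" has no universal definition; this peak-to-peak convention is
ours and is stated wherever the number is reported. Up-state frequency is
count divided by analyzed span.

## Spectral estimation

Long-trace spectra are multitaper estimates: the demeaned trace is
multiplied by k orthogonal DPSS tapers (time–bandwidth product nw = 3,
k = 5 = 2·nw − 1 by default; both exposed), the one-sided periodograms are
averaged, and the result is a density in mV²/Hz satisfying Parseval
(∫S df = variance) to well under 5% for broadband inputs. Spectrograms
use 150 ms windows sharing 50 ms; at that window length a DPSS set with
nw ≥ 2 would be over-resolved, so each window gets a single Hamming taper
by default (a DPSS path is available via `nw`/`k`). Band powers are
trapezoidal integrals with interpolated band edges; the high-frequency
band (>100 Hz) integrates to 500 Hz.

Cohort spectra are compared per 10-Hz window from 10–20 Hz to 90–100 Hz:
each subject contributes its mean log₁₀ power in the window and windows
are tested with a two-sided Mann–Whitney test (asymptotic, no continuity
correction, so identical cohorts give p = 1 exactly). Raw p-values are the
primary readout — matching how such figures are conventionally annotated —
with Holm-adjusted values reported alongside. The difference curve is the
difference of group-mean log₁₀ spectra on the common grid.

## VEP analysis

Stimulus contrast is the session-normalized luminance-ratio scale
K = (L/l − L_min/l_min)/(L_max/l_max − L_min/l_min)·100%, clipped to
[0, 100] with a warning if outside by more than rounding error.

Trials are epoched at checkerboard reversals (0.5 Hz pattern rate, one
reversal per second; 0–1 s windows) and averaged per contrast; 120–180
trials is the recommended range and a count outside it warns. Baseline is
the mean over 30–80 ms post-stimulus; the peak is the extremum of the
absolute baseline-corrected deflection over 90–500 ms, reported signed
(mouse layer II/III VEPs are typically negative) with its magnitude used
as the amplitude. The slope is a least-squares line over an 80 ms window
centered on the first crossing of baseline + half the signed peak on the
flank rising toward the peak (crossing time linearly interpolated); the
window is clipped at the peak time with a warning when it would reach
past it.

The contrast transfer function is fitted by bounded nonlinear least
squares on the Michaelis–Menten form A(k) = A_max·k/(K_50 + k), from five
deterministic K_50 starts (1, 5, 15, 50, 150%), bounds
A_max ∈ (0, 10·max A], K_50 ∈ (0, 500]; best residual wins. The objective
is unweighted by default — appropriate for trial-averaged amplitudes whose
measurement noise is contrast-independent — with optional per-point
weights (e.g. 1/SEM) for heteroscedastic inputs. Zero-contrast points are
excluded (the model forces A(0) = 0) but retained for the gamma-ratio
null. The fitted curve is monotone nondecreasing through the origin, and
the fit is scale-equivariant (scaling amplitudes scales A_max, leaves K_50).

The gamma response ratio is, per trial, log₁₀ of response-window
(90–500 ms) to baseline-window (30–80 ms) gamma RMS, averaged across
trials as the mean of per-trial log ratios (not the log of mean ratios).
Trials with zero baseline RMS are excluded with a warning. The pipeline
filters the *continuous* recording to the gamma band once and epochs
afterwards; zero-phase filtering of short epoched trials instead smears
response power backward into the baseline window (a measured ~4–5%
downward bias of the ratio) and is supported only as a fallback.

## Gated statistics

Normality is screened per group with Shapiro–Wilk at α = 0.05; *any* group
failing switches the comparison to the nonparametric branch (the
conservative reading of a gate that the source convention leaves
unspecified for the one-fails case). Two groups: Student's t (equal
variances) vs Mann–Whitney. Three or more: one-way ANOVA with Holm–Šidák
pairwise t post hoc vs Kruskal–Wallis with a Holm-adjusted Dunn post hoc
(tie-corrected rank z-tests). Contrast-response curves: two-way
group × contrast ANOVA with type-III sums of squares on sum-to-zero
coding (robust to mild imbalance); the primary p-value is the group main
effect — testing group and interaction jointly without correction would
inflate the false-positive rate — with the interaction p and per-contrast
Holm–Šidák t-tests reported alongside. Paired parameter comparisons use
the exact Wilcoxon signed-rank test (n ≤ 25); all-zero differences return
p = 1. Every result embeds its decision trail (normality p-values, chosen
test, post hoc tables). Cohort values can be aggregated per mouse or per
trace; the unit of analysis is a named config choice because published
reports are often ambiguous about it.

## Synthetic sessions

**Slow-wave generator.** An alternating semi-Markov sequence starting in a
down state; durations are gamma-distributed with shape 4 (means 1.0 s
up / 1.5 s down by default) — the shape keeps near-zero durations rare so
the 100 ms rule is exercised but not dominated; the last interval is
truncated so intervals tile the span exactly. The trace is the sum of a
state-locked slow deflection (−0.30 mV during up states, 25 ms cosine
ramps), band-limited (25–80 Hz) Gaussian noise whose amplitude is
0.03 mV RMS in down states times a gain of 3 in up states, a 1/f
background (0.05 mV RMS), and optional >100 Hz noise and 50 Hz line
components. Band-limited noise is white noise shaped in the frequency
domain by the squared Butterworth magnitude (the spectrum zero-phase
filtering would produce), which is fast and transient-free. With these
defaults the log-power mixture separation is ≈ 5, comfortably above the
warning threshold of 2. A 90-s span at ~2.5 s mean cycle gives ~35 up
states per session; spans shorter than 5 mean cycles are rejected.

**VEP generator.** Back-to-back 1-s trials, each contrast repeated equally
(default 140, inside the recommended 120–180) in globally shuffled order.
Each trial carries a biphasic raised-cosine template scaled by
A(k) = A_max·k/(K_50 + k) (defaults A_max = 0.30 mV, K_50 = 10%) with
Gaussian latency jitter (sd 5 ms), plus 1/f noise (0.06 mV RMS =
0.2·A_max) and a gamma-band component at 0.3× the noise amplitude whose
response-window level is multiplied by 1 + gain·A(k)/A_max — so blank
trials have a response/baseline gamma ratio of exactly 0 and the ratio
grows with contrast. Template geometry: onset 85 ms, negative trough at
115 ms, positive after-lobe, 120 ms total width — chosen so its support
(85–205 ms) stays clear of the 30–80 ms baseline window and inside the
90–500 ms peak window; with noise and jitter at zero the pipeline recovers
A(k) to machine precision, which pins down the amplitude bookkeeping. All
randomness derives from one seed via SeedSequence spawning; outputs are
pure functions of (config, seed).

**Presets** encode only directions of effect, with magnitudes that are
testing conventions: `shank3_ko_like` = up-state duration ×1.5, gamma gain
×1.3, K_50 ×0.5; `pv_cko_like` = slow deflection ×1.4 plus added >100 Hz
noise at unchanged gamma gain; `midazolam_like`/`ganaxolone_like` revert
to the reference bundle. They are not claims about real effect sizes.

## What the synthetic data do and do not show

The generators reproduce the *structure* the analysis relies on — bimodal
log gamma power, alternating states with controllable duration statistics,
1/f background, saturating contrast responses with known parameters — so
passing recovery tests demonstrates that the estimators are unbiased and
appropriately powered *under the model*. They do not emulate movement or
electrode artifacts, anesthesia-depth drift, non-Gaussian gamma bursting,
cross-frequency coupling, or between-animal variability beyond seed noise;
recovery rates here are therefore upper bounds on what real recordings
would give, and the statistical comparisons on simulated cohorts test the
machinery, not biological effect sizes.

## Verification problem sizes

The acceptance script and test suite use: 1000 random label sequences
(length ≤ 50) for oracle equivalence; 50 random mixtures against a
1e-5-resolution sweep for the threshold; ten 90-s sessions for duration
and boundary recovery; 20 noise realizations for Parseval; 200
Michaelis–Menten replicates per seed over a ten-seed grid (the pooled
median estimates the true ~14% median K_50 error at 10% multiplicative
noise with ~0.4% Monte-Carlo uncertainty); ten end-to-end VEP sessions;
100 trials per gamma-ratio identity; 12-vs-12 cohorts across ten seed
repeats for the direction-of-effect study; and 500 null simulations per
type-I calibration.
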