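# lfpstates

Analysis of single-channel cortical local field potentials (LFP) recorded
under urethane anesthesia, built for studies of cortical
excitation/inhibition balance in mouse models:

* **Up/down-state segmentation.** Under urethane the cortex alternates
  between depolarized *up states* rich in gamma-band (25–80 Hz) activity
  and quiescent *down states*. The trace is band-passed to the gamma band,
  reduced to sliding-window RMS power (250 ms windows advancing by 100 ms),
  and the distribution of log₁₀ power — bimodal in this state — is fitted
  with a two-component Gaussian mixture. The classification threshold
  minimizes expected false positives plus false negatives under the fitted
  mixture (the equal-cost ROC point), and states shorter than 100 ms are
  absorbed into the ongoing opposite state. Outputs: per-state durations,
  up-state frequency, gamma RMS and peak-to-peak amplitude per up state.
* **Multitaper spectra.** DPSS (Slepian) eigenspectrum averages on long
  traces (default nw = 3, k = 5), Hamming-window spectrograms (150 ms
  windows, 50 ms shared), band powers (<0.5 Hz, 10–25 Hz, 25–80 Hz,
  >100 Hz), and a per-10-Hz-window Mann–Whitney cohort comparison.
* **VEP contrast-gain analysis.** Trial-averaged visual evoked potentials
  from contrast-reversing checkerboard stimulation (0.5 Hz reversal), peak
  amplitude in the 90–500 ms window against a 30–80 ms baseline, and the
  contrast transfer function fitted with the saturating Michaelis–Menten
  (Naka–Rushton) form

  $$A(k) = \frac{A_\max \, k}{K_{50} + k}$$

  where $A_\max$ is the saturated amplitude and $K_{50}$ the
  half-saturating contrast — a lower $K_{50}$ means saturation at lower
  contrast, i.e. higher contrast gain (weaker inhibitory gain control).
  Also: the VEP slope over an 80 ms window centered on the half-peak
  crossing, and the mean log₁₀ ratio of response- to baseline-window gamma
  RMS power per trial.
* **Normality-gated statistics.** Shapiro–Wilk per group, then Student's
  t / one-way ANOVA (Holm–Šidák post hoc) when compatible with normality,
  otherwise Mann–Whitney / Kruskal–Wallis (Dunn post hoc); two-way
  group × contrast ANOVA for contrast-response curves; Wilcoxon
  signed-rank for paired pre/post parameter comparisons.
* **Synthetic sessions with ground truth.** Because no public recordings
  exist for this kind of study, the package ships generators for slow-wave
  and VEP sessions (semi-Markov state alternation, 1/f background,
  band-limited gamma carriers, Michaelis–Menten-scaled evoked templates)
  plus genotype/treatment-like presets that encode directions of effect.
  Every analysis stage is validated by parameter recovery against the
  generator's ground truth.

## Worked example

Simulate a 90-s slow-wave session and segment it:

```bash
lfpstates simulate-sw --preset wt --seed 7 --span 90 --out demo
lfpstates detect-states --input demo/trace.f32 --out demo
# 43 up states; wrote demo/states.tsv
```

`demo/state_metrics.json` then contains (abridged):

```json
{"n_us": 43, "separation": 4.75, "threshold_log10": -1.318,
 "us_duration_mean_s": 0.981, "us_frequency_hz": 0.479,
 "us_amplitude_median_mV": 0.688}
```

The mixture separation (4.75 pooled standard deviations between the two
log-power modes) says the bimodality is strong; the recovered mean
up-state duration (0.981 s) matches the generator's 1.0 s setting, and
`demo/states.tsv` lists the half-open state intervals with per-up-state
gamma RMS.

Simulate a VEP session (140 trials per contrast at the six standard
contrasts 100, 28, 5.7, 2.3, 1.8, 0 %) and fit the transfer function:

```bash
lfpstates simulate-vep --preset wt --seed 7 --out demo
lfpstates vep --trace demo/trace.f32 --stim demo/stim.tsv --out demo
lfpstates contrast-fit --input demo/response.tsv --out demo
# A_max=0.2875 mV, K_50=11.28%
```

The generator's true parameters are A_max = 0.30 mV and K_50 = 10 %; the
recovered values are within the accuracy expected at this noise level
(noise RMS = 0.2·A_max). `demo/response.tsv` also carries the per-contrast
gamma response ratio, which grows monotonically with contrast (0.039 at
blank to 0.191 at 100 %).

The same operations are available as library calls
(`lfpstates.fit_bimodal`, `lfpstates.segment_states`,
`lfpstates.fit_contrast_response`, ...), and the two fit-shaped pieces are
scikit-learn estimators (`UpStateDetector`, `MichaelisMentenRegressor`)
that compose with sklearn tooling. `lfpstates run-all --config cfg.yaml`
drives the whole pipeline (detection → spectra → VEP → group statistics)
over two cohorts of recordings and writes a JSON report with the full
decision trail.

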