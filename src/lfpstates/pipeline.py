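"""End-to-end pipeline driver: detection → spectra → VEP → group statistics.

A :class:`PipelineConfig` names the input recordings (grouped into cohorts,
each trace optionally paired with a stimulus log), the analysis windows and
bands, and the unit of analysis.  :func:`run_pipeline` runs every stage per
recording, then the between-cohort comparisons, and returns a
machine-readable report that embeds the fully resolved configuration.
Stage failures are recorded per recording and do not abort the run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gstats, io, spectral, states, vep
from .signals import Recording, bandpass, epoch, notch, sliding_rms

__all__ = ["PipelineConfig", "RecordingInput", "run_pipeline"]

log = logging.getLogger("lfpstates")


@dataclass(frozen=True)
class RecordingInput:
    """One input trace (f32+sidecar or TSV) with an optional stimulus log."""

    trace: str
    sidecar: str | None = None
    stimulus: str | None = None
    subject: str | None = None


@dataclass
class PipelineConfig:
    """Fully resolved pipeline parameters.

    Defaults follow the standard analysis: 25–80 Hz gamma RMS on 250 ms
    windows advancing by 100 ms, a 100 ms minimum state duration,
    multitaper spectra at nw = 3 / k = 5, and a 0–1 s epoch per stimulus
    reversal.
    """

    groups: dict = field(default_factory=dict)  # name -> list[RecordingInput]
    out_dir: str = "lfpstates_out"
    gamma_band: tuple[float, float] = (25.0, 80.0)
    rms_width: float = 0.250
    rms_overlap: float = 0.150
    min_dur: float = 0.100
    spec_nw: float = 3.0
    spec_k: int = 5
    sgram_window: float = 0.150
    sgram_overlap: float = 0.050
    epoch_pre: float = 0.0
    epoch_post: float = 1.0
    apply_notch: bool = False
    notch_hz: float = 50.0
    unit_of_analysis: str = "mouse"   # "mouse" or "trace"
    seed: int = 0

    def validate(self) -> None:
        if not (self.rms_width > self.rms_overlap >= 0):
            raise ValueError("rms window geometry invalid")
        if not (self.sgram_window > self.sgram_overlap >= 0):
            raise ValueError("spectrogram window geometry invalid")
        if self.min_dur <= 0:
            raise ValueError("min_dur must be positive")
        if self.unit_of_analysis not in ("mouse", "trace"):
            raise ValueError("unit_of_analysis must be 'mouse' or 'trace'")

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = {g: [dataclasses.asdict(r) if not isinstance(r, dict)
                           else r for r in recs]
                       for g, recs in self.groups.items()}
        return d


def _load(item: RecordingInput) -> Recording:
    p = Path(item.trace)
    if p.suffix in (".tsv", ".txt", ".csv"):
        return io.read_recording_tsv(p)
    return io.read_recording(p, item.sidecar)


def analyze_recording(rec: Recording, cfg: PipelineConfig,
                      stimulus: tuple[np.ndarray, np.ndarray] | None = None
                      ) -> dict:
    """All per-recording stages; each stage's failure is caught and logged."""
    out: dict = {"errors": {}}
    if cfg.apply_notch:
        rec = notch(rec, cfg.notch_hz)
    try:
        gamma = bandpass(rec, *cfg.gamma_band)
        p = sliding_rms(gamma, cfg.rms_width, cfg.rms_overlap)
        fit = states.fit_bimodal(p, random_state=cfg.seed)
        seg = states.refine_boundaries(
            states.segment_states(p, fit.threshold, cfg.min_dur), p)
        m = states.state_metrics(seg, rec, p, gamma_band=cfg.gamma_band)
        out["segmentation"] = seg
        out["state_metrics"] = {
            "us_duration_mean": float(np.mean(m.us_durations)) if m.n_us else 0.0,
            "us_frequency": m.us_frequency,
            "us_amplitude_median": m.us_amplitude_median,
            "us_gamma_rms_median": (float(np.median(m.us_gamma_rms))
                                    if m.n_us else 0.0),
            "n_us": m.n_us,
        }
        out["bimodal_fit"] = dataclasses.asdict(fit)
    except Exception as exc:  # stage-isolated
        out["errors"]["state_detection"] = f"{type(exc).__name__}: {exc}"
        log.warning("state detection failed: %s", exc)
    try:
        spec = spectral.multitaper_spectrum(rec, cfg.spec_nw, cfg.spec_k)
        out["spectrum"] = spec
        out["band_powers"] = {
            name: spectral.band_power(spec, band)
            for name, band in spectral.BAND_PRESETS.items()}
    except Exception as exc:
        out["errors"]["spectral"] = f"{type(exc).__name__}: {exc}"
        log.warning("spectral stage failed: %s", exc)
    if stimulus is not None:
        try:
            ev, con = stimulus
            tm = epoch(rec, ev, cfg.epoch_pre, cfg.epoch_post,
                       contrasts=con, on_out_of_bounds="drop")
            # gamma ratio on trials cut from the once-filtered trace
            gtm = epoch(bandpass(rec, *cfg.gamma_band), ev, cfg.epoch_pre,
                        cfg.epoch_post, contrasts=con, on_out_of_bounds="drop")
            amps, ratios, used = [], [], []
            for c in sorted(set(con.tolist())):
                sub = tm.select(c)
                if sub.n_trials < 2:
                    continue
                v = vep.average_vep(sub)
                amp, _t, _b = vep.vep_peak(v.waveform, v.fs)
                ratios.append(vep.gamma_response_ratio(gtm.select(c),
                                                       band=None))
                if c > 0:
                    amps.append(abs(amp))
                    used.append(c)
            cr = vep.fit_contrast_response(np.array(used), np.array(amps))
            out["contrast_response"] = {
                "contrasts": used, "amplitudes": amps,
                "A_max": cr.A_max, "K_50": cr.K_50, "fit_rss": cr.fit_rss,
                "gamma_ratios": ratios,
            }
        except Exception as exc:
            out["errors"]["vep"] = f"{type(exc).__name__}: {exc}"
            log.warning("VEP stage failed: %s", exc)
    return out


def _group_stat(values_by_group: dict, fn=gstats.gated_two_group):
    names = list(values_by_group)
    a, b = values_by_group[names[0]], values_by_group[names[1]]
    return fn(np.asarray(a, float), np.asarray(b, float)).to_dict()


def run_pipeline(cfg: PipelineConfig,
                 preloaded: dict | None = None) -> dict:
    """Run every stage over the configured cohorts and compare them.

    ``preloaded`` may map group names to lists of
    ``(Recording, stimulus-or-None)`` pairs to bypass file reading (used by
    simulation studies and tests); otherwise recordings are read from the
    paths in ``cfg.groups``.
    """
    cfg.validate()
    log.info("resolved config: %s", cfg.resolved())
    report: dict = {"config": cfg.resolved(), "recordings": {}, "errors": {}}
    per_group: dict = {}
    for gname in (preloaded or cfg.groups):
        items = (preloaded[gname] if preloaded
                 else [(_load(r), (io.read_stimulus_log(r.stimulus)
                                   if r.stimulus else None))
                       for r in cfg.groups[gname]])
        subjects = (None if preloaded
                    else [r.subject for r in cfg.groups[gname]])
        per_group[gname] = []
        for i, (rec, stim) in enumerate(items):
            res = analyze_recording(rec, cfg, stimulus=stim)
            res["subject"] = (subjects[i] if subjects and subjects[i]
                              else rec.meta.get("subject", f"{gname}/{i}"))
            key = f"{gname}/{i}"
            report["recordings"][key] = {
                k: v for k, v in res.items()
                if k in ("state_metrics", "band_powers", "contrast_response",
                         "bimodal_fit", "errors", "subject")}
            per_group[gname].append(res)

    def aggregate(pairs):
        """Per-trace values, or per-subject means when unit is 'mouse'."""
        if cfg.unit_of_analysis == "trace":
            return [v for _s, v in pairs]
        by_subj: dict = {}
        for s, v in pairs:
            by_subj.setdefault(s, []).append(v)
        return [float(np.mean(v)) for v in by_subj.values()]

    names = list(per_group)
    if len(names) == 2:
        comparisons: dict = {}

        def collect(path):
            vals = {}
            for g in names:
                v = [r[path[0]][path[1]] for r in per_group[g]
                     if path[0] in r]
                vals[g] = v
            return vals

        try:
            for metric in ("us_duration_mean", "us_gamma_rms_median",
                           "us_frequency", "us_amplitude_median"):
                vals = {g: aggregate([(r["subject"], r["state_metrics"][metric])
                                      for r in per_group[g]
                                      if "state_metrics" in r])
                        for g in names}
                if all(len(v) >= 3 for v in vals.values()):
                    comparisons[metric] = _group_stat(vals)
        except Exception as exc:
            report["errors"]["state_comparison"] = str(exc)
        try:
            for bname in spectral.BAND_PRESETS:
                vals = {g: aggregate([(r["subject"], r["band_powers"][bname])
                                      for r in per_group[g]
                                      if "band_powers" in r])
                        for g in names}
                if all(len(v) >= 3 for v in vals.values()):
                    comparisons[f"band_power_{bname}"] = _group_stat(
                        {g: np.log10(v) for g, v in vals.items()})
            specs = {g: [r["spectrum"] for r in per_group[g]
                         if "spectrum" in r] for g in names}
            if all(len(s) >= 3 for s in specs.values()):
                gc = spectral.group_spectral_comparison(specs[names[0]],
                                                        specs[names[1]])
                comparisons["spectral_windows"] = gc["table"].to_dict(
                    orient="records")
        except Exception as exc:
            report["errors"]["spectral_comparison"] = str(exc)
        try:
            have_cr = all(
                sum("contrast_response" in r for r in per_group[g]) >= 3
                for g in names)
            if have_cr:
                k50 = {g: aggregate([(r["subject"],
                                      r["contrast_response"]["K_50"])
                                     for r in per_group[g]
                                     if "contrast_response" in r])
                       for g in names}
                comparisons["K_50"] = _group_stat(k50)
                import pandas as pd
                frames = {}
                for g in names:
                    rows = []
                    for si, r in enumerate(per_group[g]):
                        if "contrast_response" not in r:
                            continue
                        cr = r["contrast_response"]
                        for c, a in zip(cr["contrasts"], cr["amplitudes"]):
                            rows.append({"subject": si, "contrast": c,
                                         "amplitude": a})
                    frames[g] = pd.DataFrame(rows)
                comparisons["contrast_curves"] = gstats.contrast_curve_comparison(
                    frames[names[0]], frames[names[1]]).to_dict()
        except Exception as exc:
            report["errors"]["contrast_comparison"] = str(exc)
        report["comparisons"] = comparisons
    return report
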