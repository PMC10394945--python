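"""Parameter-recovery experiments on synthetic sessions.

No public recordings exist for the kind of study this package analyzes, so
every stage is validated by recovery: generate sessions with known ground
truth, run the full analysis, and compare estimates with the generating
parameters.  These helpers run one session end to end and report both
truth and estimate; they are used by the test suite and by the acceptance
script, and are handy for power analyses when planning a new study.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import gstats
from .signals import bandpass, epoch, sliding_rms
from .spectral import BAND_PRESETS, band_power, multitaper_spectrum
from .states import (fit_bimodal, refine_boundaries, segment_states,
                     state_metrics)
from .synth import (SlowWaveConfig, VEPConfig, boundary_match_fraction,
                    preset, simulate_slow_wave, simulate_vep_session)
from .vep import average_vep, fit_contrast_response, vep_peak

__all__ = ["recover_slow_wave", "recover_vep", "cohort_direction_study"]


def recover_slow_wave(cfg: SlowWaveConfig, fit_seed: int = 0,
                      compute_band_powers: bool = False) -> dict:
    """Simulate one slow-wave session and run the detection chain on it.

    Returns ground-truth and recovered up-state statistics plus the
    fraction of true state boundaries matched within one power-trace step.
    """
    rec, truth = simulate_slow_wave(cfg)
    p = sliding_rms(bandpass(rec, *cfg.gamma_band))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_bimodal(p, random_state=fit_seed)
        seg = refine_boundaries(segment_states(p, fit.threshold), p)
        m = state_metrics(seg, rec, p, gamma_band=cfg.gamma_band)
    out = {
        "true_us_mean": float(truth.durations("US").mean()),
        "est_us_mean": float(m.us_durations.mean()) if m.n_us else 0.0,
        "boundary_match": boundary_match_fraction(
            truth.boundaries(), seg.boundaries(), tol=p.step),
        "us_gamma_rms_median": (float(np.median(m.us_gamma_rms))
                                if m.n_us else 0.0),
        "us_amplitude_median": m.us_amplitude_median,
        "us_frequency": m.us_frequency,
        "separation": fit.separation,
        "n_us": m.n_us,
    }
    if compute_band_powers:
        spec = multitaper_spectrum(rec)
        out["band_powers"] = {name: band_power(spec, band)
                              for name, band in BAND_PRESETS.items()}
    return out


def recover_vep(cfg: VEPConfig) -> dict:
    """Simulate one VEP session and recover the contrast transfer function."""
    rec, events, contrasts, _truth = simulate_vep_session(cfg)
    tm = epoch(rec, events, 0.0, cfg.trial_dur, contrasts=contrasts)
    amps, used = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in sorted(set(contrasts.tolist())):
            if c <= 0:
                continue
            v = average_vep(tm.select(c))
            amp, _t, _b = vep_peak(v.waveform, v.fs)
            amps.append(abs(amp))
            used.append(c)
        cr = fit_contrast_response(np.array(used), np.array(amps))
    return {"contrasts": used, "amplitudes": amps,
            "est_A_max": cr.A_max, "est_K_50": cr.K_50,
            "true_A_max": cfg.A_max, "true_K_50": cfg.K_50}


def _sw_cohort(name: str, n: int, base_seed: int,
               band_powers: bool = False) -> list[dict]:
    out = []
    for i in range(n):
        cfg, _ = preset(name, seed=base_seed + i)
        out.append(recover_slow_wave(cfg, fit_seed=0,
                                     compute_band_powers=band_powers))
    return out


def _vep_cohort(name: str, n: int, base_seed: int) -> list[dict]:
    out = []
    for i in range(n):
        _, cfg = preset(name, seed=base_seed + i)
        out.append(recover_vep(cfg))
    return out


def cohort_direction_study(n_per_group: int = 12, n_repeats: int = 10,
                           seed: int = 0, include_pv: bool = True,
                           alpha: float = 0.05) -> dict:
    """Direction-of-effect study: wt vs ko-like (and pv-cko-like) cohorts.

    For each repeat, simulated cohorts are pushed through the full pipeline
    and the group differences the ko-like preset encodes (longer up states,
    higher up-state gamma RMS, lower K_50) are tested with the rank test /
    curve comparison.  Returns per-effect detection rates across repeats.
    """
    from scipy import stats as sstats

    hits = {"us_duration": 0, "us_gamma_rms": 0, "k50_lower": 0,
            "contrast_curves": 0, "pv_us_amplitude": 0,
            "pv_slow_power": 0, "pv_hf_power": 0}
    for rep in range(n_repeats):
        b = seed + 10_000 * rep
        wt = _sw_cohort("wt", n_per_group, b, band_powers=include_pv)
        ko = _sw_cohort("shank3_ko_like", n_per_group, b + 500)

        def rank_greater(key, grp_a, grp_b):
            a = [r[key] for r in grp_a]
            bb = [r[key] for r in grp_b]
            _, p = sstats.mannwhitneyu(bb, a, alternative="greater")
            return p < alpha

        hits["us_duration"] += rank_greater("est_us_mean", wt, ko)
        hits["us_gamma_rms"] += rank_greater("us_gamma_rms_median", wt, ko)

        wt_v = _vep_cohort("wt", n_per_group, b)
        ko_v = _vep_cohort("shank3_ko_like", n_per_group, b + 500)
        k50_wt = [r["est_K_50"] for r in wt_v]
        k50_ko = [r["est_K_50"] for r in ko_v]
        _, p = sstats.mannwhitneyu(k50_ko, k50_wt, alternative="less")
        hits["k50_lower"] += p < alpha
        curves_wt = np.array([r["amplitudes"] for r in wt_v])
        curves_ko = np.array([r["amplitudes"] for r in ko_v])
        res = gstats.contrast_curve_comparison(
            curves_wt, curves_ko, contrasts=np.asarray(wt_v[0]["contrasts"]))
        hits["contrast_curves"] += (
            min(res.p_value, res.extra["p_interaction"]) < alpha)

        if include_pv:
            pv = _sw_cohort("pv_cko_like", n_per_group, b + 900,
                            band_powers=True)
            hits["pv_us_amplitude"] += rank_greater(
                "us_amplitude_median", wt, pv)
            for key, band in (("pv_slow_power", "slow"),
                              ("pv_hf_power", "hf")):
                a = [r["band_powers"][band] for r in wt]
                bb = [r["band_powers"][band] for r in pv]
                _, p = sstats.mannwhitneyu(bb, a, alternative="greater")
                hits[key] += p < alpha
    return {k: v / n_repeats for k, v in hits.items()} | {
        "n_repeats": n_repeats, "n_per_group": n_per_group}
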