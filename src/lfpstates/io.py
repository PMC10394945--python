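"""Readers and writers for the package's on-disk formats.

Traces travel either as two-column TSV (``time_s<TAB>voltage_mV``) or as a
raw little-endian float32 file with a JSON sidecar carrying the sampling
rate and metadata (lossless for float32 data and far smaller).  Interval
outputs are BED-like TSVs with half-open ``[start, end)`` coordinates in
seconds from the trace origin; all headers state this convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import PowerTrace, Recording
from .states import StateSegmentation

__all__ = [
    "read_recording",
    "write_recording",
    "read_recording_tsv",
    "write_recording_tsv",
    "write_power_trace",
    "write_segmentation",
    "read_segmentation",
    "read_stimulus_log",
    "write_stimulus_log",
    "write_spectrum",
    "write_json",
]


class FormatError(ValueError):
    """File violates the declared format."""


def write_recording(rec: Recording, path: str | Path) -> tuple[Path, Path]:
    """Write a trace as raw float32 plus a JSON sidecar; returns both paths."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    rec.samples.astype("<f4").tofile(path)
    meta = {"fs_hz": rec.fs, "units": "mV", "t0_s": rec.t0,
            "n_samples": rec.n}
    meta.update({k: v for k, v in rec.meta.items()
                 if isinstance(v, (str, int, float, bool))})
    sidecar.write_text(json.dumps(meta, indent=1))
    return path, sidecar


def read_recording(path: str | Path, sidecar: str | Path | None = None
                   ) -> Recording:
    """Read a raw float32 trace with its JSON sidecar."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    meta = json.loads(Path(sidecar).read_text())
    fs = meta.pop("fs_hz", None)
    if fs is None or fs <= 0:
        raise FormatError(f"{sidecar}: sidecar must declare fs_hz > 0")
    t0 = meta.pop("t0_s", 0.0)
    meta.pop("n_samples", None)
    samples = np.fromfile(path, dtype="<f4").astype(np.float64)
    n_bad = int(np.count_nonzero(~np.isfinite(samples)))
    if n_bad:
        raise FormatError(f"{path}: {n_bad} non-finite sample(s)")
    return Recording(samples, fs=fs, t0=t0, meta=meta)


def read_recording_edf(path: str | Path) -> Recording:
    """Extension point for vendor EDF files (not implemented).

    Convert EDF exports to the f32+sidecar or TSV formats upstream, or
    plug a reader in here.
    """
    raise NotImplementedError(
        "EDF input is a documented extension point; convert to f32+JSON "
        "or TSV, or contribute a reader")


def write_recording_tsv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": rec.times, "voltage_mV": rec.samples}).to_csv(
        path, sep="\t", index=False, float_format="%.7g")
    return path


def read_recording_tsv(path: str | Path, jitter_tol: float = 0.01
                       ) -> Recording:
    """Read a ``time_s<TAB>voltage_mV`` trace; timestamps must be uniform.

    Sampling irregularity beyond ``jitter_tol`` of the median interval is a
    format error (resample upstream instead of silently regridding).
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["time_s", "voltage_mV"]:
        raise FormatError(f"{path}: expected header time_s<TAB>voltage_mV")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["voltage_mV"].to_numpy(dtype=float)
    if np.count_nonzero(~np.isfinite(v)):
        raise FormatError(f"{path}: non-finite voltage values")
    dt = np.diff(t)
    if dt.size == 0 or (dt <= 0).any():
        raise FormatError(f"{path}: timestamps must increase")
    med = float(np.median(dt))
    if np.abs(dt - med).max() > jitter_tol * med:
        raise FormatError(f"{path}: non-uniform sampling "
                          f"(jitter > {jitter_tol:.0%} of the interval)")
    return Recording(v, fs=1.0 / med, t0=float(t[0]))


def write_power_trace(p: PowerTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"center_s": p.centers, "rms_mV": p.values}).to_csv(
        path, sep="\t", index=False, float_format="%.7g")
    return path


def write_segmentation(seg: StateSegmentation, path: str | Path,
                       gamma_rms: np.ndarray | None = None,
                       p2p: np.ndarray | None = None) -> Path:
    """BED-like state intervals: half-open [start, end) seconds from t0."""
    path = Path(path)
    rows = []
    i_us = 0
    for s, e, lab in seg.intervals:
        row = {"start_s": s, "end_s": e, "state": lab,
               "gamma_rms_mV": np.nan, "p2p_mV": np.nan}
        if lab == "US":
            if gamma_rms is not None and i_us < len(gamma_rms):
                row["gamma_rms_mV"] = gamma_rms[i_us]
            if p2p is not None and i_us < len(p2p):
                row["p2p_mV"] = p2p[i_us]
            i_us += 1
        rows.append(row)
    with open(path, "w") as fh:
        fh.write("# half-open intervals [start_s, end_s), seconds from t0\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False,
                                  float_format="%.6g")
    return path


def read_segmentation(path: str | Path) -> StateSegmentation:
    df = pd.read_csv(path, sep="\t", comment="#")
    intervals = [(float(r.start_s), float(r.end_s), str(r.state))
                 for r in df.itertuples()]
    return StateSegmentation(intervals)


def write_stimulus_log(event_times: np.ndarray, contrasts: np.ndarray,
                       path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"event_time_s": event_times,
                  "contrast_pct": contrasts}).to_csv(
        path, sep="\t", index=False, float_format="%.6g")
    return path


def read_stimulus_log(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["event_time_s", "contrast_pct"]:
        raise FormatError(f"{path}: expected event_time_s<TAB>contrast_pct")
    t = df["event_time_s"].to_numpy(dtype=float)
    c = df["contrast_pct"].to_numpy(dtype=float)
    if (np.diff(t) <= 0).any():
        raise FormatError(f"{path}: event times must increase")
    if ((c < 0) | (c > 100)).any():
        raise FormatError(f"{path}: contrasts must lie in [0, 100]%")
    return t, c


def write_spectrum(freqs: np.ndarray, power: np.ndarray,
                   path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"freq_hz": freqs, "power": power}).to_csv(
        path, sep="\t", index=False, float_format="%.7g")
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=_default, sort_keys=True))
    return path
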