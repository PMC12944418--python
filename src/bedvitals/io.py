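"""Signal and configuration file round-trips.

Signals travel as two-column CSV (``time_s,value`` with a header row)
or mono float32 WAV; both preserve the sampling rate exactly and the
samples to float32 precision.  Run configuration is YAML mirroring the
dataclass field names, validated with every violation reported at
once.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .channel import ChannelModel
from .signal import VibrationSignal
from .synth import HR_RANGE_BPM, RR_RANGE_BPM, SynthesisConfig

__all__ = ["read_signal", "write_signal", "RunConfig", "load_config", "dump_config"]


def write_signal(signal: VibrationSignal, path: str | os.PathLike, format: str | None = None) -> Path:
    """Write a signal to CSV or WAV (format inferred from the suffix).

    CSV dialect: header ``time_s,value``, '.' decimal separator, LF
    line endings.  WAV: mono float32 with fs in the header (fs must be
    an integer for the WAV container).
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        t = signal.times
        with open(path, "w", newline="\n") as fh:
            fh.write("time_s,value\n")
            for ti, vi in zip(t, signal.samples):
                fh.write(f"{ti:.6f},{vi:.9g}\n")
    elif fmt == "wav":
        fs = int(round(signal.fs))
        if abs(fs - signal.fs) > 1e-9:
            raise ValueError("WAV requires an integer sampling rate")
        wavfile.write(path, fs, signal.samples.astype(np.float32))
    else:
        raise ValueError(f"unknown signal format {fmt!r} (use csv or wav)")
    return path


def read_signal(path: str | os.PathLike) -> VibrationSignal:
    """Read a signal written by :func:`write_signal`.

    CSV parsing reports the first offending line on malformed input;
    the sampling rate is recovered from the time column (median step).
    """
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "wav":
        fs, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError(f"{path}: expected mono WAV, got {data.ndim} channels")
        return VibrationSignal(samples=np.asarray(data, dtype=float), fs=float(fs),
                               label=str(path))
    if fmt != "csv":
        raise ValueError(f"unknown signal format {fmt!r} (use csv or wav)")
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        if header.strip().lower() != "time_s,value":
            raise ValueError(f"{path}:1: expected header 'time_s,value', got {header.strip()!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two comma-separated columns")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if len(values) == 0:
        raise ValueError(f"{path}: no samples")
    if len(values) == 1:
        raise ValueError(f"{path}: need at least two samples to infer the sampling rate")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    fs = 1.0 / float(np.median(steps))
    # snap to a clean rate when the time stamps were printed rounded
    fs = round(fs, 6)
    return VibrationSignal(samples=np.asarray(values), fs=fs, label=str(path))


@dataclass(frozen=True)
class RunConfig:
    """Umbrella configuration: generator, channel and estimator knobs.

    Absent YAML fields fall back to the documented defaults; the seed
    fans out to per-module streams.
    """

    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    channel: ChannelModel = field(default_factory=ChannelModel)
    hr_window_s: float = 10.0
    rr_window_s: float = 50.0
    hop_s: float = 1.0
    band_hr: tuple[float, float] = (0.1, 20.0)
    band_rr: tuple[float, float] = (0.1, 2.0)
    log_level: str = "INFO"
    seed: int = 0


def _validate(errors: list[str], name: str, value, lo, hi) -> None:
    if not (lo <= value <= hi):
        errors.append(f"{name}={value!r} outside allowed range [{lo}, {hi}]")


def load_config(path: str | os.PathLike | None) -> RunConfig:
    """Load a YAML run configuration, filling defaults for absent keys.

    Validation collects every violation and raises a single
    ``ValueError`` naming all offending keys; an empty file yields the
    full default configuration.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")

    errors: list[str] = []
    synth_raw = dict(raw.get("synthesis", {}))
    chan_raw = dict(raw.get("channel", {}))
    known_synth = set(SynthesisConfig.__dataclass_fields__)
    known_chan = set(ChannelModel.__dataclass_fields__)
    for key in synth_raw.keys() - known_synth:
        errors.append(f"synthesis.{key}: unknown key")
    for key in chan_raw.keys() - known_chan:
        errors.append(f"channel.{key}: unknown key")
    if "hr_bpm" in synth_raw:
        _validate(errors, "synthesis.hr_bpm", synth_raw["hr_bpm"], *HR_RANGE_BPM)
    if "rr_bpm" in synth_raw:
        _validate(errors, "synthesis.rr_bpm", synth_raw["rr_bpm"], *RR_RANGE_BPM)
    if "sawtooth_min" in synth_raw:
        _validate(errors, "synthesis.sawtooth_min", synth_raw["sawtooth_min"], 1e-9, 1.0)
    if "noise_sd" in chan_raw and chan_raw["noise_sd"] < 0:
        errors.append("channel.noise_sd: must be >= 0")

    top = {
        k: raw[k]
        for k in ("hr_window_s", "rr_window_s", "hop_s", "band_hr", "band_rr", "log_level", "seed")
        if k in raw
    }
    for k in ("band_hr", "band_rr"):
        if k in top:
            top[k] = tuple(float(v) for v in top[k])
            if not (0 < top[k][0] < top[k][1]):
                errors.append(f"{k}: require 0 < low < high")
    for k in ("hr_window_s", "rr_window_s", "hop_s"):
        if k in top and top[k] <= 0:
            errors.append(f"{k}: must be positive")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))

    if "impulse_response" in chan_raw:
        chan_raw["impulse_response"] = tuple(float(v) for v in chan_raw["impulse_response"])
    try:
        synthesis = SynthesisConfig(**synth_raw)
        channel = ChannelModel(**chan_raw)
    except ValueError as exc:
        raise ValueError(f"invalid configuration: {exc}") from None
    return RunConfig(synthesis=synthesis, channel=channel, **top)


def dump_config(config: RunConfig, path: str | os.PathLike | None = None) -> str:
    """Serialize a RunConfig to YAML (returns the text; optionally writes)."""
    d = asdict(config)
    d["channel"]["impulse_response"] = list(d["channel"]["impulse_response"])
    d["band_hr"] = list(d["band_hr"])
    d["band_rr"] = list(d["band_rr"])
    text = yaml.safe_dump(d, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
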