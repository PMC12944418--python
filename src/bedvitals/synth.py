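"""Cardiorespiratory drive-signal generator.

Emulates the digital control signal of a single-motor bed testbed:
each heartbeat is one positive half-cycle pulse (the motor strikes and
returns to its ground position), beat amplitudes are modulated by a
rising sawtooth respiratory envelope discretized at the beat onsets,
and the result is quantized to integer DAC levels.  Abnormal rhythms
(e.g. atrial-fibrillation-like irregularity) are produced by driving
the schedule with explicit or randomly drawn per-beat intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .signal import VibrationSignal, child_rng

__all__ = [
    "HR_RANGE_BPM",
    "RR_RANGE_BPM",
    "BeatSchedule",
    "SynthesisConfig",
    "AbnormalitySpec",
    "build_beat_schedule",
    "render_pulse_train",
    "respiratory_gains",
    "synthesize",
]

#: Design range of heart rates the testbed covers, beats/min.
HR_RANGE_BPM = (40.0, 240.0)
#: Design range of respiratory rates, breaths/min.
RR_RANGE_BPM = (8.0, 40.0)


@dataclass(frozen=True)
class BeatSchedule:
    """Ordered beat onsets with one interval per beat.

    ``intervals[i] == onsets[i+1] - onsets[i]`` for all but the last
    beat, whose interval is its nominal width (used to size its pulse).
    ``abnormal`` flags schedules whose instantaneous rates may leave
    the physiological design band.
    """

    onsets: np.ndarray
    intervals: np.ndarray
    abnormal: bool = False

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "intervals", intervals)
        if onsets.size != intervals.size:
            raise ValueError("one interval per beat required")
        if onsets.size and not np.all(np.diff(onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(intervals <= 0):
            raise ValueError("all beat intervals must be positive")
        if not self.abnormal and onsets.size:
            rates = 60.0 / intervals
            lo, hi = HR_RANGE_BPM
            if np.any(rates < lo - 1e-9) or np.any(rates > hi + 1e-9):
                raise ValueError(
                    "normal schedule has instantaneous rates outside "
                    f"[{lo}, {hi}] bpm; flag the schedule abnormal"
                )

    @property
    def n_beats(self) -> int:
        return self.onsets.size


@dataclass(frozen=True)
class AbnormalitySpec:
    """User-controlled irregular rhythm specification.

    ``explicit_intervals`` replays the given per-beat intervals
    verbatim; ``random_variability`` draws i.i.d. per-beat intervals
    from a truncated normal (mean_s, sd_s, clipped to bounds_s).
    """

    mode: Literal["explicit_intervals", "random_variability"]
    intervals: Sequence[float] | None = None
    mean_s: float | None = None
    sd_s: float | None = None
    bounds_s: tuple[float, float] = (0.25, 1.5)
    seed: int | None = None

    def realize(self, duration_s: float) -> np.ndarray:
        """Materialize the per-beat interval sequence covering duration_s."""
        if self.mode == "explicit_intervals":
            if self.intervals is None or len(self.intervals) == 0:
                raise ValueError("explicit_intervals mode requires a nonempty interval list")
            iv = np.asarray(self.intervals, dtype=float)
            if np.any(iv <= 0):
                raise ValueError("explicit intervals must all be positive")
            return iv
        if self.mode == "random_variability":
            if self.mean_s is None or self.sd_s is None:
                raise ValueError("random_variability mode requires mean_s and sd_s")
            lo, hi = self.bounds_s
            if not (0 < lo <= self.mean_s <= hi):
                raise ValueError("mean_s must lie within bounds_s")
            rng = child_rng(self.seed, "abnormal-intervals")
            n_guess = int(np.ceil(duration_s / lo)) + 1
            iv = np.clip(rng.normal(self.mean_s, self.sd_s, size=n_guess), lo, hi)
            return iv
        raise ValueError(f"unknown abnormality mode {self.mode!r}")


@dataclass(frozen=True)
class SynthesisConfig:
    """All generator parameters.

    hr_bpm, rr_bpm : float
        Target heart rate (40-240 bpm) and respiratory rate (8-40 brpm).
    fs : float
        Sampling rate, Hz (default 100, matching the sensing side).
    duration_s : float
        Signal length in seconds.
    pulse_amplitude : float
        Peak drive level in DAC counts (default 256; small relative to
        the 12-bit full scale so the motor can return to ground between
        beats at high rates).
    dac_bits : int
        DAC resolution; levels span [0, 2**dac_bits - 1].
    sawtooth_min, sawtooth_max : float
        Bounds of the rising respiratory amplitude ramp (default
        0.95-1.0, a 5% beat-to-beat modulation depth).
    pulse_shape : {"half_sine", "square"}
        Half-sine is the physiologically motivated default; square is
        kept as a contrast waveform.
    duty : float
        Fraction of each beat interval occupied by the pulse, in (0, 1].
    seed : int
        Seed fanned out to any stochastic stage (abnormal rhythms).
    """

    hr_bpm: float = 60.0
    rr_bpm: float = 15.0
    fs: float = 100.0
    duration_s: float = 60.0
    pulse_amplitude: float = 256.0
    dac_bits: int = 12
    sawtooth_min: float = 0.95
    sawtooth_max: float = 1.0
    pulse_shape: Literal["half_sine", "square"] = "half_sine"
    duty: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (HR_RANGE_BPM[0] <= self.hr_bpm <= HR_RANGE_BPM[1]):
            raise ValueError(f"hr_bpm={self.hr_bpm} outside design range {HR_RANGE_BPM}")
        if not (RR_RANGE_BPM[0] <= self.rr_bpm <= RR_RANGE_BPM[1]):
            raise ValueError(f"rr_bpm={self.rr_bpm} outside design range {RR_RANGE_BPM}")
        if not (0 < self.sawtooth_min <= self.sawtooth_max <= 1):
            raise ValueError("require 0 < sawtooth_min <= sawtooth_max <= 1")
        if not (0 <= self.pulse_amplitude <= 2 ** self.dac_bits - 1):
            raise ValueError("pulse_amplitude must fit the DAC range")
        if not (0 < self.duty <= 1):
            raise ValueError("duty must lie in (0, 1]")
        if self.fs * 60.0 / self.hr_bpm < 2:
            raise ValueError("fewer than two samples per beat; raise fs or lower hr_bpm")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.pulse_shape not in ("half_sine", "square"):
            raise ValueError(f"unknown pulse_shape {self.pulse_shape!r}")


def build_beat_schedule(
    hr_bpm: float,
    duration_s: float,
    abnormality: AbnormalitySpec | None = None,
    fs: float = 100.0,
) -> BeatSchedule:
    """Lay out beat onsets over [0, duration_s).

    Normal schedules place beats at a constant interval 60/hr_bpm
    starting at t = 0.  With an :class:`AbnormalitySpec` the per-beat
    intervals come from the spec instead and the schedule is flagged
    abnormal.  Intervals of two sample periods or less are rejected as
    unrenderable.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if abnormality is None:
        if not (HR_RANGE_BPM[0] <= hr_bpm <= HR_RANGE_BPM[1]):
            raise ValueError(f"hr_bpm={hr_bpm} outside design range {HR_RANGE_BPM}")
        period = 60.0 / hr_bpm
        if period <= 2.0 / fs:
            raise ValueError("beat interval <= 2 sample periods is unrenderable")
        n = int(np.ceil(duration_s / period - 1e-12))
        onsets = np.arange(n) * period
        onsets = onsets[onsets < duration_s]
        intervals = np.full(onsets.size, period)
        return BeatSchedule(onsets=onsets, intervals=intervals, abnormal=False)

    iv = abnormality.realize(duration_s)
    if np.any(iv <= 2.0 / fs):
        raise ValueError("abnormal interval <= 2 sample periods is unrenderable")
    onsets = np.concatenate([[0.0], np.cumsum(iv)])
    keep = onsets < duration_s
    onsets = onsets[keep]
    # each beat's nominal width is its following interval; the last
    # rendered beat reuses the final realized interval
    widths = np.concatenate([iv, [iv[-1]]])[keep]
    return BeatSchedule(onsets=onsets, intervals=widths, abnormal=True)


def render_pulse_train(
    schedule: BeatSchedule,
    config: SynthesisConfig,
    gains: np.ndarray | None = None,
) -> VibrationSignal:
    """Render one nonnegative pulse per beat into a sampled signal.

    Each pulse spans ``duty * interval`` seconds from its onset —
    half_sine: ``A * sin(pi * t' / width)`` (peak A at mid-pulse);
    square: a constant block at A.  The signal is exactly zero between
    pulses (motor resting at ground).  If a pulse would overrun the
    next onset (short abnormal interval) it is truncated there with a
    warning.  ``gains`` optionally scales each beat's whole pulse.
    """
    fs = config.fs
    n = int(round(config.duration_s * fs))
    out = np.zeros(n)
    if gains is None:
        gains = np.ones(schedule.n_beats)
    gains = np.asarray(gains, dtype=float)
    if gains.size != schedule.n_beats:
        raise ValueError("one gain per beat required")

    for b, (onset, interval) in enumerate(zip(schedule.onsets, schedule.intervals)):
        width = config.duty * interval
        end = onset + width
        if b + 1 < schedule.n_beats and end > schedule.onsets[b + 1]:
            warnings.warn(
                f"pulse at {onset:.3f} s overlaps next onset; truncating",
                RuntimeWarning,
                stacklevel=2,
            )
            end = schedule.onsets[b + 1]
        i0 = int(np.ceil(onset * fs - 1e-9))
        i1 = min(int(np.floor(end * fs - 1e-9)) + 1, n)
        if i1 <= i0:
            continue
        t_rel = np.arange(i0, i1) / fs - onset
        amp = config.pulse_amplitude * gains[b]
        if config.pulse_shape == "half_sine":
            pulse = amp * np.sin(np.pi * np.clip(t_rel, 0, width) / width)
            out[i0:i1] = np.maximum(pulse, 0.0)
        else:  # square
            out[i0:i1] = amp
    return VibrationSignal(samples=out, fs=fs, label="drive pulse train")


def respiratory_gains(
    schedule: BeatSchedule,
    rr_bpm: float,
    sawtooth_min: float = 0.95,
    sawtooth_max: float = 1.0,
) -> np.ndarray:
    """Sample the rising respiratory sawtooth at each beat onset.

    The continuous envelope is a ramp of period 60/rr_bpm rising from
    sawtooth_min (at t = 0) to sawtooth_max, discretized at the beat
    onsets so each heartbeat gets a single amplitude gain.
    """
    if not (RR_RANGE_BPM[0] <= rr_bpm <= RR_RANGE_BPM[1]):
        raise ValueError(f"rr_bpm={rr_bpm} outside design range {RR_RANGE_BPM}")
    if not (0 < sawtooth_min <= sawtooth_max <= 1):
        raise ValueError("require 0 < sawtooth_min <= sawtooth_max <= 1")
    period = 60.0 / rr_bpm
    phase = np.mod(schedule.onsets, period) / period
    return sawtooth_min + (sawtooth_max - sawtooth_min) * phase


def quantize_dac(x: np.ndarray, dac_bits: int) -> np.ndarray:
    """Quantize to integer DAC levels in [0, 2**dac_bits - 1].

    Round-half-to-even then clip; values stay exact integers stored as
    floats so later stages can treat them as ordinary samples.
    """
    levels = 2 ** dac_bits - 1
    return np.clip(np.rint(x), 0, levels)


def synthesize(
    config: SynthesisConfig,
    abnormality: AbnormalitySpec | None = None,
) -> VibrationSignal:
    """Full generator pipeline: schedule -> pulses -> respiration -> DAC.

    Deterministic for a given (config, abnormality) pair: the only
    stochastic stage is an abnormal rhythm in random_variability mode,
    which draws from its own seeded stream (falling back to
    ``config.seed`` when the spec leaves seed unset).
    """
    if abnormality is not None and abnormality.seed is None:
        abnormality = AbnormalitySpec(
            mode=abnormality.mode,
            intervals=abnormality.intervals,
            mean_s=abnormality.mean_s,
            sd_s=abnormality.sd_s,
            bounds_s=abnormality.bounds_s,
            seed=config.seed,
        )
    schedule = build_beat_schedule(config.hr_bpm, config.duration_s, abnormality, fs=config.fs)
    gains = respiratory_gains(schedule, config.rr_bpm, config.sawtooth_min, config.sawtooth_max)
    train = render_pulse_train(schedule, config, gains=gains)
    quantized = quantize_dac(train.samples, config.dac_bits)
    label = f"synth hr={config.hr_bpm} rr={config.rr_bpm}" + (" abnormal" if abnormality else "")
    return VibrationSignal(samples=quantized, fs=config.fs, label=label)
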