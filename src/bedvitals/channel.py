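"""Bed-transmission channel model and excitation waveforms.

Stands in for the physical path from the vibration motor to the
under-bed geophone: a linear impulse response (bed medium), an
optional weight-dependent ringing tail that makes adjacent beats
overlap at high heart rates (heavier loads ring longer), and additive
white Gaussian sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal import VibrationSignal, child_rng

__all__ = ["ChannelModel", "apply_channel", "make_chirp", "noise_sd_for_snr"]


@dataclass(frozen=True)
class ChannelModel:
    """Linear bed channel with weight distortion and sensor noise.

    impulse_response : sequence of tap weights (dimensionless); the
        default single unit tap is the identity medium.
    weight_factor : float >= 0
        Distortion severity knob; 0 means none.  Larger values add an
        exponentially decaying ringing tail
        ``weight_factor * exp(-k / (tau * (1 + weight_factor)))``
        on top of the base response, so heavier simulated loads both
        strengthen and lengthen the ringing until successive beats
        overlap.  The mapping from added kilograms to this factor is a
        free calibration.
    noise_sd : float >= 0
        Standard deviation of additive white Gaussian noise, in output
        units.
    ringing_tau_s : float
        Base ringing time constant in seconds (default 0.05 s).
    seed : int or None
        Seed of the noise stream; None draws fresh entropy.
    """

    impulse_response: tuple[float, ...] = (1.0,)
    weight_factor: float = 0.0
    noise_sd: float = 0.0
    ringing_tau_s: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        ir = tuple(float(v) for v in np.atleast_1d(self.impulse_response))
        object.__setattr__(self, "impulse_response", ir)
        if len(ir) == 0 or not np.all(np.isfinite(ir)):
            raise ValueError("impulse_response must be finite and non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.weight_factor < 0:
            raise ValueError("weight_factor must be >= 0")
        if self.ringing_tau_s <= 0:
            raise ValueError("ringing_tau_s must be positive")

    def effective_impulse_response(self, fs: float) -> np.ndarray:
        """Base taps plus the weight-dependent ringing tail, sampled at fs."""
        base = np.asarray(self.impulse_response, dtype=float)
        if self.weight_factor == 0:
            return base
        tau = self.ringing_tau_s * fs * (1.0 + self.weight_factor)
        n_tail = int(np.ceil(8.0 * tau))
        k = np.arange(n_tail)
        tail = self.weight_factor * np.exp(-k / tau)
        h = np.zeros(max(base.size, n_tail))
        h[: base.size] += base
        h[:n_tail] += tail
        return h


def apply_channel(signal: VibrationSignal, model: ChannelModel) -> VibrationSignal:
    """Pass a drive signal through the bed channel.

    Output = (signal convolved with the effective impulse response,
    truncated to the input length and aligned at zero lag) plus seeded
    white Gaussian noise.  The identity model returns the input
    sample-for-sample.
    """
    if len(signal) == 0:
        raise ValueError("signal must be nonempty")
    h = model.effective_impulse_response(signal.fs)
    y = sps.fftconvolve(signal.samples, h, mode="full")[: len(signal)]
    if model.noise_sd > 0:
        rng = child_rng(model.seed, "channel-noise")
        y = y + rng.normal(0.0, model.noise_sd, size=y.size)
    return VibrationSignal(samples=y, fs=signal.fs, label=f"{signal.label} | channel")


def noise_sd_for_snr(signal: VibrationSignal | np.ndarray, snr_db: float) -> float:
    """Noise standard deviation giving the requested SNR against the
    signal's AC power (power of the mean-removed samples)."""
    x = signal.samples if isinstance(signal, VibrationSignal) else np.asarray(signal, float)
    rms = float(np.std(x))
    if rms == 0:
        raise ValueError("cannot set an SNR against a constant signal")
    return rms * 10.0 ** (-snr_db / 20.0)


def make_chirp(f0: float, f1: float, duration_s: float, fs: float = 100.0) -> VibrationSignal:
    """Unit-amplitude linear frequency sweep from f0 to f1 Hz.

    Used as the broadband excitation for transfer-function estimation;
    the sweep covers every frequency of interest exactly once.
    """
    if not (0 < f0 < f1):
        raise ValueError("require 0 < f0 < f1 (constant-frequency sweep is disallowed)")
    if f1 >= fs / 2:
        raise ValueError(f"f1={f1} Hz must be below Nyquist {fs / 2} Hz")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    t = np.arange(int(round(duration_s * fs))) / fs
    x = sps.chirp(t, f0=f0, f1=f1, t1=duration_s, method="linear")
    return VibrationSignal(samples=x, fs=fs, label=f"chirp {f0}-{f1} Hz")
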