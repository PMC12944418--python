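"""Bed transfer-function estimation and source-signal recovery.

With a broadband excitation x (a chirp) over the bed and the sensed
response y under it, the channel's frequency response is H(f) =
Y(f)/X(f).  The bare ratio explodes at bins where X has no energy, so
both the estimate and the inversion use Wiener-style regularized
division.  Inverting H recovers the clean over-bed source from a noisy
under-bed recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import irfft, rfft, rfftfreq

from .signal import VibrationSignal, max_normalized_xcorr

__all__ = [
    "TransferFunctionEstimate",
    "estimate_transfer",
    "recover_signal",
    "recovery_accuracy",
]


@dataclass(frozen=True)
class TransferFunctionEstimate:
    """Complex frequency response on the one-sided FFT grid of its fit.

    ``regularization_eps`` is the relative Wiener floor used at
    estimation time and reused for inversion; ``n_samples`` records the
    time-domain length the grid corresponds to.
    """

    freqs: np.ndarray
    H: np.ndarray
    regularization_eps: float
    fs: float
    n_samples: int

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        H = np.asarray(self.H, dtype=complex)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "H", H)
        if freqs.size != H.size:
            raise ValueError("freqs and H must align")
        if freqs.size and not np.all(np.diff(freqs) > 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.all(np.isfinite(H)):
            raise ValueError("H must be finite everywhere (regularize the division)")


def estimate_transfer(
    x: VibrationSignal,
    y: VibrationSignal,
    regularization_eps: float = 1e-3,
    welch_nperseg: int | None = None,
) -> TransferFunctionEstimate:
    """Estimate H(f) = Y(f)/X(f) from a paired over/under-bed recording.

    Single-segment FFT estimate with regularized division
    ``H = Y conj(X) / (|X|^2 + eps * max|X|^2)``.  Passing
    ``welch_nperseg`` switches to Welch-averaged cross/auto spectra
    (cross-spectral density over power spectral density), trading
    frequency resolution for variance on noisy inputs.
    """
    if len(x) != len(y) or x.fs != y.fs:
        raise ValueError("x and y must share length and sampling rate")
    if len(x) == 0:
        raise ValueError("signals must be nonempty")
    if welch_nperseg is None:
        X = rfft(x.samples)
        Y = rfft(y.samples)
        denom = np.abs(X) ** 2
        H = Y * np.conj(X) / (denom + regularization_eps * denom.max())
        freqs = rfftfreq(len(x), d=1.0 / x.fs)
        return TransferFunctionEstimate(freqs, H, regularization_eps, x.fs, len(x))
    freqs, pxx = sps.welch(x.samples, fs=x.fs, nperseg=welch_nperseg)
    _, pxy = sps.csd(x.samples, y.samples, fs=x.fs, nperseg=welch_nperseg)
    H = pxy / (pxx + regularization_eps * pxx.max())
    return TransferFunctionEstimate(freqs, H, regularization_eps, x.fs, len(x))


def recover_signal(y: VibrationSignal, tf: TransferFunctionEstimate) -> VibrationSignal:
    """Deconvolve an under-bed recording through an estimated H.

    ``Xhat = Y conj(H) / (|H|^2 + eps * max|H|^2)`` per bin, then the
    inverse FFT; the output is real by construction.  Requires y at the
    sampling rate of H; when the signal's FFT grid differs from the
    estimation grid (e.g. a Welch-averaged H), H is linearly
    interpolated onto the signal's grid.
    """
    if y.fs != tf.fs:
        raise ValueError("sampling-rate mismatch between signal and transfer function")
    if len(y) == 0:
        raise ValueError("signal must be nonempty")
    Y = rfft(y.samples)
    grid = rfftfreq(len(y), d=1.0 / y.fs)
    if grid.size == tf.freqs.size and np.allclose(grid, tf.freqs):
        H = tf.H
    else:
        H = np.interp(grid, tf.freqs, tf.H.real) + 1j * np.interp(grid, tf.freqs, tf.H.imag)
    mag2 = np.abs(H) ** 2
    floor = tf.regularization_eps * mag2.max() if mag2.max() > 0 else 1.0
    Xhat = Y * np.conj(H) / (mag2 + floor)
    x = irfft(Xhat, n=len(y))
    return VibrationSignal(samples=x, fs=y.fs, label=f"{y.label} | recovered")


def recovery_accuracy(original: VibrationSignal, recovered: VibrationSignal) -> float:
    """Agreement score in [0, 1] between source and recovery.

    Maximum over lags of the normalized cross-correlation of the two
    z-scored signals: 1 for a perfect (possibly delayed and rescaled)
    recovery, near 0 for unrelated signals.  Constant inputs are
    rejected (correlation undefined).
    """
    if len(original) != len(recovered):
        raise ValueError("signals must have equal length")
    return max_normalized_xcorr(original.samples, recovered.samples)
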