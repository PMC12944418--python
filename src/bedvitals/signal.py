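"""Core signal container and shared signal-comparison utilities.

A :class:`VibrationSignal` is the universal currency between the
generator, the channel model and the estimators: a uniformly sampled,
single-channel time series with an explicit sampling rate.  Drive
signals carry integer DAC levels; after the channel the samples are in
arbitrary velocity units (a geophone outputs a voltage proportional to
surface velocity).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = ["VibrationSignal", "max_normalized_xcorr", "zscore", "child_rng"]


@dataclass(frozen=True)
class VibrationSignal:
    """Uniformly sampled single-channel vibration time series.

    Parameters
    ----------
    samples : ndarray
        Amplitude values; DAC levels for drive signals, arbitrary
        velocity units after the channel.
    fs : float
        Sampling rate in Hz.
    label : str
        Free-text provenance (who made this signal and how).
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not (self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from signal start."""
        return np.arange(self.samples.size) / self.fs

    def segment(self, start_s: float, stop_s: float, label: str | None = None) -> "VibrationSignal":
        """Return the sub-signal covering [start_s, stop_s)."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(stop_s * self.fs))
        if not (0 <= i0 < i1 <= self.samples.size):
            raise ValueError(f"segment [{start_s}, {stop_s}) s outside signal of {self.duration_s} s")
        return replace(self, samples=self.samples[i0:i1],
                       label=self.label if label is None else label)


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to zero mean and unit standard deviation.

    Raises ``ValueError`` on signals shorter than two samples or with
    zero variance (a constant signal carries no information to scale).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to z-score")
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant signal (zero variance)")
    return (x - x.mean()) / sd


def max_normalized_xcorr(a: np.ndarray, b: np.ndarray) -> float:
    """Maximum over lags of the normalized cross-correlation.

    Both inputs are z-scored and cross-correlated; each lag is
    normalized by its overlap length so a pure delay still scores 1.
    Lags with less than half overlap are excluded (their normalized
    correlation is too noisy to be meaningful).  Identical signals
    score exactly 1 at zero lag; unrelated signals score near 0.  Used
    both as the signal-comparison score and as the transfer-function
    recovery accuracy.
    """
    a = zscore(np.asarray(a, dtype=float))
    b = zscore(np.asarray(b, dtype=float))
    cc = sps.correlate(a, b, mode="full", method="auto")
    overlap = sps.correlate(np.ones(a.size), np.ones(b.size), mode="full", method="direct")
    overlap = np.rint(overlap)
    valid = overlap >= max(min(a.size, b.size) / 2.0, 1.0)
    return float((cc[valid] / overlap[valid]).max())


def child_rng(seed: int | None, label: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream for a module.

    A single global seed fans out to per-purpose streams keyed by a
    stable label hash, so adding one consumer never perturbs another's
    stream.  ``seed=None`` yields a fresh nondeterministic stream.
    """
    import zlib

    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng([int(seed), zlib.crc32(label.encode("utf-8"))])
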