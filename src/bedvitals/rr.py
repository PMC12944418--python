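"""Respiratory-rate estimation via displacement integration.

A geophone reads surface velocity, so cumulative summation of the
(mean-centered) signal recovers chest displacement up to an additive
random walk from sensor noise.  Respiration is encoded as slow
amplitude modulation of the cardiac oscillation in that displacement:
the pipeline isolates the cardiac carrier band, takes its Hilbert
envelope, keeps the 0.1-2 Hz band of the envelope spectrum, and counts
breath peaks.  With P peaks in ``duration`` seconds,
RR = 60 * P / duration breaths per minute — a resolution of
60/duration (1.2 brpm at the default 50 s window).

Because the respiratory envelope is sampled once per heartbeat, rates
at or above half the heart rate are aliased and cannot be recovered —
an undersampling limit of the modulation mechanism itself, not of the
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import irfft, rfft, rfftfreq

from .signal import VibrationSignal

__all__ = [
    "RREstimate",
    "DisplacementSeries",
    "integrate_displacement",
    "extract_respiration",
    "count_respiration_peaks",
    "estimate_rr",
    "estimate_rr_series",
]

#: Envelope spectrum band retained for respiration, Hz.
RR_BAND_HZ = (0.1, 2.0)
#: Maximum physiological respiratory rate, brpm, setting the minimum
#: peak separation (with 20% tolerance) and the fundamental search band.
RR_MAX_BPM = 40.0
#: Search band for the cardiac carrier fundamental, Hz (40-240 bpm
#: with margin for off-grid FFT bins).
CARRIER_SEARCH_HZ = (0.55, 4.3)
#: Carrier isolation band relative to the detected fundamental: wide
#: enough to keep modulation sidebands up to the per-beat sampling
#: limit, narrow enough to exclude the second harmonic.
CARRIER_REL_BAND = (0.52, 1.48)
#: Absolute cap on the sideband span kept around the carrier, Hz.
#: Physiological respiration tops out at 0.667 Hz, so sidebands never
#: sit further than ~0.7 Hz from the carrier; capping the band at
#: +/-0.9 Hz (margin for the filter corner) excludes needless noise
#: bandwidth at fast heart rates.
CARRIER_SIDEBAND_CAP_HZ = 0.9


@dataclass(frozen=True)
class DisplacementSeries:
    """Cumulative displacement track (arbitrary units) at rate fs."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not (self.fs > 0):
            raise ValueError("fs must be positive")


@dataclass(frozen=True)
class RREstimate:
    """Respiratory-rate estimate from peak counting.

    rr_bpm = 60 * peak_count / duration_s; ``plausible`` is False when
    no credible respiratory modulation was found (RR 0 is not a
    physiological reading).
    """

    rr_bpm: float
    peak_count: int
    duration_s: float
    peak_times: np.ndarray
    plausible: bool = True


def integrate_displacement(signal: VibrationSignal) -> DisplacementSeries:
    """Cumulative sum of the mean-centered signal.

    Centering removes the sensor's DC operating point; the running sum
    turns velocity into displacement.  Integrated white noise of
    variance sigma^2 contributes a random walk whose variance grows as
    sigma^2 * T, which the later band selection suppresses.
    """
    if len(signal) == 0:
        raise ValueError("signal must be nonempty")
    x = signal.samples
    return DisplacementSeries(values=np.cumsum(x - x.mean()), fs=signal.fs)


def _mirror_pad(x: np.ndarray, n_pad: int) -> np.ndarray:
    n_pad = min(n_pad, x.size - 1)
    return np.concatenate([x[n_pad:0:-1], x, x[-2 : -n_pad - 2 : -1]])


def _respiration_pipeline(
    displacement: DisplacementSeries,
    band: tuple[float, float],
    detrend: bool,
    envelope_first: bool,
    pad_s: float,
    carrier_isolation: bool,
) -> tuple[np.ndarray, float]:
    """Shared core; returns (respiration waveform, mean carrier envelope).

    The mean carrier envelope is the reference level against which the
    modulation strength (hence plausibility) is judged.
    """
    fs = displacement.fs
    d = displacement.values
    if d.size == 0:
        raise ValueError("displacement must be nonempty")
    if detrend and d.size > 1:
        d = sps.detrend(d, type="linear")
    if not np.any(d):
        return np.zeros(d.size), 0.0

    n_pad = int(round(pad_s * fs))
    dp = _mirror_pad(d, n_pad) if n_pad > 0 else d
    n_pad = (dp.size - d.size) // 2

    if carrier_isolation:
        # locate the beat fundamental and keep carrier + modulation
        # sidebands only: the envelope then tracks beat amplitude free
        # of harmonic-beating ripple
        freqs = rfftfreq(dp.size, d=1.0 / fs)
        amp = np.abs(rfft(dp))
        search = (freqs >= CARRIER_SEARCH_HZ[0]) & (freqs <= CARRIER_SEARCH_HZ[1])
        if np.any(search) and amp[search].max() > 0:
            f0 = freqs[search][np.argmax(amp[search])]
            lo = max(CARRIER_REL_BAND[0] * f0, f0 - CARRIER_SIDEBAND_CAP_HZ)
            hi = min(CARRIER_REL_BAND[1] * f0, f0 + CARRIER_SIDEBAND_CAP_HZ, 0.49 * fs)
            sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
            dp = sps.sosfiltfilt(sos, dp)

    if envelope_first:
        env = np.abs(sps.hilbert(dp))
        env_mean = float(env[n_pad : n_pad + d.size].mean())
        spectrum = rfft(env)
        mask = _band_mask(env.size, fs, band)
        spectrum[~mask] = 0.0
        resp = irfft(spectrum, n=env.size)
    else:
        spectrum = rfft(dp)
        mask = _band_mask(dp.size, fs, band)
        spectrum[~mask] = 0.0
        filtered = irfft(spectrum, n=dp.size)
        env = np.abs(sps.hilbert(filtered))
        env_mean = float(env[n_pad : n_pad + d.size].mean())
        resp = env - env.mean()
    return resp[n_pad : n_pad + d.size], env_mean


def _band_mask(n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    freqs = rfftfreq(n, d=1.0 / fs)
    return (freqs >= band[0]) & (freqs <= band[1])


def extract_respiration(
    displacement: DisplacementSeries,
    band: tuple[float, float] = RR_BAND_HZ,
    detrend: bool = True,
    envelope_first: bool = True,
    pad_s: float = 5.0,
    carrier_isolation: bool = True,
) -> np.ndarray:
    """Isolate the respiratory waveform from a displacement track.

    Hilbert envelope of the displacement, forward FFT, zero every bin
    outside ``band`` (edges inclusive; conjugate symmetry preserved so
    the inverse is real), inverse FFT.  Two robustness measures wrap
    that core: the displacement is mirror-padded by ``pad_s`` seconds
    so the envelope's edge transients fall outside the analysis span,
    and (``carrier_isolation``) the cardiac carrier band is isolated
    first so the envelope reads beat-amplitude modulation rather than
    harmonic-beating ripple.  ``envelope_first=False`` applies the
    spectral mask before the envelope — an ablation switch.
    """
    resp, _ = _respiration_pipeline(
        displacement, band, detrend, envelope_first, pad_s, carrier_isolation
    )
    return resp


#: A spectral line must exceed this multiple of the local continuum
#: before a subharmonic step-down will trust it as a real fundamental.
LINE_QUALITY_MIN = 1.45


def _dominant_fundamental(
    w: np.ndarray, fs: float, sub_ratio: float = 0.5
) -> tuple[float, float]:
    """Dominant respiratory fundamental and its line quality.

    Works on a Welch-averaged, zero-padded amplitude spectrum:
    incoherent noise excursions average down while the respiratory line
    does not, and the fine interpolated grid avoids scalloping loss
    when the line falls between bins.  The strongest line in the
    physiological band is taken as the fundamental candidate; it steps
    down to f/3 or f/2 only when the lower line exists (stands above
    the local continuum) and its non-coinciding harmonics — the
    multiples the candidate does not share — independently carry at
    least ``sub_ratio`` of the candidate's amplitude.  That separates a
    true slow fundamental with strong harmonics from mere
    period-doubling of a faster breath.

    Returns ``(fundamental_hz, quality)`` where quality is the ratio
    of the line amplitude to the local continuum level (≫ 1 for real
    periodicity, ≈ 1 for noise).
    """
    wc = w - w.mean()
    nper = min(2048, wc.size)
    freqs, psd = sps.welch(wc, fs=fs, nperseg=nper, nfft=4 * nper)
    amp = np.sqrt(psd)
    band = (freqs >= 0.1) & (freqs <= RR_MAX_BPM / 60.0 * 1.07)
    if not np.any(band) or amp[band].max() == 0:
        return RR_MAX_BPM / 60.0, 0.0

    def amp_near(fq: float, rel: float = 0.06) -> float:
        sel = (freqs >= (1 - rel) * fq) & (freqs <= (1 + rel) * fq)
        return float(amp[sel].max()) if np.any(sel) else 0.0

    def quality(fq: float) -> float:
        # line-to-local-continuum ratio; ≈1 for noise, ≫1 for a real line
        sel = (freqs >= 0.7 * fq) & (freqs <= 1.4 * fq)
        near = (freqs >= 0.9 * fq) & (freqs <= 1.1 * fq)
        floor_sel = sel & ~near
        if not np.any(floor_sel):
            return np.inf
        floor = float(np.median(amp[floor_sel]))
        return amp_near(fq, 0.10) / floor if floor > 0 else np.inf

    band_f = freqs[band]
    band_a = amp[band]
    fm = float(band_f[np.argmax(band_a)])
    for _ in range(2):  # a 4x harmonic lock needs two halving steps
        a_fm = amp_near(fm, 0.07)
        stepped = False
        for div in (3, 2):
            fq = fm / div
            if fq < 0.1 or quality(fq) <= LINE_QUALITY_MIN:
                continue
            others = [k * fq for k in range(1, 6) if k % div != 0 and k * fq <= RR_BAND_HZ[1]]
            if others and np.mean([amp_near(f) for f in others]) > sub_ratio * a_fm:
                fm = fq
                stepped = True
                break
        if not stepped:
            break
    return fm, quality(fm)


def count_respiration_peaks(
    respiration: np.ndarray,
    fs: float,
    min_separation_s: float = 60.0 / RR_MAX_BPM * 0.8,
    prominence_frac: float = 0.2,
    refine_fundamental: bool = True,
) -> np.ndarray:
    """Times of breath peaks in a filtered respiration waveform.

    Local maxima at least ``min_separation_s`` apart (1.2 s by default:
    the 40 brpm period with 20% tolerance) with prominence at least
    ``prominence_frac`` of the waveform's interquartile range.  With
    ``refine_fundamental`` the waveform is first low-passed just above
    its dominant respiratory line, so modulation harmonics along slow
    breaths do not register as extra peaks.  Zero peaks is a legal
    result.
    """
    respiration = np.asarray(respiration, dtype=float)
    if respiration.size == 0:
        raise ValueError("respiration waveform must be nonempty")
    if float(np.subtract(*np.percentile(respiration, [75, 25]))) == 0:
        return np.array([])
    if refine_fundamental and respiration.size > 50:
        fm, _ = _dominant_fundamental(respiration, fs)
        hi = float(np.clip(1.35 * fm, 0.25, 0.49 * fs))
        lo = max(0.06, 0.6 * fm)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        # periodic extension at the detected breath period keeps the
        # boundary breaths countable (any other padding distorts the
        # first/last cycle through the narrowband filter)
        n = respiration.size
        period = int(round(fs / fm)) if fm > 0 else n
        if 0 < period <= n // 2:
            n_pad = int(5 * fs)
            reps = -(-n_pad // period)
            left = np.tile(respiration[:period], reps)[-n_pad:]
            right = np.tile(respiration[n - period :], reps)[:n_pad]
            filtered = sps.sosfiltfilt(sos, np.concatenate([left, respiration, right]))
            respiration = filtered[n_pad : n_pad + n]
        else:
            padlen = min(n - 1, int(10 * fs))
            respiration = sps.sosfiltfilt(sos, respiration, padtype="odd", padlen=padlen)
    iqr = float(np.subtract(*np.percentile(respiration, [75, 25])))
    if iqr == 0:
        return np.array([])
    distance = max(int(round(min_separation_s * fs)), 1)
    idx, _ = sps.find_peaks(respiration, distance=distance, prominence=prominence_frac * iqr)
    return idx / fs


def estimate_rr(
    signal: VibrationSignal,
    band: tuple[float, float] = RR_BAND_HZ,
    min_separation_s: float = 60.0 / RR_MAX_BPM * 0.8,
    prominence_frac: float = 0.2,
    detrend: bool = True,
    envelope_first: bool = True,
    carrier_isolation: bool = True,
    min_modulation: float = 0.005,
) -> RREstimate:
    """Full respiratory-rate pipeline on one segment (50 s advised).

    integrate_displacement -> extract_respiration -> peak count P ->
    RR = 60 * P / duration.  The estimate is flagged implausible when
    no peaks are found, when the respiratory waveform's amplitude is
    below ``min_modulation`` of the mean carrier envelope, or when no
    spectral line stands clear of the local continuum — the signatures
    of a beat train carrying no resolvable breathing modulation (e.g.
    a respiratory rate aliased by the per-beat sampling, or modulation
    buried in sensor noise).
    """
    duration = signal.duration_s
    disp = integrate_displacement(signal)
    resp, env_mean = _respiration_pipeline(
        disp, band, detrend, envelope_first, 5.0, carrier_isolation
    )
    modulated = env_mean > 0 and float(resp.std()) >= min_modulation * env_mean
    if modulated:
        peak_times = count_respiration_peaks(
            resp, signal.fs, min_separation_s=min_separation_s, prominence_frac=prominence_frac
        )
    else:
        peak_times = np.array([])
    p = int(peak_times.size)
    return RREstimate(
        rr_bpm=60.0 * p / duration,
        peak_count=p,
        duration_s=duration,
        peak_times=peak_times,
        plausible=p > 0 and modulated,
    )


def estimate_rr_series(
    signal: VibrationSignal,
    window_s: float = 50.0,
    hop_s: float = 1.0,
    **kwargs,
) -> list[tuple[float, RREstimate]]:
    """Sliding-window respiratory-rate track: (window start, estimate)."""
    out: list[tuple[float, RREstimate]] = []
    t = 0.0
    while t + window_s <= signal.duration_s + 1e-9:
        seg = signal.segment(t, min(t + window_s, signal.duration_s))
        out.append((t, estimate_rr(seg, **kwargs)))
        t += hop_s
    if not out:
        raise ValueError(f"signal shorter than one {window_s} s window")
    return out
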