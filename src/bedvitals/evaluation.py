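"""Evaluation harness: error metrics, agreement analysis, grid sweeps.

Reproduces the study-style evaluation on simulated data: sweep a grid
of heart-rate x respiratory-rate combinations through the generator,
channel and estimators, then summarize with MAE / MAPE / error SD,
Bland-Altman limits of agreement, and per-cell error matrices for
heatmap rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .channel import ChannelModel, apply_channel
from .hr import estimate_hr_series
from .rr import estimate_rr_series
from .signal import VibrationSignal, max_normalized_xcorr
from .synth import SynthesisConfig, synthesize

__all__ = [
    "EvaluationReport",
    "mae",
    "mape",
    "std_error",
    "bland_altman",
    "aligned_cross_correlation",
    "spectral_error",
    "sweep_grid",
]


def _paired(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("true and predicted vectors must have equal nonzero length")
    return t, p


def mae(y_true, y_pred) -> float:
    """Mean absolute error, mean_i |yhat_i - y_i|."""
    t, p = _paired(y_true, y_pred)
    return float(np.mean(np.abs(p - t)))


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error, 100/n * sum |yhat_i - y_i| / y_i."""
    t, p = _paired(y_true, y_pred)
    if np.any(t == 0):
        raise ValueError("MAPE undefined when a true value is zero")
    return float(100.0 * np.mean(np.abs(p - t) / np.abs(t)))


def std_error(errors) -> float:
    """Sample standard deviation of errors (n-1 denominator)."""
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 errors for a sample standard deviation")
    return float(np.std(e, ddof=1))


@dataclass(frozen=True)
class BlandAltman:
    """Bland-Altman agreement summary with the plotting pairs."""

    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(y_true, y_pred) -> BlandAltman:
    """Bland-Altman agreement: bias and 1.96-SD limits of agreement.

    diffs = yhat - y; bias = mean(diffs); limits = bias +/- 1.96 * SD;
    the x-axis pairs are the per-sample means (yhat + y)/2.
    """
    t, p = _paired(y_true, y_pred)
    if t.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = p - t
    bias = float(diffs.mean())
    sd = std_error(diffs)
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(p + t) / 2.0,
        diffs=diffs,
    )


def aligned_cross_correlation(a: VibrationSignal, b: VibrationSignal) -> float:
    """Similarity of two signals after scale normalization and alignment.

    Both are z-scored and the normalized cross-correlation is taken at
    the best lag, so a pure delay still scores 1.
    """
    return max_normalized_xcorr(a.samples, b.samples)


def spectral_error(a: VibrationSignal, b: VibrationSignal, nperseg: int | None = None) -> float:
    """Mean squared difference between unit-normalized Welch PSDs.

    Both PSDs are computed on a common frequency grid and normalized to
    total power 1 before differencing, making the score invariant to
    overall amplitude.
    """
    if a.fs != b.fs:
        raise ValueError("sampling-rate mismatch")
    n = min(len(a), len(b))
    if nperseg is None:
        nperseg = min(1024, n)
    _, pa = sps.welch(a.samples[:n], fs=a.fs, nperseg=nperseg)
    _, pb = sps.welch(b.samples[:n], fs=b.fs, nperseg=nperseg)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.mean((pa - pb) ** 2))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-cell sweep results plus the study-style summaries.

    rows : DataFrame
        One row per (hr_true, rr_true, replicate) with median estimates
        and signed errors; invalid estimator outputs appear as NaN.
    summary : dict
        ``{"hr": {"mae", "mape", "std", "n_invalid"}, "rr": {...}}``
        over the valid rows.
    bland_altman : dict of BlandAltman per vital.
    hr_max_error, rr_max_error, hr_median_error, rr_median_error :
        DataFrames indexed by rr_true with hr_true columns — per-cell
        absolute-error matrices for heatmap rendering (max across
        windows and replicates, and the median-estimate error).
    """

    rows: pd.DataFrame
    summary: dict
    bland_altman: dict
    hr_max_error: pd.DataFrame
    rr_max_error: pd.DataFrame
    hr_median_error: pd.DataFrame
    rr_median_error: pd.DataFrame


def _summarize(rows: pd.DataFrame, vital: str) -> dict:
    sub = rows.dropna(subset=[f"{vital}_est"])
    out = {"n_invalid": int(len(rows) - len(sub))}
    if len(sub):
        out["mae"] = mae(sub[f"{vital}_true"], sub[f"{vital}_est"])
        out["mape"] = mape(sub[f"{vital}_true"], sub[f"{vital}_est"])
    if len(sub) >= 2:
        out["std"] = std_error(sub[f"{vital}_est"] - sub[f"{vital}_true"])
    return out


def sweep_grid(
    hr_list: Sequence[float],
    rr_list: Sequence[float],
    channel: ChannelModel | None = None,
    replicates: int = 1,
    seed: int = 0,
    duration_s: float = 60.0,
    fs: float = 100.0,
    hr_window_s: float = 10.0,
    rr_window_s: float = 50.0,
    hop_s: float = 1.0,
) -> EvaluationReport:
    """Sweep HR x RR combinations through the full simulate/estimate loop.

    For every (hr, rr, replicate): synthesize ``duration_s`` seconds,
    pass through ``channel`` (identity when None) with a derived
    per-cell noise seed, run the sliding-window estimators, and record
    the median estimate — the per-cell operating value — alongside the
    worst window (the heatmap convention).  Deterministic for a given
    seed.
    """
    if channel is None:
        channel = ChannelModel()
    records = []
    cells_hr_max: dict[tuple[float, float], float] = {}
    cells_rr_max: dict[tuple[float, float], float] = {}
    for hr_true in hr_list:
        for rr_true in rr_list:
            for rep in range(replicates):
                cell_seed = int(
                    np.random.SeedSequence(
                        [seed, int(round(hr_true * 10)), int(round(rr_true * 10)), rep]
                    ).generate_state(1)[0] % (2**31)
                )
                cfg = SynthesisConfig(
                    hr_bpm=hr_true, rr_bpm=rr_true, fs=fs, duration_s=duration_s, seed=cell_seed
                )
                sig = synthesize(cfg)
                sensed = apply_channel(sig, replace(channel, seed=cell_seed))

                hr_track = [e.hr_bpm for _, e in
                            estimate_hr_series(sensed, window_s=hr_window_s, hop_s=hop_s)
                            if e.valid]
                rr_track = [e.rr_bpm for _, e in
                            estimate_rr_series(sensed, window_s=rr_window_s, hop_s=hop_s)
                            if e.plausible]
                hr_est = float(np.median(hr_track)) if hr_track else np.nan
                rr_est = float(np.median(rr_track)) if rr_track else np.nan
                records.append(
                    {
                        "hr_true": hr_true,
                        "rr_true": rr_true,
                        "replicate": rep,
                        "seed": cell_seed,
                        "hr_est": hr_est,
                        "rr_est": rr_est,
                        "hr_err": hr_est - hr_true,
                        "rr_err": rr_est - rr_true,
                    }
                )
                key = (rr_true, hr_true)
                hr_worst = max((abs(v - hr_true) for v in hr_track), default=np.nan)
                rr_worst = max((abs(v - rr_true) for v in rr_track), default=np.nan)
                cells_hr_max[key] = np.nanmax([cells_hr_max.get(key, np.nan), hr_worst])
                cells_rr_max[key] = np.nanmax([cells_rr_max.get(key, np.nan), rr_worst])

    rows = pd.DataFrame.from_records(records)
    summary = {"hr": _summarize(rows, "hr"), "rr": _summarize(rows, "rr")}
    ba = {}
    for vital in ("hr", "rr"):
        sub = rows.dropna(subset=[f"{vital}_est"])
        if len(sub) >= 2:
            ba[vital] = bland_altman(sub[f"{vital}_true"], sub[f"{vital}_est"])

    def matrix(cells: dict) -> pd.DataFrame:
        m = pd.DataFrame(
            index=pd.Index(sorted(set(rr_list)), name="rr_true"),
            columns=pd.Index(sorted(set(hr_list)), name="hr_true"),
            dtype=float,
        )
        for (rr_v, hr_v), val in cells.items():
            m.loc[rr_v, hr_v] = val
        return m

    med_hr = rows.groupby(["rr_true", "hr_true"])["hr_err"].apply(
        lambda e: np.nanmedian(np.abs(e))
    )
    med_rr = rows.groupby(["rr_true", "hr_true"])["rr_err"].apply(
        lambda e: np.nanmedian(np.abs(e))
    )
    return EvaluationReport(
        rows=rows,
        summary=summary,
        bland_altman=ba,
        hr_max_error=matrix(cells_hr_max),
        rr_max_error=matrix(cells_rr_max),
        hr_median_error=matrix(dict(med_hr.items())),
        rr_median_error=matrix(dict(med_rr.items())),
    )
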