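"""Designed waveform features (4 families x 10) and respiratory-cycle tools.

Each window is summarised by forty numbers chosen to expose the contrasts
between quiet breathing, breath-holds and swallow pauses:

* movement range — ten symmetric inter-quantile spans q(50+5k) - q(50-5k),
  k = 1..10, from a tight central span out to max-min (k = 5 is the IQR);
  robust to isolated noise spikes, near zero during holds;
* autocorrelation — the normalised autocorrelation at lags 0.4, 0.8, ..,
  4.0 s; peaked for periodic breathing, washed out when periodicity breaks;
* FFT — magnitudes of the ten lowest positive-frequency bins of the
  mean-removed window (0.25-2.5 Hz at the 4 s / 100 Hz default), the band
  that carries the respiratory cycle;
* histogram — fractions in ten equal-width bins spanning min..max; breathing
  piles mass at both turning points (two-peak shape) while pauses
  concentrate it in one bin.

A scaling by a > 0 scales the range and FFT families by a and leaves the
autocorrelation and histogram families unchanged.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import DisplacementTrace
from .segmentation import WindowDataset

__all__ = [
    "movement_range_features",
    "autocorrelation_features",
    "fft_features",
    "histogram_features",
    "designed_features",
    "designed_feature_names",
    "feature_matrix",
    "general_features",
    "prune_constant_features",
    "estimate_respiratory_cycle",
]

N_PER_FAMILY = 10
FAMILIES = ("range", "ac", "fft", "hist")

_VAR_FLOOR = 1e-24  # below this a window counts as constant


def movement_range_features(x: np.ndarray) -> np.ndarray:
    """Symmetric inter-quantile spans q(50+5k) - q(50-5k), k = 1..10.

    Nonnegative and nondecreasing in k; k = 10 is max - min.  All zeros for a
    constant window.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    k = np.arange(1, N_PER_FAMILY + 1)
    upper = np.percentile(x, 50 + 5 * k)
    lower = np.percentile(x, 50 - 5 * k)
    return upper - lower


def autocorrelation_features(
    x: np.ndarray, frame_interval: float = 0.01, lag_step_s: float = 0.4
) -> np.ndarray:
    """Normalised autocorrelation at lags lag_step_s * (1..10).

    Mean-removed, variance-normalised, with the biased (zero-padded)
    estimator, so values stay in [-1, 1] and a lag at or past the window
    length returns 0.  A zero-variance window yields all zeros.
    """
    x = np.asarray(x, dtype=float)
    lags = np.round(lag_step_s / frame_interval * np.arange(1, N_PER_FAMILY + 1)
                    ).astype(int)
    if x.size < 1 or lags[-1] < 1:
        raise ValueError("window too short for the requested lags")
    n = x.size
    var = np.var(x)
    if var <= _VAR_FLOOR:
        return np.zeros(N_PER_FAMILY)
    xc = x - x.mean()
    out = np.zeros(N_PER_FAMILY)
    for i, lag in enumerate(lags):
        if lag < n:
            out[i] = float(xc[:-lag] @ xc[lag:]) / (n * var)
    return out


def fft_features(x: np.ndarray) -> np.ndarray:
    """Magnitudes of the 10 lowest positive-frequency DFT bins.

    The DC component is removed by mean subtraction first; for the default
    4 s window at 100 Hz the bins cover 0.25-2.5 Hz.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * N_PER_FAMILY:
        raise ValueError("window too short for 10 positive-frequency bins")
    spectrum = np.fft.rfft(x - x.mean())
    return np.abs(spectrum[1: N_PER_FAMILY + 1])


def histogram_features(x: np.ndarray) -> np.ndarray:
    """Fractions per bin for 10 equal-width bins spanning min..max.

    Fractions (not counts) keep the family comparable across window sizes.
    The top bin is right-closed, so the maximum sample lands in bin 10.  A
    flat window puts all mass in bin 0 by convention, preserving the
    single-spike shape that separates pauses from breathing.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("window must be nonempty")
    lo, hi = x.min(), x.max()
    out = np.zeros(N_PER_FAMILY)
    if hi <= lo:
        out[0] = 1.0
        return out
    counts, _ = np.histogram(x, bins=N_PER_FAMILY, range=(lo, hi))
    return counts / x.size


def designed_features(x: np.ndarray, frame_interval: float = 0.01) -> np.ndarray:
    """The 40-value designed feature vector (range, ac, fft, hist; 10 each)."""
    return np.concatenate(
        [
            movement_range_features(x),
            autocorrelation_features(x, frame_interval),
            fft_features(x),
            histogram_features(x),
        ]
    )


def designed_feature_names() -> list[str]:
    return [f"{fam}_{i:02d}" for fam in FAMILIES
            for i in range(1, N_PER_FAMILY + 1)]


def feature_matrix(dataset: WindowDataset) -> pd.DataFrame:
    """Feature table for a window dataset.

    Columns: ``subject, start_s, label`` then the 40 designed features.
    """
    feats = np.stack([
        designed_features(w, dataset.frame_interval) for w in dataset.windows
    ])
    df = pd.DataFrame(feats, columns=designed_feature_names())
    df.insert(0, "label", dataset.labels)
    df.insert(0, "start_s", dataset.starts)
    df.insert(0, "subject", dataset.groups)
    return df


def general_features(x: np.ndarray, frame_interval: float = 0.01) -> pd.Series:
    """A broad catalogue of generic time-series statistics for one window.

    Covers location/scale/shape moments, quantiles, energy and variation
    measures, counts, and coarse spectral summaries.  All entries are finite
    for any finite input, including constant windows.  Intended as the
    exhaustive-feature comparison arm; constant or duplicated columns are
    pruned at dataset level with :func:`prune_constant_features`.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("window too short for general features")
    diffs = np.diff(x)
    m, sd = x.mean(), x.std()
    centered = x - m
    feats: dict[str, float] = {
        "mean": m,
        "median": float(np.median(x)),
        "std": sd,
        "var": float(np.var(x)),
        "min": float(x.min()),
        "max": float(x.max()),
        "ptp": float(np.ptp(x)),
        "abs_energy": float(x @ x),
        "rms": float(np.sqrt(np.mean(x**2))),
        "mean_abs": float(np.mean(np.abs(x))),
        "mean_change": float(diffs.mean()),
        "mean_abs_change": float(np.mean(np.abs(diffs))),
        "max_abs_change": float(np.max(np.abs(diffs))),
        "first": float(x[0]),
        "last": float(x[-1]),
        "argmin_frac": float(np.argmin(x) / n),
        "argmax_frac": float(np.argmax(x) / n),
        "count_above_mean": float(np.sum(x > m) / n),
        "count_below_mean": float(np.sum(x < m) / n),
        "longest_run_above_mean": _longest_run(x > m) / n,
        "longest_run_below_mean": _longest_run(x < m) / n,
        "zero_crossings_centered": float(np.sum(np.diff(np.sign(centered)) != 0)),
        "sum": float(x.sum()),
    }
    for q in (5, 10, 25, 75, 90, 95):
        feats[f"q{q:02d}"] = float(np.percentile(x, q))
    if sd > 0:
        z = centered / sd
        feats["skewness"] = float(np.mean(z**3))
        feats["kurtosis"] = float(np.mean(z**4) - 3.0)
    else:
        feats["skewness"] = 0.0
        feats["kurtosis"] = 0.0
    # coarse autocorrelation summary
    var = np.var(x)
    for lag_s in (0.1, 0.5, 1.0, 2.0):
        lag = int(round(lag_s / frame_interval))
        key = f"autocorr_{lag_s:g}s"
        if 0 < lag < n and var > _VAR_FLOOR:
            feats[key] = float(centered[:-lag] @ centered[lag:]) / (n * var)
        else:
            feats[key] = 0.0
    # coarse spectral summary of the mean-removed window
    spec = np.abs(np.fft.rfft(centered))
    freqs = np.fft.rfftfreq(n, d=frame_interval)
    power = spec**2
    total = power.sum()
    feats["spectral_total_power"] = float(total)
    if total > 0:
        feats["spectral_centroid_hz"] = float((freqs * power).sum() / total)
        feats["spectral_peak_hz"] = float(freqs[np.argmax(power)])
        p = power / total
        nz = p[p > 0]
        feats["spectral_entropy"] = float(-(nz * np.log(nz)).sum())
    else:
        feats["spectral_centroid_hz"] = 0.0
        feats["spectral_peak_hz"] = 0.0
        feats["spectral_entropy"] = 0.0
    for band, (lo, hi) in {"resp_band": (0.2, 0.4), "low": (0.0, 1.0),
                           "mid": (1.0, 5.0)}.items():
        sel = (freqs >= lo) & (freqs < hi)
        feats[f"power_{band}"] = float(power[sel].sum())
    return pd.Series(feats, dtype=float)


def _longest_run(mask: np.ndarray) -> float:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return float(best)


def prune_constant_features(df: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance columns, then exact duplicate columns."""
    variable = df.loc[:, df.nunique(axis=0) > 1]
    return variable.T.drop_duplicates().T


def estimate_respiratory_cycle(
    trace: DisplacementTrace | np.ndarray,
    frame_interval: float | None = None,
    search_band_s: tuple[float, float] = (1.5, 8.0),
    min_peak: float = 0.3,
) -> float | None:
    """Breathing period from the highest autocorrelation peak in 1.5-8 s.

    Returns the peak lag in seconds, or None when no peak reaches
    ``min_peak`` (e.g. white noise or a breath-hold — the period is
    indeterminate).  Requires at least 10 s of signal.
    """
    if isinstance(trace, DisplacementTrace):
        x, dt = trace.values, trace.frame_interval
    else:
        if frame_interval is None:
            raise ValueError("frame_interval required for a bare array")
        x, dt = np.asarray(trace, dtype=float), float(frame_interval)
    n = x.size
    if n * dt < 10.0:
        raise ValueError("need at least 10 s of signal")
    var = np.var(x)
    if var <= _VAR_FLOOR:
        return None
    xc = x - x.mean()
    max_lag = min(n - 1, int(round(search_band_s[1] / dt)))
    ac = np.array([float(xc[:-lag] @ xc[lag:]) / (n * var)
                   for lag in range(1, max_lag + 1)])
    peaks, _ = sps.find_peaks(ac)
    lo = int(round(search_band_s[0] / dt))
    peaks = peaks[(peaks + 1 >= lo) & (ac[peaks] >= min_peak)]
    if peaks.size == 0:
        return None
    best = peaks[np.argmax(ac[peaks])]
    return float((best + 1) * dt)
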