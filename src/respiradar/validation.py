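"""Validation utilities: reference filtering, waveform agreement, and
pre/post-swallow respiratory-pattern calls.

The band-type reference channel is low-pass filtered (zero-phase Butterworth,
5 Hz cutoff, order 4) before comparison; agreement between radar-derived and
reference waveforms is scored as the zero-lag Pearson correlation of 5 s
breathing-only segments.  The respiratory pattern around a swallow is called
from the mean displacement slope just before onset and just after offset:
positive slope (expiration-positive convention) means the subject was
exhaling, negative inhaling, and a slope below threshold is indeterminate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import RESP, ActivityAnnotation, DisplacementTrace, Interval

__all__ = [
    "CorrelationSummary",
    "SwallowPatternCall",
    "lowpass_reference",
    "cross_correlation",
    "segment_respire_intervals",
    "respiratory_pattern",
    "summarize_correlations",
    "default_slope_threshold",
]

EXPIRATION, INSPIRATION, INDETERMINATE = "expiration", "inspiration", "indeterminate"


@dataclass
class CorrelationSummary:
    """Per-segment waveform correlations with per-subject and pooled stats."""

    per_segment: dict[str, list[float]]  # subject -> correlations
    pooled_mean: float
    pooled_sd: float
    subject_mean: dict[str, float]
    subject_sd: dict[str, float]
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray

    def to_dict(self) -> dict:
        return {
            "pooled_mean": self.pooled_mean,
            "pooled_sd": self.pooled_sd,
            "subject_mean": self.subject_mean,
            "subject_sd": self.subject_sd,
            "histogram_counts": self.histogram_counts.tolist(),
            "histogram_edges": self.histogram_edges.tolist(),
        }


@dataclass(frozen=True)
class SwallowPatternCall:
    """Respiratory phase immediately before and after a swallow pause."""

    pre: str
    post: str

    def __post_init__(self) -> None:
        for v in (self.pre, self.post):
            if v not in (EXPIRATION, INSPIRATION, INDETERMINATE):
                raise ValueError(f"invalid pattern value {v!r}")


def lowpass_reference(
    x: np.ndarray, sampling_rate: float = 100.0, cutoff_hz: float = 5.0,
    order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (DC gain 1) for the reference channel."""
    x = np.asarray(x, dtype=float)
    if sampling_rate <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sampling_rate,
                     output="sos")
    padlen = 3 * (2 * order + 1)
    if x.size <= padlen:
        raise ValueError("input too short for zero-phase filtering")
    return sps.sosfiltfilt(sos, x)


def cross_correlation(
    a: np.ndarray, b: np.ndarray, max_lag_s: float = 0.0,
    sampling_rate: float = 100.0
) -> float:
    """Zero-lag Pearson correlation of two mean-removed segments, in [-1, 1].

    With ``max_lag_s > 0`` the maximum correlation over lags within
    +/- max_lag_s is returned instead, absorbing a fixed sensor delay.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("segments must have equal lengths of at least 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant segment")
    if max_lag_s <= 0:
        return float(np.corrcoef(a, b)[0, 1])
    max_lag = int(round(max_lag_s * sampling_rate))
    best = -1.0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            aa, bb = a[lag:], b[: b.size - lag]
        else:
            aa, bb = a[:lag], b[-lag:]
        if aa.size >= 2 and np.std(aa) > 0 and np.std(bb) > 0:
            best = max(best, float(np.corrcoef(aa, bb)[0, 1]))
    return best


def segment_respire_intervals(
    trace: DisplacementTrace,
    annotation: ActivityAnnotation,
    segment_s: float = 5.0,
    per_trial: int = 3,
) -> list[np.ndarray]:
    """Up to ``per_trial`` non-overlapping breathing-only segments of 5 s."""
    dt = trace.frame_interval
    seg_len = int(round(segment_s / dt))
    segments: list[np.ndarray] = []
    for iv in annotation.with_label(RESP):
        start = int(np.ceil(iv.start / dt - 1e-9))
        stop = int(np.floor(iv.end / dt + 1e-9))
        while start + seg_len <= min(stop, len(trace)):
            if len(segments) >= per_trial:
                return segments
            segments.append(trace.values[start: start + seg_len])
            start += seg_len
    if len(segments) < per_trial:
        warnings.warn(
            f"only {len(segments)} breathing segments available", stacklevel=2
        )
    return segments


def default_slope_threshold(
    trace: DisplacementTrace, annotation: ActivityAnnotation | None = None,
    fraction: float = 0.1
) -> float:
    """10% of the median breathing-slope magnitude (scales with amplitude)."""
    dt = trace.frame_interval
    slopes = np.abs(np.gradient(trace.values, dt))
    if annotation is not None:
        mask = np.zeros(len(trace), dtype=bool)
        t = trace.times
        for iv in annotation.with_label(RESP):
            mask |= (t >= iv.start) & (t < iv.end)
        if mask.any():
            slopes = slopes[mask]
    return float(fraction * np.median(slopes))


def _mean_slope(values: np.ndarray, dt: float) -> float:
    t = dt * np.arange(values.size)
    return float(np.polyfit(t, values, 1)[0])


def respiratory_pattern(
    trace: DisplacementTrace,
    swallow_interval: Interval | tuple[float, float],
    span_s: float = 0.8,
    slope_threshold: float | None = None,
    annotation: ActivityAnnotation | None = None,
) -> SwallowPatternCall:
    """Call the breathing phase in the ``span_s`` before and after a swallow."""
    if isinstance(swallow_interval, Interval):
        onset, offset = swallow_interval.start, swallow_interval.end
    else:
        onset, offset = swallow_interval
    dt = trace.frame_interval
    if slope_threshold is None:
        slope_threshold = default_slope_threshold(trace, annotation)
    span = int(round(span_s / dt))

    def call(segment: np.ndarray) -> str:
        if segment.size < max(2, span // 2):
            return INDETERMINATE
        slope = _mean_slope(segment, dt)
        if abs(slope) < slope_threshold:
            return INDETERMINATE
        return EXPIRATION if slope > 0 else INSPIRATION

    i_on = int(round(onset / dt))
    i_off = int(round(offset / dt))
    pre = trace.values[max(0, i_on - span): i_on]
    post = trace.values[i_off: i_off + span]
    return SwallowPatternCall(pre=call(pre), post=call(post))


def summarize_correlations(per_segment: dict[str, list[float]]
                           ) -> CorrelationSummary:
    """Pool per-subject segment correlations into summary statistics."""
    pooled = np.concatenate([np.asarray(v, dtype=float)
                             for v in per_segment.values() if len(v)])
    if pooled.size == 0:
        raise ValueError("no correlations to summarise")
    if np.any(np.abs(pooled) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    counts, edges = np.histogram(pooled, bins=np.arange(-1.0, 1.0501, 0.05))
    return CorrelationSummary(
        per_segment={k: list(map(float, v)) for k, v in per_segment.items()},
        pooled_mean=float(pooled.mean()),
        pooled_sd=float(pooled.std()),
        subject_mean={k: float(np.mean(v)) for k, v in per_segment.items()
                      if len(v)},
        subject_sd={k: float(np.std(v)) for k, v in per_segment.items()
                    if len(v)},
        histogram_counts=counts,
        histogram_edges=edges,
    )
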