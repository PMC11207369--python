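"""Sliding-window extraction and ground-truth labelling.

Displacement traces are cut into fixed-length windows (4 s = 400 frames by
default) slid every 1 s (100 frames).  Each window takes the label of the
activity at its midpoint sample, except that a swallow interval whose start
and end both fall inside the window overrides the midpoint — short
deglutition apneas would otherwise almost never sit exactly at a midpoint.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import SWAL, ActivityAnnotation, DisplacementTrace

__all__ = ["WindowSample", "WindowDataset", "slide_windows", "label_window",
           "build_dataset"]


@dataclass
class WindowSample:
    """One fixed-length displacement segment with an optional label."""

    values: np.ndarray
    start_time: float
    frame_interval: float
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("window values must be a nonempty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def end_time(self) -> float:
        return self.start_time + self.values.size * self.frame_interval

    @property
    def midpoint_time(self) -> float:
        """Time of the midpoint sample (index W//2 for an even-length window)."""
        return self.start_time + (self.values.size // 2) * self.frame_interval


@dataclass
class WindowDataset:
    """Labelled windows pooled across recordings, with subject group tags."""

    windows: np.ndarray  # (n_windows, window_len)
    labels: np.ndarray   # (n_windows,) str
    groups: np.ndarray   # (n_windows,) str subject ids
    starts: np.ndarray   # (n_windows,) window start time within its recording
    frame_interval: float
    n_excluded: int = 0

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def slide_windows(
    trace: DisplacementTrace, window_s: float = 4.0, stride_s: float = 1.0
) -> list[WindowSample]:
    """Windows at starts 0, stride, 2*stride, ...; trailing partials dropped.

    Yields ``floor((N - W) / S) + 1`` windows for N trace frames, window W
    and stride S frames; an empty list (with a warning) if the trace is
    shorter than one window.
    """
    w = int(round(window_s / trace.frame_interval))
    s = int(round(stride_s / trace.frame_interval))
    if w <= 0 or s <= 0:
        raise ValueError("window and stride must be positive")
    n = len(trace)
    if n < w:
        warnings.warn("trace shorter than one window; no windows extracted",
                      stacklevel=2)
        return []
    return [
        WindowSample(
            values=trace.values[i: i + w],
            start_time=i * trace.frame_interval,
            frame_interval=trace.frame_interval,
        )
        for i in range(0, n - w + 1, s)
    ]


def label_window(window: WindowSample, annotation: ActivityAnnotation
                 ) -> str | None:
    """Ground-truth label: contained-swallow override, else midpoint activity.

    Returns None when the midpoint falls outside every annotated interval;
    such windows are excluded from datasets.
    """
    w0, w1 = window.start_time, window.end_time
    eps = 1e-9
    for iv in annotation.with_label(SWAL):
        if iv.start >= w0 - eps and iv.end <= w1 + eps:
            return SWAL
    return annotation.label_at(window.midpoint_time)


def build_dataset(
    recordings: list[tuple[DisplacementTrace, ActivityAnnotation, str]],
    window_s: float = 4.0,
    stride_s: float = 1.0,
) -> WindowDataset:
    """Pool labelled windows across recordings, keeping subject group tags.

    Windows without a midpoint label are dropped but counted, so
    ``len(dataset) + dataset.n_excluded`` equals the total number of windows
    extracted.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    rows, labels, groups, starts = [], [], [], []
    n_excluded = 0
    dt = recordings[0][0].frame_interval
    for trace, annotation, subject in recordings:
        for window in slide_windows(trace, window_s, stride_s):
            label = label_window(window, annotation)
            if label is None:
                n_excluded += 1
                continue
            rows.append(window.values)
            labels.append(label)
            groups.append(subject)
            starts.append(window.start_time)
    if not rows:
        raise ValueError("no labelled windows were produced")
    return WindowDataset(
        windows=np.vstack(rows),
        labels=np.asarray(labels),
        groups=np.asarray(groups),
        starts=np.asarray(starts, dtype=float),
        frame_interval=dt,
        n_excluded=n_excluded,
    )
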