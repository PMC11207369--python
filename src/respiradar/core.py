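"""Core data containers shared across the pipeline.

The radar records one *sweep* (an amplitude/phase profile over range bins)
per transmission interval.  Chest motion appears as a phase trajectory at the
range bin occupied by the chest surface; everything downstream works on the
displacement trace recovered from that phase.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

#: Activity labels: quiet respiration, commanded breath-hold, swallow
#: (deglutition apnea).
RESP, HOLD, SWAL = "resp", "hold", "swal"
LABELS = (RESP, HOLD, SWAL)


@dataclass(frozen=True)
class RadarConfig:
    """Pulse-coherent radar acquisition geometry.

    Defaults match a 60-GHz-band module sweeping 0.2-0.7 m at 1 mm range
    resolution with a 0.01 s transmission interval.

    Parameters
    ----------
    center_frequency : float
        Carrier frequency ``f`` in Hz used in the phase-to-distance relation
        ``delta_phi = 4 * pi * delta_R * f / c``.
    speed_of_light : float
        Propagation speed ``c`` in m/s.
    frame_interval : float
        Time between successive sweeps, in seconds.
    range_start, range_stop, range_step : float
        Extent and resolution of the range axis, in metres.
    """

    center_frequency: float = 60.5e9
    speed_of_light: float = 2.998e8
    frame_interval: float = 0.01
    range_start: float = 0.2
    range_stop: float = 0.7
    range_step: float = 0.001

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if self.speed_of_light <= 0:
            raise ValueError("speed_of_light must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not self.range_start < self.range_stop:
            raise ValueError("range_start must be below range_stop")
        if self.range_step <= 0:
            raise ValueError("range_step must be positive")

    @property
    def n_bins(self) -> int:
        return int(round((self.range_stop - self.range_start) / self.range_step)) + 1

    @property
    def range_axis(self) -> np.ndarray:
        """Bin centre distances in metres (strictly increasing)."""
        return self.range_start + self.range_step * np.arange(self.n_bins)

    @property
    def wavelength(self) -> float:
        return self.speed_of_light / self.center_frequency

    def to_dict(self) -> dict:
        return {
            "center_frequency": self.center_frequency,
            "speed_of_light": self.speed_of_light,
            "frame_interval": self.frame_interval,
            "range_start": self.range_start,
            "range_stop": self.range_stop,
            "range_step": self.range_step,
        }


@dataclass
class SweepSeries:
    """Time x range-bin matrix of reflected amplitude and wrapped phase.

    ``amplitude`` and ``phase`` have shape (frames, bins); ``times`` is the
    per-frame acquisition time in seconds and ``ranges`` the per-bin distance
    in metres.  Phases are principal values in ``[0, 2*pi)``.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    times: np.ndarray
    ranges: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.ranges = np.asarray(self.ranges, dtype=float)
        if self.amplitude.ndim != 2 or self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must be 2-D with equal shapes")
        if self.amplitude.shape[0] != self.times.size:
            raise ValueError("times length must equal the number of frames")
        if self.amplitude.shape[1] != self.ranges.size:
            raise ValueError("ranges length must equal the number of bins")
        if self.amplitude.shape[0] == 0:
            raise ValueError("sweep series must contain at least one frame")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be nonnegative")
        if np.any(self.phase < 0) or np.any(self.phase >= TWO_PI):
            raise ValueError("phases must lie in [0, 2*pi)")
        for axis in (self.times, self.ranges):
            if axis.size > 1 and np.any(np.diff(axis) <= 0):
                raise ValueError("axes must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_bins(self) -> int:
        return self.amplitude.shape[1]

    @property
    def frame_interval(self) -> float:
        if self.times.size < 2:
            raise ValueError("frame interval undefined for a single frame")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sweep series is not uniformly sampled")
        return float(steps[0])


@dataclass
class DisplacementTrace:
    """Uniformly sampled chest-displacement series in millimetres.

    ``expiration_positive`` records the sign convention: the chest recedes
    from a front-mounted radar while exhaling, so an increase in radar-to-
    chest distance is plotted as positive displacement.
    """

    values: np.ndarray
    frame_interval: float
    expiration_positive: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("displacement values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("displacement values must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.frame_interval * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.frame_interval * self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "displacement_mm": self.values}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, expiration_positive: bool = True
                   ) -> "DisplacementTrace":
        t = np.asarray(df["time_s"], dtype=float)
        if t.size < 2:
            raise ValueError("need at least two samples to infer the interval")
        return cls(
            values=np.asarray(df["displacement_mm"], dtype=float),
            frame_interval=float(t[1] - t[0]),
            expiration_positive=expiration_positive,
        )


@dataclass(frozen=True)
class Interval:
    """One annotated activity interval, end-exclusive: ``[start, end)``."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("interval start must precede its end")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ActivityAnnotation:
    """Ground-truth activity intervals for one recording.

    ``instruction_delay_applied`` flags whether the breath-hold intervals have
    already been shifted by the subject's reaction delay to the on-screen
    instruction (0.5 s by default in the simulator).
    """

    intervals: tuple[Interval, ...]
    instruction_delay_applied: bool = True

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals, key=lambda iv: iv.start))
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError("annotation intervals must not overlap")
        self.intervals = ivs

    def label_at(self, t: float) -> str | None:
        """Label of the interval containing time ``t``; None if uncovered."""
        for iv in self.intervals:
            if iv.start <= t < iv.end:
                return iv.label
        return None

    def with_label(self, label: str) -> tuple[Interval, ...]:
        return tuple(iv for iv in self.intervals if iv.label == label)

    @property
    def duration(self) -> float:
        return max(iv.end for iv in self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [iv.start for iv in self.intervals],
                "end_s": [iv.end for iv in self.intervals],
                "label": [iv.label for iv in self.intervals],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, instruction_delay_applied: bool = True
                   ) -> "ActivityAnnotation":
        ivs = tuple(
            Interval(float(r.start_s), float(r.end_s), str(r.label))
            for r in df.itertuples()
        )
        return cls(ivs, instruction_delay_applied)


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Principal value of a phase in ``[0, 2*pi)``."""
    return np.mod(phi, TWO_PI)
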