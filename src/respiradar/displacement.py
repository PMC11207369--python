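"""Chest-displacement estimation from radar sweeps.

The chest surface is located as the range bin whose amplitude is most often
the per-frame maximum (the mode over the extracted interval, which is robust
to single-frame noise outliers).  The wrapped phase at that bin is unwrapped
with the exceeds-pi rule and converted to a distance change through

    delta_phi = 4 * pi * delta_R * f / c

so a 1 mm chest movement at 60 GHz appears as a ~144 degree phase change.
No filtering is applied: the raw unwrapped phase is handed downstream.
"""
from __future__ import annotations

import numpy as np

from .core import TWO_PI, DisplacementTrace, RadarConfig, SweepSeries

__all__ = [
    "select_range_bin",
    "extract_phase",
    "unwrap_phase",
    "phase_to_displacement",
    "displacement_to_phase",
    "estimate_displacement",
]


def select_range_bin(sweeps: SweepSeries) -> int:
    """Target range bin: mode of the per-frame argmax-amplitude bin.

    Ties within a frame resolve to the lowest bin (argmax convention); ties
    in the mode also resolve to the lowest bin.
    """
    per_frame = np.argmax(sweeps.amplitude, axis=1)
    counts = np.bincount(per_frame, minlength=sweeps.n_bins)
    return int(np.argmax(counts))


def extract_phase(sweeps: SweepSeries, bin_index: int) -> np.ndarray:
    """Wrapped phase series (one value per frame) at ``bin_index``."""
    if not 0 <= bin_index < sweeps.n_bins:
        raise IndexError(f"bin {bin_index} outside [0, {sweeps.n_bins})")
    return sweeps.phase[:, bin_index].copy()


def unwrap_phase(phases: np.ndarray) -> np.ndarray:
    """Remove 2*pi boundary crossings from a wrapped phase series.

    A successive difference whose magnitude strictly exceeds pi is treated
    as a boundary crossing and corrected by one full turn; a difference of
    exactly pi is left as-is.  The first sample is returned unchanged, so the
    output is elementwise congruent to the input modulo 2*pi.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 1 or phases.size == 0:
        raise ValueError("phase series must be a nonempty 1-D array")
    if phases.size == 1:
        return phases.copy()
    diffs = np.diff(phases)
    # wrapped inputs lie in [0, 2*pi), so one correction is always enough
    incr = diffs - TWO_PI * (diffs > np.pi) + TWO_PI * (diffs < -np.pi)
    out = np.empty_like(phases)
    out[0] = phases[0]
    out[1:] = phases[0] + np.cumsum(incr)
    return out


def phase_to_displacement(
    delta_phi: np.ndarray | float, config: RadarConfig | None = None
) -> np.ndarray | float:
    """Distance change in metres for a phase change in radians.

    Inverts ``delta_phi = 4 * pi * delta_R * f / c``; linear and
    sign-preserving.
    """
    config = config or RadarConfig()
    delta_phi = np.asarray(delta_phi, dtype=float)
    if not np.all(np.isfinite(delta_phi)):
        raise ValueError("phase change must be finite")
    out = delta_phi * config.speed_of_light / (4.0 * np.pi * config.center_frequency)
    return float(out) if out.ndim == 0 else out


def displacement_to_phase(
    delta_r: np.ndarray | float, config: RadarConfig | None = None
) -> np.ndarray | float:
    """Phase change in radians for a distance change in metres (forward model)."""
    config = config or RadarConfig()
    delta_r = np.asarray(delta_r, dtype=float)
    out = 4.0 * np.pi * delta_r * config.center_frequency / config.speed_of_light
    return float(out) if out.ndim == 0 else out


def estimate_displacement(
    sweeps: SweepSeries, config: RadarConfig | None = None
) -> DisplacementTrace:
    """Full displacement estimate: bin selection -> phase -> unwrap -> Eq. scale.

    The absolute offset is discarded (only distance *changes* are physical),
    so the returned trace starts at 0 mm.  Because the chest recedes from a
    front-mounted radar during exhalation, a positive distance change already
    is expiration-positive; no sign flip is needed.
    """
    config = config or RadarConfig()
    bin_index = select_range_bin(sweeps)
    wrapped = extract_phase(sweeps, bin_index)
    unwrapped = unwrap_phase(wrapped)
    delta_r = phase_to_displacement(unwrapped - unwrapped[0], config)
    if sweeps.n_frames > 1:
        dt = sweeps.frame_interval
    else:
        dt = config.frame_interval
    return DisplacementTrace(
        values=np.atleast_1d(delta_r) * 1000.0,
        frame_interval=dt,
        expiration_positive=True,
    )
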