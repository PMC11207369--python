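"""Persistence: sweep containers, traces and annotations on disk.

Sweeps are stored as a compressed array container (``.npz`` with amplitude,
phase, times and ranges) plus a JSON metadata sidecar carrying the radar
configuration; traces and annotations are plain CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ActivityAnnotation, DisplacementTrace, RadarConfig, SweepSeries

__all__ = [
    "save_sweeps", "load_sweeps",
    "save_trace", "load_trace",
    "save_annotation", "load_annotation",
]


def save_sweeps(path: str | Path, sweeps: SweepSeries,
                config: RadarConfig | None = None) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        amplitude=sweeps.amplitude,
        phase=sweeps.phase,
        times=sweeps.times,
        ranges=sweeps.ranges,
    )
    sidecar = path.with_suffix(".json")
    meta = {"format": "respiradar-sweeps", "version": 1,
            "n_frames": sweeps.n_frames, "n_bins": sweeps.n_bins}
    if config is not None:
        meta["radar_config"] = config.to_dict()
    sidecar.write_text(json.dumps(meta, indent=2))


def load_sweeps(path: str | Path) -> tuple[SweepSeries, RadarConfig | None]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        sweeps = SweepSeries(
            amplitude=data["amplitude"], phase=data["phase"],
            times=data["times"], ranges=data["ranges"],
        )
    sidecar = path.with_suffix(".json")
    config = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "radar_config" in meta:
            config = RadarConfig(**meta["radar_config"])
    return sweeps, config


def save_trace(path: str | Path, trace: DisplacementTrace) -> None:
    trace.to_frame().to_csv(path, index=False)


def load_trace(path: str | Path) -> DisplacementTrace:
    return DisplacementTrace.from_frame(pd.read_csv(path))


def save_annotation(path: str | Path, annotation: ActivityAnnotation) -> None:
    annotation.to_frame().to_csv(path, index=False)


def load_annotation(path: str | Path) -> ActivityAnnotation:
    return ActivityAnnotation.from_frame(pd.read_csv(path))
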