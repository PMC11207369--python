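"""Synthetic chest motion, radar sweeps and a band-sensor reference channel.

Real recordings of this kind are not openly available, so the simulator
emulates the study conditions end to end: quasi-periodic breathing (period
2.5-5 s, peak-to-peak amplitude 2-8 mm, asymmetric inspiration/expiration),
commanded breath-holds realised 0.5 s after the instruction, and short flat
swallow pauses (0.3-1.5 s) inserted at a configurable point of the breathing
cycle (mid-expiration by default, the dominant exhale-swallow-exhale
coordination in healthy adults).  Sweeps are rendered with the radar forward
model: a Gaussian amplitude peak at the chest bin plus wrapped phase
4*pi*f*d(t)/c with Gaussian phase noise (sd 6.1 degrees by default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .core import (
    HOLD,
    LABELS,
    RESP,
    SWAL,
    TWO_PI,
    ActivityAnnotation,
    DisplacementTrace,
    Interval,
    RadarConfig,
    SweepSeries,
    wrap_phase,
)

__all__ = [
    "SubjectProfile",
    "TrialSchedule",
    "generate_motion",
    "render_sweeps",
    "render_band_signal",
    "simulate_recordings",
]

#: Shortest usable recording: one analysis window (seconds).
MIN_SCHEDULE_S = 4.0


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject physiological and noise parameters.

    Parameters
    ----------
    breathing_period : float
        Respiratory cycle in seconds; healthy adults span roughly 2.5-5 s.
    breathing_amplitude : float
        Peak-to-peak chest excursion in mm (natural breathing stays below
        10 mm; 2-8 mm is typical here).
    inspiration_fraction : float
        Fraction of the cycle spent inhaling, in (0, 1); inhalation is
        normally the shorter limb.
    swallow_pause_duration : float
        Length of the deglutition apnea plateau in seconds (0.3-1.5 s).
    baseline_distance : float
        Resting radar-to-chest distance in metres; must keep the chest
        inside the swept range.
    motion_noise_sd : float
        Gaussian jitter added to the motion trace, mm.
    phase_noise_sd : float
        Radar phase noise, degrees (6.1 matches the sensor's bench spec).
    period_variability, amplitude_variability : float
        Coefficient of variation of the slow breath-to-breath drift in cycle
        period and depth; ~0.1 is typical of resting adults.  Set to 0 for a
        strictly periodic oracle signal.
    seed : int
        Seed for every random draw tied to this subject/trial.
    """

    breathing_period: float = 3.8
    breathing_amplitude: float = 5.0
    inspiration_fraction: float = 0.4
    swallow_pause_duration: float = 1.0
    baseline_distance: float = 0.45
    motion_noise_sd: float = 0.05
    phase_noise_sd: float = 6.1
    period_variability: float = 0.1
    amplitude_variability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2.5 <= self.breathing_period <= 5.0:
            raise ValueError("breathing_period must lie in [2.5, 5.0] s")
        if not 0 < self.breathing_amplitude < 10.0:
            raise ValueError("breathing_amplitude must be in (0, 10) mm")
        if not 0 < self.inspiration_fraction < 1:
            raise ValueError("inspiration_fraction must lie in (0, 1)")
        if self.swallow_pause_duration <= 0:
            raise ValueError("swallow_pause_duration must be positive")
        if not 0.25 <= self.baseline_distance <= 0.65:
            raise ValueError("baseline_distance must lie in [0.25, 0.65] m")
        if self.motion_noise_sd < 0 or self.phase_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if not 0 <= self.period_variability < 0.5:
            raise ValueError("period_variability must lie in [0, 0.5)")
        if not 0 <= self.amplitude_variability < 0.5:
            raise ValueError("amplitude_variability must lie in [0, 0.5)")

    @classmethod
    def random(cls, rng: np.random.Generator, seed: int | None = None
               ) -> "SubjectProfile":
        """Draw a subject from the study's population ranges."""
        return cls(
            breathing_period=float(rng.uniform(2.5, 5.0)),
            breathing_amplitude=float(rng.uniform(2.0, 8.0)),
            inspiration_fraction=float(rng.uniform(0.33, 0.47)),
            swallow_pause_duration=float(rng.uniform(0.3, 1.5)),
            baseline_distance=float(rng.uniform(0.30, 0.60)),
            seed=int(rng.integers(2**31) if seed is None else seed),
        )


@dataclass(frozen=True)
class TrialSchedule:
    """Instructed activity sequence for one trial.

    ``segments`` is an ordered list of ``(label, duration_s)`` pairs; the
    instruction delay models the lag between the on-screen prompt and the
    subject's response and is applied to breath-hold intervals only.
    """

    segments: tuple[tuple[str, float], ...]
    instruction_delay: float = 0.5

    def __post_init__(self) -> None:
        segments = tuple((str(lab), float(dur)) for lab, dur in self.segments)
        object.__setattr__(self, "segments", segments)
        if not segments:
            raise ValueError("schedule must contain at least one segment")
        for lab, dur in segments:
            if lab not in LABELS:
                raise ValueError(f"unknown activity {lab!r}")
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if lab == SWAL and dur > 2.0:
                raise ValueError("a swallow pause cannot exceed 2 s")
        if self.total_duration < MIN_SCHEDULE_S:
            raise ValueError(
                f"schedule must span at least one {MIN_SCHEDULE_S:.0f} s window"
            )
        if self.instruction_delay < 0:
            raise ValueError("instruction_delay must be nonnegative")

    @property
    def total_duration(self) -> float:
        return sum(dur for _, dur in self.segments)

    @classmethod
    def default(cls, swallow_duration: float = 1.0) -> "TrialSchedule":
        """Breathe / hold / breathe / swallow / breathe template (~36 s)."""
        return cls(
            (
                (RESP, 10.0),
                (HOLD, 5.0),
                (RESP, 10.0),
                (SWAL, swallow_duration),
                (RESP, 10.0),
            )
        )


def _breath_shape(phase: np.ndarray | float, inspiration_fraction: float
                  ) -> np.ndarray:
    """Raised-cosine breathing waveform of unit peak-to-peak, expiration-positive.

    Cycle phase 0 is end-expiration (maximum +1/2); the chest falls to -1/2
    over the inspiratory limb and rises back over the (longer) expiratory
    limb.  Both turning points have zero slope, so plateaus splice in
    smoothly.
    """
    phi = np.mod(np.asarray(phase, dtype=float), 1.0)
    fi = inspiration_fraction
    insp = 0.5 * np.cos(np.pi * phi / fi)
    expi = -0.5 * np.cos(np.pi * (phi - fi) / (1.0 - fi))
    return np.where(phi < fi, insp, expi)


def _phase_modulator(rng: np.random.Generator, n_components: int = 3):
    """Smooth zero-mean unit-rms drift as a function of cycle phase.

    A mixture of a few incommensurate slow sinusoids (0.05-0.35 drift cycles
    per breathing cycle).  Because it is a function of the *cycle phase* it
    freezes during pauses, keeping plateaus continuous with the breathing on
    both sides.
    """
    freqs = rng.uniform(0.05, 0.35, n_components)
    offsets = rng.uniform(0.0, TWO_PI, n_components)
    coeffs = rng.normal(0.0, 1.0, n_components)
    rms = np.sqrt((coeffs**2).sum() / 2.0)
    coeffs = coeffs / rms if rms > 0 else coeffs

    def mod(phi):
        phi = np.asarray(phi, dtype=float)
        return np.sin(TWO_PI * freqs * phi[..., None] + offsets) @ coeffs

    return mod


def _breath_amplitude(profile: SubjectProfile, modulator, phi) -> np.ndarray:
    """Instantaneous peak-to-peak amplitude, capped below the 10 mm envelope."""
    a = profile.breathing_amplitude
    if profile.amplitude_variability == 0:
        return np.full(np.shape(np.asarray(phi, dtype=float)), a)
    factor = 1.0 + profile.amplitude_variability * modulator(phi)
    return a * np.clip(factor, 0.6, min(1.4, 9.9 / a))


def _realized_intervals(schedule: TrialSchedule
                        ) -> tuple[list[Interval], float]:
    """Translate instructed segments into realised pause intervals.

    Breath-holds start (and end) ``instruction_delay`` after the prompt;
    swallow intervals are taken at face value (the camera-derived truth in
    the real protocol needs no reaction correction).
    """
    delay = schedule.instruction_delay
    total = schedule.total_duration
    pauses: list[Interval] = []
    t = 0.0
    for lab, dur in schedule.segments:
        if lab == HOLD:
            start, end = t + delay, t + dur + delay
            if end > total:
                raise ValueError(
                    "instruction delay pushes a breath-hold past the trial end"
                )
            pauses.append(Interval(start, end, HOLD))
        elif lab == SWAL:
            pauses.append(Interval(t, t + dur, SWAL))
        t += dur
    pauses.sort(key=lambda iv: iv.start)
    for a, b in zip(pauses, pauses[1:]):
        if b.start < a.end:
            raise ValueError("realised pause intervals overlap; add breathing "
                             "time between instructed pauses")
    return pauses, total


def generate_motion(
    profile: SubjectProfile,
    schedule: TrialSchedule,
    frame_interval: float = 0.01,
    swallow_phase: float | None = None,
) -> tuple[DisplacementTrace, ActivityAnnotation]:
    """Ground-truth chest displacement plus its activity annotation.

    Breathing segments follow the subject's raised-cosine cycle; hold and
    swallow segments freeze the cycle phase, producing flat plateaus that are
    continuous with the surrounding breathing.  Ahead of a swallow the cycle
    rate is nudged (by at most a fraction of a cycle over the whole breathing
    stretch) so the plateau lands at ``swallow_phase`` — mid-expiration when
    not specified.  With a fixed profile seed the output is bit-identical.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if swallow_phase is None:
        fi = profile.inspiration_fraction
        swallow_phase = fi + (1.0 - fi) / 2.0  # middle of the expiratory limb
    swallow_phase = float(np.mod(swallow_phase, 1.0))

    pauses, total = _realized_intervals(schedule)
    n = int(round(total / frame_interval))
    tt = frame_interval * np.arange(n)
    values = np.empty(n, dtype=float)

    mod_rng = np.random.default_rng([profile.seed, 2])
    rate_mod = _phase_modulator(mod_rng)
    amp_mod = _phase_modulator(mod_rng)
    pv = profile.period_variability
    base_rate = 1.0 / profile.breathing_period

    # breathing gaps between pauses (and before/after the first/last pause)
    edges = [0.0] + [b for iv in pauses for b in (iv.start, iv.end)] + [total]
    phi = 0.0
    for k in range(0, len(edges) - 1, 2):
        g0, g1 = edges[k], edges[k + 1]
        pause = pauses[k // 2] if k // 2 < len(pauses) else None
        if g1 > g0:  # breathing stretch
            steps = int(round((g1 - g0) / frame_interval))
            if pv == 0:
                phis = phi + base_rate * frame_interval * np.arange(steps)
                end_phase = phi + base_rate * (g1 - g0)
            else:
                # integrate the slowly drifting cycle rate sample by sample
                phis = np.empty(steps)
                p = phi
                for j in range(steps):
                    phis[j] = p
                    rate = base_rate * (1.0 + pv * float(rate_mod(p)))
                    p += frame_interval * max(rate, 0.2 * base_rate)
                end_phase = p
            if pause is not None and pause.label == SWAL:
                # rescale this stretch's phase advance so the cycle lands on
                # the swallow phase exactly at the pause onset
                turns_raw = end_phase - phi
                frac = np.mod(swallow_phase - phi, 1.0)
                turns = max(0.0, round(turns_raw - frac)) + frac
                if turns < 0.25:  # never stall the cycle completely
                    turns += 1.0
                phis = phi + (phis - phi) * (turns / turns_raw)
                end_phase = phi + turns
            mask = (tt >= g0 - 1e-9) & (tt < g1 - 1e-9)
            phis = phis[: int(mask.sum())]
            values[mask] = _breath_amplitude(profile, amp_mod, phis) * \
                _breath_shape(phis, profile.inspiration_fraction)
            phi = end_phase
        if pause is not None:
            mask = (tt >= pause.start - 1e-9) & (tt < pause.end - 1e-9)
            values[mask] = float(
                _breath_amplitude(profile, amp_mod, phi)
                * _breath_shape(phi, profile.inspiration_fraction)
            )

    if profile.motion_noise_sd > 0:
        rng = np.random.default_rng([profile.seed, 0])
        values = values + rng.normal(0.0, profile.motion_noise_sd, n)

    # annotation: pauses as realised, breathing filling the gaps
    intervals: list[Interval] = list(pauses)
    for k in range(0, len(edges) - 1, 2):
        if edges[k + 1] > edges[k] + 1e-9:
            intervals.append(Interval(edges[k], edges[k + 1], RESP))
    annotation = ActivityAnnotation(tuple(intervals), instruction_delay_applied=True)
    trace = DisplacementTrace(values, frame_interval, expiration_positive=True)
    return trace, annotation


def render_sweeps(
    trace: DisplacementTrace,
    config: RadarConfig | None = None,
    profile: SubjectProfile | None = None,
    amplitude_noise_sd: float = 0.02,
    range_falloff_bins: float = 3.0,
) -> SweepSeries:
    """Radar forward model: displacement trace -> amplitude/phase sweeps.

    The instantaneous radar-to-chest distance is the subject's baseline plus
    the (expiration-positive) displacement.  Per frame, amplitude peaks at
    the nearest range bin with a Gaussian falloff of ``range_falloff_bins``
    bins, and the wrapped phase everywhere tracks ``4*pi*f*d(t)/c`` plus
    Gaussian phase noise of ``profile.phase_noise_sd`` degrees.
    """
    config = config or RadarConfig()
    profile = profile or SubjectProfile()
    distance = profile.baseline_distance + trace.values / 1000.0
    if distance.min() < config.range_start or distance.max() > config.range_stop:
        raise ValueError("chest motion leaves the swept range")

    n = distance.size
    ranges = config.range_axis
    rng = np.random.default_rng([profile.seed, 1])

    sigma = range_falloff_bins * config.range_step
    amp = np.exp(-((ranges[None, :] - distance[:, None]) ** 2) / (2.0 * sigma**2))
    if amplitude_noise_sd > 0:
        amp = amp + rng.normal(0.0, amplitude_noise_sd, amp.shape)
    amp = np.clip(amp, 0.0, None)

    phase = (4.0 * np.pi * config.center_frequency / config.speed_of_light
             ) * distance[:, None]
    phase = np.broadcast_to(phase, amp.shape)
    sd_rad = np.deg2rad(profile.phase_noise_sd)
    if sd_rad > 0:
        phase = phase + rng.normal(0.0, sd_rad, amp.shape)
    phase = wrap_phase(phase)

    times = trace.frame_interval * np.arange(n)
    return SweepSeries(amplitude=amp, phase=phase, times=times, ranges=ranges)


def render_band_signal(
    trace: DisplacementTrace,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Band-type chest-circumference reference: gain x displacement + noise.

    Shares the trace's sampling grid; arbitrary units.
    """
    out = gain * trace.values
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, out.size)
    return out


def simulate_recordings(
    n_subjects: int = 19,
    trials_per_subject: int = 10,
    seed: int = 0,
    through_radar: bool = True,
    config: RadarConfig | None = None,
    motion_noise_sd: float | None = None,
    phase_noise_sd: float | None = None,
    schedule: TrialSchedule | None = None,
) -> list[tuple[DisplacementTrace, ActivityAnnotation, str]]:
    """Simulate a cohort: per subject a fixed physiology, per trial fresh noise.

    When ``through_radar`` is true each trial is rendered to sweeps and run
    back through the displacement estimator, so downstream stages see
    radar-derived traces rather than the noiseless truth.
    """
    from .displacement import estimate_displacement  # local: avoid cycle at import

    config = config or RadarConfig()
    root = np.random.SeedSequence(seed)
    recordings: list[tuple[DisplacementTrace, ActivityAnnotation, str]] = []
    for i, subject_ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(subject_ss)
        profile = SubjectProfile.random(rng)
        if motion_noise_sd is not None:
            profile = replace(profile, motion_noise_sd=motion_noise_sd)
        if phase_noise_sd is not None:
            profile = replace(profile, phase_noise_sd=phase_noise_sd)
        sched = schedule or TrialSchedule.default(profile.swallow_pause_duration)
        for _ in range(trials_per_subject):
            trial = replace(profile, seed=int(rng.integers(2**31)))
            trace, annotation = generate_motion(trial, sched,
                                                frame_interval=config.frame_interval)
            if through_radar:
                sweeps = render_sweeps(trace, config, trial)
                trace = estimate_displacement(sweeps, config)
            recordings.append((trace, annotation, f"S{i:02d}"))
    return recordings
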