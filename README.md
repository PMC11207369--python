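# respiradar

Unconstrained respiratory measurement and swallow-apnea identification from
millimetre-wave pulse-coherent radar sweeps.

Breathing pauses briefly while a person swallows (deglutition apnea), and the
respiratory phase around that pause carries clinically relevant information
about aspiration risk, especially in older adults. `respiradar` implements a
contact-free way to observe this: a 60-GHz-band pulse-coherent radar pointed
at the chest records, every 10 ms, an amplitude/phase profile over 1 mm range
bins (0.2–0.7 m). Chest motion of a few millimetres appears as a large phase
change at the chest's range bin, so the displacement waveform of breathing —
and its interruptions by breath-holds and swallows — can be recovered without
any worn sensor. The package is written for physiological-monitoring and
biomedical-signal researchers who want a fully testable reference
implementation of this pipeline; because recordings of this kind are not
openly available, it ships a first-class synthetic cohort simulator that
stands in for the human data at every stage.

## Method

1. **Displacement estimation.** The chest bin is chosen as the mode over
   frames of the per-frame argmax-amplitude bin. The wrapped phase φ(t) at
   that bin is unwrapped (a successive difference exceeding π is corrected by
   2π) and converted to a distance change by the pulse-coherent relation

   Δφ = 4π · ΔR · f / c,

   with f the carrier (60.5 GHz by default) and c the speed of light: 1 mm of
   motion ≈ 144° of phase at 60 GHz, and the sensor's 6.1° phase noise floor
   corresponds to ≈ 42 μm. No filtering is applied to the recovered trace.
2. **Windowing and labels.** The trace is cut into 4 s (400-frame) windows
   slid every 1 s. A window is labelled by the activity at its midpoint
   sample — except that a swallow interval contained entirely inside the
   window overrides the midpoint, since a sub-second apnea rarely sits
   exactly at a midpoint.
3. **Designed features.** Each window yields 40 numbers: ten symmetric
   inter-quantile spans of the movement range (IQR-like, robust to spikes),
   ten autocorrelation values at lags 0.4–4.0 s, ten low-frequency FFT
   magnitudes (0.25–2.5 Hz), and ten histogram fractions over equal-width
   bins spanning min–max.
4. **Classification.** Because quiet breathing dominates the data, training
   uses balanced class weights w_c = N/(k·n_c) and model selection maximises
   the macro-averaged F1 score under leave-one-subject-out cross-validation.
   Linear/RBF margin classifiers and a random-forest ensemble are provided.
5. **Validation utilities.** Zero-phase Butterworth low-pass (5 Hz, order 4)
   for a band-type chest-circumference reference channel, zero-lag Pearson
   correlation of 5 s breathing segments between channels, and an automated
   call of the respiratory phase (expiration/inspiration/indeterminate)
   immediately before and after each swallow from the local displacement
   slope.

## Worked example

```python
import numpy as np
import respiradar as rr
from respiradar.features import estimate_respiratory_cycle, feature_matrix
from respiradar.classify import TrainConfig, cross_validated_report

# one subject, one trial: breathe / hold / breathe / swallow / breathe
profile = rr.SubjectProfile(breathing_period=3.8, breathing_amplitude=5.0, seed=42)
truth, annotation = rr.generate_motion(profile, rr.TrialSchedule.default(1.0))
sweeps = rr.render_sweeps(truth, rr.RadarConfig(), profile)
trace = rr.estimate_displacement(sweeps)
print(f"r = {np.corrcoef(trace.values, truth.values)[0, 1]:.4f}")
print(f"period = {estimate_respiratory_cycle(trace):.2f} s")

# a small cohort, end to end
recordings = rr.simulate_recordings(n_subjects=5, trials_per_subject=4, seed=0)
dataset = rr.build_dataset(recordings)
table = feature_matrix(dataset)
X = table[[c for c in table.columns if c not in ("subject", "start_s", "label")]].to_numpy()
report = cross_validated_report(X, dataset.labels, dataset.groups,
                                TrainConfig(), params={"n_estimators": 300})
print(report)
```

Output:

```
r = 0.9997
period = 3.66 s
            Pred.
              hold    resp    swal
       hold    100       0       0
Ans.   resp      4     458       6
       swal      7      28      41
hold: precision=0.901 recall=1.000 F1=0.948
resp: precision=0.942 recall=0.979 F1=0.960
swal: precision=0.872 recall=0.539 F1=0.667
macro-F1=0.858
```

The radar-derived trace reproduces the true chest motion almost exactly
(r = 0.9997 despite the 6.1° phase noise), and the autocorrelation-based
period estimate lands near the subject's 3.8 s cycle. On this deliberately
small 5-subject cohort the class-weighted forest separates breath-holds
perfectly, while swallows — short plateaus easily confused with breathing —
are the weakest class, the same difficulty ordering seen at full cohort
scale. A larger simulation (19 subjects × 10 trials) raises the
leave-one-subject-out macro-F1 above 0.9; see `tests/test_acceptance.py`.

A `respiradar` command-line tool exposes the same pipeline as `simulate`,
`estimate`, `featurize`, `train` and `validate` subcommands.

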