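# Methods

This note records the models, conventions and numerical choices behind
`respiradar`, in the order the pipeline runs.

## Radar forward and inverse model

A pulse-coherent radar transmits phase-controlled pulses every
`frame_interval` (0.01 s) and records, per 1 mm range bin between 0.2 and
0.7 m, the reflected amplitude and the wrapped phase in [0, 2π). Target
displacement ΔR maps to phase change by Δφ = 4π·ΔR·f/c. At the 60.5 GHz
centre frequency one wavelength is ≈ 4.96 mm, so breathing excursions of a
few millimetres span several radians — easily resolved — while the sensor's
6.1° phase jitter corresponds to only ≈ 42 μm of apparent motion.

**Bin selection.** The chest bin is the mode, over the analysed interval, of
the per-frame argmax-amplitude bin. The mode (rather than per-frame argmax)
suppresses single-frame amplitude outliers; it assumes the subject holds
posture over the interval. Ties inside a frame and ties in the mode both
resolve to the lower bin, a fixed arbitrary convention.

**Unwrapping.** Successive wrapped-phase differences whose magnitude
*strictly exceeds* π are corrected by one full turn; a difference of exactly
π is left alone. Because inputs are principal values in [0, 2π), one
correction per step suffices. The output is congruent to the input modulo 2π
elementwise, and its increments never exceed π in magnitude. Recovery is
exact only while the true per-frame motion stays below c/(4f) ≈ 1.24 mm per
10 ms frame (a quarter wavelength); beyond that the increment aliases by half
a wavelength. Breathing at ≤ 10 mm peak-to-peak and ≥ 2.5 s period stays an
order of magnitude below this bound.

**Scale and sign.** Only phase *changes* are physical, so the estimated
trace is anchored at 0 mm at the first frame and the absolute offset is
discarded. The chest recedes from a front-mounted radar during exhalation,
so a positive distance change is already "expiration-positive"; traces carry
an `expiration_positive` flag rather than being renegotiated downstream. The
carrier used in the conversion defaults to the 60.5 GHz centre frequency and
is configurable (the difference against 60 GHz is a 0.8% scale factor). No
filtering is applied to the estimated displacement; the raw unwrapped phase
is what downstream stages see.

## Synthetic cohort

No recordings of this kind are openly available, so the simulator emulates
the study conditions and serves as the ground truth for every test.

* **Breathing waveform.** Raised-cosine half-cycles with separate
  inspiratory and expiratory durations (`inspiration_fraction`, drawn in
  0.33–0.47 — inhalation is the shorter limb). The turning points have zero
  slope, so pause plateaus splice in smoothly, and the waveform spends more
  time near its extremes than a sine, giving the two-peak displacement
  histogram characteristic of real breathing windows.
* **Quasi-periodicity.** Cycle period and depth drift slowly from breath to
  breath (CV 0.1 each, typical of resting adults). The drift is a smooth
  mixture of slow sinusoids *in cycle phase*, so it freezes during pauses
  and never breaks plateau continuity. Setting both CVs to zero yields a
  strictly periodic oracle signal for closed-form tests.
* **Population ranges.** Period 2.5–5 s, peak-to-peak amplitude 2–8 mm
  (instantaneous amplitude capped at 9.9 mm), swallow pause 0.3–1.5 s,
  baseline distance 0.30–0.60 m — each drawn once per subject; per-trial
  randomness reseeds only the noise.
* **Schedule.** The default trial is breathe 10 s / hold 5 s / breathe 10 s /
  swallow / breathe 10 s (~36 s). Breath-holds are realised 0.5 s after the
  instruction (start and end both shifted, duration preserved), modelling
  reaction delay; swallow intervals need no such correction. At 19 subjects
  × 10 trials this yields ≈ 6200 windows with class counts ordered
  respire ≫ hold > swallow (≈ 4500/950/690), the imbalance structure of the
  motivating study design.
* **Swallow placement.** The pause is inserted at a configurable cycle
  phase. The default is mid-expiration, reflecting the dominant
  exhale–swallow–exhale coordination in healthy adults; the breathing rate
  over the preceding stretch is rescaled by at most a fraction of a cycle so
  the plateau lands exactly there.
* **Radar rendering.** Amplitude peaks at the chest's bin with a Gaussian
  falloff of 3 bins (any peaked profile works with mode-of-argmax
  selection) plus white amplitude noise (sd 0.02 of peak); phase tracks the
  forward relation plus Gaussian noise of sd 6.1° independently per frame
  and bin. A band-type reference channel is gain × displacement + white
  noise on the same grid.
* **What is *not* modelled:** multipath reflections (the range restriction
  avoids them), clothing penetration, gross body-movement artifacts, and
  sensor-specific drift. Passing tests on this cohort therefore demonstrate
  the correctness of the processing chain and its behaviour under the
  stated noise, not robustness to real-world motion artifacts — the
  dominant error source reported for measurements of this kind.

## Windowing, labels, features

Windows are 4 s (400 frames) slid every 1 s; both are configurable, and a
window-size sweep utility re-runs the full chain for sizes 2–6 s with the
labelling rules held fixed. The midpoint of an even-length window is the
sample at index W/2. A window whose midpoint is uncovered by any annotation
is excluded (and counted); a swallow interval whose start and end both fall
inside the window overrides the midpoint label.

The four feature families (10 values each, 40 total) are described in the
README. Concrete choices within each family: quantile spans at 5% steps so
k = 5 is the IQR and k = 10 is max–min; autocorrelation lags at 0.4 s steps
with the biased (zero-padded) estimator, which keeps values in [−1, 1] and
returns 0 at lags past the window length; the 10 lowest positive-frequency
DFT magnitudes of the mean-removed window; histogram fractions (not counts)
so the family is window-length independent, with a flat window placing all
mass in the first bin to preserve the pause-vs-breathing contrast. FFT
features are magnitudes rather than power, and histograms fractions rather
than counts — either convention is defensible; these were fixed once.

An optional "general features" arm computes ~55 standard time-series
statistics per window (moments, quantiles, energy, run lengths, coarse
autocorrelation and spectral summaries) with dataset-level removal of
constant and duplicated columns. It exists as the exhaustive-catalogue
comparison arm; its exact dimensionality is not asserted anywhere.

The respiratory period of a subject is estimated as the lag of the highest
autocorrelation peak within 1.5–8 s on ≥ 10 s of signal; a peak below 0.3
returns an indeterminate result (as for white noise or a breath-hold).

## Classification and evaluation

Class weights follow the balanced scheme w_c = N/(k·n_c). Cross-validation
is leave-one-subject-out by default (grouped k-fold and plain stratified
k-fold are available) so windows from one subject never straddle a split;
model selection maximises macro-averaged F1. Default grids: C ∈ {0.1, 1, 10,
100} (RBF width at 0.1×/1×/10× the `1/(d·var)` heuristic); forests with
100/300 trees, depth ∈ {None, 5, 10}, √d or log₂d features per split. A
training run is rejected when any class lives in a single subject, since
every training fold would then lack it. Precision, recall and F1 are
computed from the confusion matrix with undefined ratios set to 0 (logged
convention, applied symmetrically); macro-F1 is their unweighted mean.

## Validation computations

The band reference is low-passed with a zero-phase Butterworth filter
(5 Hz cutoff, order 4, DC gain 1; the zero-phase pass squares the magnitude
response). Waveform agreement is the zero-lag Pearson correlation of
mean-removed 5 s breathing-only segments, up to three per trial; a
max-over-±lags variant is available to absorb a fixed sensor delay.
Pre/post-swallow respiratory phase is called from the least-squares slope
over 0.8 s (configurable) before the pause onset and after its offset:
positive → expiration, negative → inspiration, |slope| below threshold →
indeterminate. The default threshold is 10% of the subject's median
breathing-slope magnitude, so it scales with breathing depth.

## Problem sizes and determinism

Every stochastic component is seeded: subject draws, trial noise, rendering
noise and forest construction all derive from explicit integer seeds, and
fixed seeds give bit-identical outputs. The shipped tests run the full
chain at 19 subjects × 10 trials (the study's cohort size after exclusion)
for the end-to-end identification check, a 3-size window sweep on the same
cohort, and smaller cohorts (3–6 subjects) for distributional properties;
these sizes were chosen as the smallest that exercise the grouped
cross-validation realistically.

## Known limitations

* Swallow identification relies on a plateau interrupting breathing; very
  short pauses (≈ 0.3 s) inside a 4 s window produce weak signatures, and
  windows that merely *overlap* a pause near their edge are genuinely
  ambiguous under position-invariant features. Swallowing is accordingly
  the weakest class in every configuration, at clean-simulation performance
  levels well above what real, artifact-laden data can support.
* The labelling rule ties windows to midpoint activity; with window sizes
  whose midpoints fall exactly on shifted hold boundaries (3 s, 5 s at the
  default schedule), boundary windows are systematically harder, visible as
  dips in the window-size sweep.
* The simulator's noise is white; real recordings show structured artifacts
  (posture shifts, arm motion) that the displacement estimator does not
  compensate.
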