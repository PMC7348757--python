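# Methods

This note documents the generative model behind the synthetic sessions, the
feature and classifier definitions with the conventions they fix, the
validation protocols, and the choices made where more than one reasonable
design existed.

## Synthetic vigilance sessions

**Task structure.** A session is a sequence of runs. Each run holds 8
self-paced trials; each trial contributes one *attentive* interval — the
fixation-to-stimulus wait, drawn uniformly from [4, 8) s (6 s base ± up to
2 s jitter) — followed by a 1.5 s unlabelled gap standing in for the
stimulus and keypress (motion-contaminated data that the analysis never
uses). After the 8th trial the subject rests for 48 s (*rest* interval),
sized so attentive and rest data have similar total length. Defaults: 6 runs
per session, 250 Hz sampling, 2 channels. The jitter is drawn over the full
± range because the "6 ± α, α < 2" protocol description is ambiguous between
a signed and an unsigned perturbation; the bounds are configurable
(`SessionConfig.jitter_max_s`).

**Signal model.** Per channel, the signal is additive and stationary within
a state:

    s(t) = noise_amplitude · pink(t) + Σ_bands baseline_b · m_b(state(t)) · carrier_b(t)

where `pink` is 1/f^1 background noise (spectrally shaped white noise,
unit variance) and each `carrier_b` is unit-variance narrowband noise
(order-4 Butterworth-filtered white noise centred in the band). The two
channels share 60% of each component's variance through a common latent
series, mimicking the high interchannel correlation of closely spaced
in-ear electrodes. The default state multipliers encode the classical
attention correlates — alpha rises at rest (×1.8), theta (×1.3) and gamma
(×1.2) rise during attention; all other multipliers are 1. These magnitudes
are free parameters of the generator chosen to give a clear but not
saturating contrast; they are not measured quantities. Per-subject
variability multiplies each band baseline by exp(0.1·z), z ~ N(0,1), keyed
to the subject identifier.

**Reaction times.** Trials draw N(0.4 s, 0.05 s) truncated at zero; with
probability 0.03 a trial is replaced by a false start (uniform 10–90 ms) and
with probability 0.03 by a lapse (mean + 6–10 SD), so the downstream
exclusion rules (false start < 100 ms, lapse > mean + 3·SD, SD with n−1
normalization over all of the subject's trials before any exclusion) have
genuine targets.

**What the generator does not model.** Eye-blink/EMG artifacts, electrode
impedance drift, event-related potential morphology, non-stationarity within
a state, and realistic inter-epoch autocorrelation of band power. Passing
tests therefore demonstrate that the pipeline recovers a planted band-power
contrast under 1/f noise and intersubject variability — not that real in-ear
EEG reaches any particular accuracy. Synthetic accuracies (~92–98% depending
on scheme) are accordingly higher than what two-channel in-ear recordings
yield in practice.

## Features

Epochs are 0.5 s (125 samples) cut consecutively inside each labelled
interval; windows that would straddle a label change, and interval
remainders shorter than the window, are dropped so every epoch is a pure
single-state window. The whole recording is zero-phase (forward–backward)
bandpass filtered at 1–50 Hz (6th-order Butterworth) before epoching;
zero-phase filtering is the natural offline choice and avoids group delay
misaligning epochs against labels.

*Spectral (10):* one-segment STFT of the 125-sample window with a Hamming
taper and no zero padding → 2 Hz bin spacing; the square root of the PSD is
averaged over bins whose centre frequency lies in [low, high) per band
(summation is available as a switch; band membership and taper must be fixed
for reproducibility). A band that captures no bin at this resolution is
rejected at construction.

*Temporal (50):* per band, the window is zero-phase filtered with the band's
6th-order Butterworth bandpass, then mean amplitude, SD, peak-to-peak,
skewness, and Pearson kurtosis (normal → 3) are computed. "Mean amplitude"
is the mean of absolute values by default — the signed mean of a zero-mean
band-filtered signal is ≈ 0 and uninformative — with the signed variant
available. Constant filtered windows have undefined higher moments; those
entries are set to 0. The batch extraction path filters all epochs of a
recording in one call per band; tests assert it is numerically identical to
the per-epoch operations.

*Standardization:* per-feature mean/SD are computed on **training rows
only** and frozen (computing them on pooled data would leak test information
into every CV scheme); standardized features are linearly rescaled so the
training min/max map to −1/+1. Test rows may exceed [−1, 1]; no clipping, so
the transform stays invertible. Zero-variance features get SD 1 and are
flagged; they standardize to exactly 0.

## Echo state network

Reservoir: W entries are nonzero with probability c, uniform in
[−0.5, 0.5] (the distribution is immaterial up to scale because the matrix
is subsequently rescaled so its largest eigenvalue magnitude equals the
target spectral radius λ); W_in is uniform in [−σ, σ] with σ = 1 on the
[−1, 1]-scaled features (σ is exposed in `ReservoirConfig`; no value is
canonical). Degenerate draws with zero spectral radius (possible at tiny
N·c) are resampled with an incremented seed and a warning. State update is
the leaky-integrator recursion with tanh activation; no output feedback.

Readout: ridge regression on rows (u(t), x(t), 1) — the constant component
supplies an intercept, a choice the recursion itself does not dictate —
solved through the regularized normal equations with β = 10⁻⁸ (small enough
to approximate least squares, large enough to stabilize collinear designs).
Washout defaults to 0 and is configurable. y = 0 classifies as rest: the
conservative class for an attention monitor, and a measure-zero event.

**State handling across epochs.** Consecutive feature vectors within one
contiguous stream — a run's attention epochs, or one rest block — form one
input sequence; the reservoir state resets to zero at every stream boundary.
Carrying state across a run/rest boundary would let the reservoir smuggle
label context across the train/test cut at evaluation time.

Smoothing replaces each readout with the mean of itself and the n−1
previous outputs (n = 1..12, i.e. 0.5–6 s); before n outputs exist, every
available previous output is averaged. It runs strictly causally and within
one contiguous segment, never across a stream boundary.

## Validation protocols

*Within-subject:* leave-one-run-out over a subject's K runs; fold i tests on
run i's attention stream plus the rest block that followed that run (the
natural pairing; the alternative — pooling rest data across folds — would
let identical rest epochs appear on both sides of the cut).

*Cross-subject:* leave-one-subject-out; standardizer and hyperparameters
come from the training subjects only.

*k-fold (k = 10):* pooled epochs from all subjects are randomly partitioned
into k folds with sizes differing by at most one. The partition is over
epochs, so temporally adjacent epochs can straddle the train/test boundary —
a known optimism source inherent to this protocol which the package
documents rather than repairs. (A consequence: with one epoch per run and
folds forced to run boundaries, k-fold degenerates to leave-one-run-out;
the epoch-level partition has no forcing hook, so this degeneracy is noted
rather than tested.)

*Grid search:* each (α, λ) cell trains `repeats` independent reservoirs and
is scored by mean training accuracy; selection uses training-side accuracy
because the study design reports maximum training accuracy from the search,
implying no inner validation split — documented as optimistic, with two
switches: `statistic="sse"` (negated sum of squared readout errors) and
`selection="holdout"` (an inner ~1/5-of-segments validation split for
scoring, retraining the winner on all training data). Ties break toward the
smaller λ, then the smaller α — the more contractive, more stable reservoir.
Cell seeds are keyed by the parameter values, not the cell position, so the
same (α, λ) evaluates identically on any grid laid over it and coarse/fine
searches remain comparable. `within_subject_cv` reruns the search inside
every fold by default (`grid_scope="fold"`, stricter); `grid_scope="subject"`
selects once per subject, which is cheaper but lets the selection see every
run.

In every scheme the functions that fit anything — standardizer, grid search,
readout — receive training rows only; a canary test corrupts test-fold rows
and asserts the trained readout is bit-identical.

## Numerical choices and scale

- Leaky update, ridge solve, and smoothing each have exact independent
  oracles in the tests (step-by-step loop, `lstsq` on a full-rank design,
  brute-force windowed mean).
- The echo state property is checked empirically: for λ ≤ 0.95, state
  trajectories from different initial conditions converge below 1e-3 after
  500 steps; no convergence is asserted at λ = 1.8, where the contraction
  guarantee does not apply.
- Spectral-radius rescaling uses dense eigenvalues (reservoirs up to 1000
  units are small matrices); the rescaled radius is exact to ~1e-6.
- The demonstration scale (`demo_pipeline_config`): 6 subjects × 6 runs,
  N = 100, a 2 × 2 (α, λ) grid with 2 repeats per cell. Six runs is the
  cohort's minimum session length; the reduced grid keeps a full
  three-scheme study in minutes on one core while preserving genuine
  model selection. The full 200-combination grid with 10 repeats remains the
  `GridSearchSpec` default and is what a real analysis should use.

## Known limitations

- Synthetic stationarity within states makes the per-epoch features nearly
  sufficient, so reservoir hyperparameters (λ especially) are only weakly
  identified on generated data: many (α, λ) cells score equally and the
  selected λ is tie-break- and noise-dominated. Real EEG, with temporal
  structure the features miss, should discriminate these parameters more.
- EDF can be read (via mne) but not written: no EDF writer library is
  declared as a dependency, so the delimited-text container is canonical and
  the only format exercised round-trip in tests.
- No artifact rejection, re-referencing, online/recursive training, or
  output-feedback architectures; the seven conventional ML comparators of
  the original study design are out of scope.
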