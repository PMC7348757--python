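"""Synthetic two-channel EEG sessions with attentive/rest structure.

Emulates a self-paced visual vigilance protocol: each run holds 8 trials
whose pre-stimulus fixation interval (6 s plus uniform jitter of up to +/-2 s)
is labelled *attentive*; a 48 s *rest* block follows each run; the
stimulus/response period between trials is unlabelled. The signal model is
additive and stationary within a state: 1/f background noise plus one
narrowband component per canonical EEG band whose amplitude is the band
baseline times a state-dependent multiplier. Reaction times are truncated
normal draws contaminated by false starts (< 0.1 s) and lapses (far above the
mean), feeding the downstream trial-exclusion rules.

The default band-effect profile follows the classical attention correlates:
alpha power raised at rest (multiplier 1.8), theta and gamma mildly raised
during attention (1.3 / 1.2); the two channels share 60% of each component's
variance. These magnitudes are free parameters of the generator, not measured
quantities.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .features import BandDefinition, CANONICAL_BANDS

__all__ = [
    "ATTENTIVE",
    "REST",
    "UNLABELED",
    "SessionConfig",
    "BandEffectProfile",
    "SubjectProfile",
    "Interval",
    "TrialSchedule",
    "LabeledRecording",
    "default_band_profile",
    "make_subject",
    "make_subjects",
    "make_session_schedule",
    "synthesize_recording",
    "simulate_reaction_times",
    "simulate_session",
    "child_seed",
]

ATTENTIVE = "attentive"
REST = "rest"
UNLABELED = "none"

#: Integer codes used for the per-sample label array.
LABEL_CODES = {ATTENTIVE: 1, REST: -1, UNLABELED: 0}


def child_seed(seed: int, *key: int) -> int:
    """Deterministically derive an independent sub-stream seed (< 2**31)."""
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SessionConfig:
    """Timing and sampling parameters of one recording session.

    ``pre_stimulus_base_s`` +/- ``jitter_max_s`` bounds the attentive
    (fixation-to-stimulus) interval; ``gap_s`` is the unlabelled
    stimulus/response period inserted after each trial.
    """

    n_runs: int = 6
    trials_per_run: int = 8
    pre_stimulus_base_s: float = 6.0
    jitter_max_s: float = 2.0
    rest_duration_s: float = 48.0
    gap_s: float = 1.5
    sampling_rate_hz: float = 250.0
    n_channels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 0 or self.trials_per_run <= 0:
            raise ValueError("n_runs must be >= 0 and trials_per_run positive")
        if min(self.pre_stimulus_base_s, self.rest_duration_s) <= 0 or self.gap_s < 0:
            raise ValueError("durations must be positive")
        if self.jitter_max_s < 0 or self.jitter_max_s >= self.pre_stimulus_base_s:
            raise ValueError("jitter must be >= 0 and below the base interval")
        if self.sampling_rate_hz <= 0 or self.n_channels < 1:
            raise ValueError("invalid sampling rate or channel count")

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run


@dataclass(frozen=True)
class BandEffectProfile:
    """Generative band structure: baseline amplitudes (uV RMS) and per-state
    multipliers, over a 1/f^exponent background."""

    baseline_uv: dict[str, float] = field(
        default_factory=lambda: {b.name: 1.0 for b in CANONICAL_BANDS}
    )
    attentive_mult: dict[str, float] = field(
        default_factory=lambda: {b.name: 1.0 for b in CANONICAL_BANDS}
    )
    rest_mult: dict[str, float] = field(
        default_factory=lambda: {b.name: 1.0 for b in CANONICAL_BANDS}
    )
    noise_amplitude_uv: float = 1.0
    noise_exponent: float = 1.0
    channel_correlation: float = 0.6

    def __post_init__(self) -> None:
        vals = (
            list(self.baseline_uv.values())
            + list(self.attentive_mult.values())
            + list(self.rest_mult.values())
        )
        if any(v < 0 for v in vals) or self.noise_amplitude_uv < 0:
            raise ValueError("amplitudes and multipliers must be >= 0")
        if not 0.0 <= self.channel_correlation <= 1.0:
            raise ValueError("channel correlation must be in [0, 1]")

    def multiplier(self, band: str, state: str) -> float:
        if state == ATTENTIVE:
            return self.attentive_mult[band]
        if state == REST:
            return self.rest_mult[band]
        return 1.0


def default_band_profile() -> BandEffectProfile:
    """The default attention contrast: rest alpha 1.8x, attentive theta 1.3x
    and gamma 1.2x."""
    return BandEffectProfile(
        attentive_mult={"delta": 1.0, "theta": 1.3, "alpha": 1.0, "beta": 1.0, "gamma": 1.2},
        rest_mult={"delta": 1.0, "theta": 1.0, "alpha": 1.8, "beta": 1.0, "gamma": 1.0},
    )


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters, including reaction-time behaviour."""

    subject_id: str
    band_profile: BandEffectProfile = field(default_factory=default_band_profile)
    subject_offset_scale: float = 0.0
    rt_mean_s: float = 0.4
    rt_sd_s: float = 0.05
    false_start_prob: float = 0.03
    lapse_prob: float = 0.03

    def __post_init__(self) -> None:
        if not (0 <= self.false_start_prob <= 1 and 0 <= self.lapse_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.rt_sd_s < 0 or self.rt_mean_s <= 0:
            raise ValueError("rt_mean_s must be positive and rt_sd_s >= 0")


def make_subject(
    subject_id: str,
    seed: int,
    base_profile: Optional[BandEffectProfile] = None,
    offset_scale: float = 0.1,
    **rt_kwargs,
) -> SubjectProfile:
    """A subject whose band baselines are log-normally perturbed around a
    shared profile (intersubject variability)."""
    base = base_profile or default_band_profile()
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(subject_id.encode()),))
    )
    baseline = {
        name: amp * float(np.exp(offset_scale * rng.standard_normal()))
        for name, amp in base.baseline_uv.items()
    }
    profile = replace(base, baseline_uv=baseline)
    return SubjectProfile(
        subject_id=subject_id,
        band_profile=profile,
        subject_offset_scale=offset_scale,
        **rt_kwargs,
    )


def make_subjects(n: int, seed: int, **kwargs) -> list[SubjectProfile]:
    return [make_subject(f"S{i + 1:02d}", seed, **kwargs) for i in range(n)]


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """One contiguous single-state span of the session timeline."""

    state: str
    start: float
    end: float
    run: int
    trial: Optional[int] = None

    @property
    def duration(self) -> float:
        return self.end - self.start

    # Sample coordinates are attached when a recording is synthesized.
    start_sample: int = 0
    end_sample: int = 0


@dataclass
class TrialSchedule:
    """Ordered, contiguous intervals covering a whole session."""

    intervals: list[Interval]

    @property
    def total_duration(self) -> float:
        return self.intervals[-1].end if self.intervals else 0.0

    def by_state(self, state: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.state == state]


def make_session_schedule(config: SessionConfig) -> TrialSchedule:
    """Lay out runs of jittered attentive trials, unlabelled gaps and rests.

    Attentive durations are drawn uniformly in
    ``[base - jitter_max, base + jitter_max)``; the draw order is fixed
    (runs, then trials) so the schedule is a pure function of the seed.
    """
    rng = np.random.default_rng(child_seed(config.seed, 0))
    intervals: list[Interval] = []
    t = 0.0
    trial_id = 0
    for run in range(config.n_runs):
        for _ in range(config.trials_per_run):
            dur = config.pre_stimulus_base_s + rng.uniform(
                -config.jitter_max_s, config.jitter_max_s
            )
            intervals.append(Interval(ATTENTIVE, t, t + dur, run, trial_id))
            t += dur
            trial_id += 1
            if config.gap_s > 0:
                intervals.append(Interval(UNLABELED, t, t + config.gap_s, run))
                t += config.gap_s
        intervals.append(Interval(REST, t, t + config.rest_duration_s, run))
        t += config.rest_duration_s
    return TrialSchedule(intervals)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

@dataclass
class LabeledRecording:
    """Multichannel EEG with per-sample state labels and trial reaction times.

    ``labels`` holds integer codes (+1 attentive, -1 rest, 0 unlabelled);
    ``intervals`` carries the schedule in sample coordinates so epochs can be
    traced back to their run and trial.
    """

    signal: np.ndarray
    sampling_rate_hz: float
    labels: np.ndarray
    intervals: list[Interval]
    reaction_times: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.labels.shape[0] != self.signal.shape[1]:
            raise ValueError("label array length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _narrowband(
    n: int, band: BandDefinition, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance narrowband noise centred in the band (order-4 Butterworth
    filtered white noise)."""
    sos = sps.butter(4, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def synthesize_recording(
    schedule: TrialSchedule,
    subject: SubjectProfile,
    config: SessionConfig,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
) -> LabeledRecording:
    """Render a schedule into a labelled two-channel signal.

    Per channel: 1/f background plus one narrowband component per band whose
    per-sample amplitude is ``baseline x state multiplier``. Channel pairs
    share ``channel_correlation`` of each component's variance through a
    common latent series.
    """
    if not schedule.intervals:
        raise ValueError("schedule is empty")
    fs = config.sampling_rate_hz
    gamma_edge = max(b.high_hz for b in bands)
    if fs < 2 * gamma_edge:
        raise ValueError(
            f"sampling rate {fs} Hz aliases the {gamma_edge} Hz band edge "
            f"(need >= {2 * gamma_edge} Hz)"
        )
    n = int(round(schedule.total_duration * fs))
    prof = subject.band_profile
    rng = np.random.default_rng(
        np.random.SeedSequence(
            config.seed, spawn_key=(1, zlib.crc32(subject.subject_id.encode()))
        )
    )

    # Sample-coordinate intervals and per-sample labels/state multiplier map.
    intervals: list[Interval] = []
    labels = np.zeros(n, dtype=np.int8)
    for iv in schedule.intervals:
        s0, s1 = int(round(iv.start * fs)), int(round(iv.end * fs))
        s1 = min(s1, n)
        intervals.append(replace(iv, start_sample=s0, end_sample=s1))
        labels[s0:s1] = LABEL_CODES[iv.state]

    rho = prof.channel_correlation
    w_shared, w_own = np.sqrt(rho), np.sqrt(1.0 - rho)
    signal = np.empty((config.n_channels, n))
    shared_noise = _pink_noise(n, prof.noise_exponent, rng)
    shared_bands = {b.name: _narrowband(n, b, fs, rng) for b in bands}

    for ch in range(config.n_channels):
        x = prof.noise_amplitude_uv * (
            w_shared * shared_noise + w_own * _pink_noise(n, prof.noise_exponent, rng)
        )
        for b in bands:
            carrier = w_shared * shared_bands[b.name] + w_own * _narrowband(n, b, fs, rng)
            env = np.full(n, prof.baseline_uv[b.name])
            for iv in intervals:
                env[iv.start_sample : iv.end_sample] = prof.baseline_uv[
                    b.name
                ] * prof.multiplier(b.name, iv.state)
            x = x + env * carrier
        signal[ch] = x

    rts = simulate_reaction_times(
        config.n_trials, subject, child_seed(config.seed, 2, zlib.crc32(subject.subject_id.encode()))
    )
    return LabeledRecording(
        signal=signal,
        sampling_rate_hz=fs,
        labels=labels,
        intervals=intervals,
        reaction_times=np.asarray(rts),
        subject_id=subject.subject_id,
    )


def simulate_reaction_times(
    n_trials: int, subject: SubjectProfile, seed: int
) -> np.ndarray:
    """Truncated-normal reaction times with false-start and lapse contamination.

    Normal trials draw N(rt_mean, rt_sd) truncated at 0; with
    ``false_start_prob`` a trial is replaced by a premature press (uniform in
    [0.01, 0.09] s, below the 100 ms rule) and with ``lapse_prob`` by a long
    lapse (mean + 6..10 SD), so the downstream exclusion rules have genuine
    targets.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    rng = np.random.default_rng(seed)
    rts = rng.normal(subject.rt_mean_s, subject.rt_sd_s, size=n_trials)
    rts = np.maximum(rts, 0.0)
    kind = rng.uniform(size=n_trials)
    fs_mask = kind < subject.false_start_prob
    lapse_mask = (kind >= subject.false_start_prob) & (
        kind < subject.false_start_prob + subject.lapse_prob
    )
    rts[fs_mask] = rng.uniform(0.01, 0.09, size=fs_mask.sum())
    rts[lapse_mask] = subject.rt_mean_s + subject.rt_sd_s * rng.uniform(
        6.0, 10.0, size=lapse_mask.sum()
    )
    return rts


def simulate_session(
    config: SessionConfig, subject: SubjectProfile
) -> LabeledRecording:
    """Schedule + signal + reaction times for one subject session."""
    schedule = make_session_schedule(config)
    return synthesize_recording(schedule, subject, config)
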