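"""Band-wise spectral/temporal feature extraction for two-channel EEG epochs.

The pipeline works on 0.5 s epochs (125 samples at 250 Hz). For each epoch it
computes one spectral feature per channel and canonical band (square root of
the single-window STFT power spectral density, averaged over in-band bins) and
five temporal statistics per channel and band (mean absolute amplitude,
standard deviation, peak-to-peak, skewness, kurtosis of the band-filtered
window): 10 spectral + 50 temporal = 60 features for two channels.

Feature ordering convention (fixed, reflected by :func:`feature_names`):
spectral block first — channels in recording order (left, right), bands in
canonical order delta..gamma — then the temporal block, channels × bands ×
statistics (mean_amp, std, ptp, skew, kurt).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import LabeledRecording

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "Epoch",
    "FeatureMatrix",
    "StandardizationParams",
    "feature_names",
    "segment_epochs",
    "broadband_filter",
    "bandpass_sos",
    "spectral_features",
    "temporal_features",
    "extract_features",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
]

TEMPORAL_STATISTICS = ("mean_amp", "std", "ptp", "skew", "kurt")
CHANNEL_NAMES = ("left", "right")

# Small std below which a filtered window is treated as constant and its
# third/fourth moments are undefined (returned as 0).
_CONSTANT_TOL = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG frequency band ``[low_hz, high_hz)``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low must be < high")


#: The five canonical EEG bands used throughout the pipeline.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)


@dataclass
class Epoch:
    """One fixed-length window of a labelled interval.

    ``samples`` is channels x n_samples; ``label`` is +1 (attentive) or -1
    (rest); ``run``/``trial`` identify the source interval (trial is -1 for
    rest blocks); ``start_sample`` is the offset into the recording.
    """

    samples: np.ndarray
    label: int
    run: int
    trial: int
    start_sample: int


def feature_names(
    channels: Sequence[str] = CHANNEL_NAMES,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
) -> list[str]:
    """Column names in the fixed extraction order (``channel_band_statistic``)."""
    names = [f"{ch}_{b.name}_power" for ch in channels for b in bands]
    names += [
        f"{ch}_{b.name}_{stat}"
        for ch in channels
        for b in bands
        for stat in TEMPORAL_STATISTICS
    ]
    return names


# ---------------------------------------------------------------------------
# Segmentation and filtering
# ---------------------------------------------------------------------------

def segment_epochs(recording: "LabeledRecording", epoch_s: float = 0.5) -> list[Epoch]:
    """Cut each labelled interval into consecutive non-overlapping epochs.

    Windows that would span a label change, and interval remainders shorter
    than ``epoch_s``, are dropped: every epoch is a full single-state window.
    """
    fs = recording.sampling_rate_hz
    n_win = epoch_s * fs
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError(
            f"epoch length {epoch_s} s x {fs} Hz is not an integer sample count"
        )
    n_win = int(round(n_win))
    epochs: list[Epoch] = []
    for iv in recording.intervals:
        if iv.state not in ("attentive", "rest"):
            continue
        label = 1 if iv.state == "attentive" else -1
        n_ep = (iv.end_sample - iv.start_sample) // n_win
        for k in range(n_ep):
            s0 = iv.start_sample + k * n_win
            epochs.append(
                Epoch(
                    samples=recording.signal[:, s0 : s0 + n_win],
                    label=label,
                    run=iv.run,
                    trial=-1 if iv.trial is None else iv.trial,
                    start_sample=s0,
                )
            )
    return epochs


@lru_cache(maxsize=64)
def bandpass_sos(low: float, high: float, fs: float, order: int = 6) -> np.ndarray:
    """Second-order sections of a Butterworth bandpass with edges in (0, fs/2).

    Cached: the same design is reused for every epoch of a recording.
    """
    nyq = fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band edges ({low}, {high}) Hz must satisfy 0 < low < high < {nyq}"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def broadband_filter(
    x: np.ndarray, low: float = 1.0, high: float = 50.0, order: int = 6, fs: float = 250.0
) -> np.ndarray:
    """Zero-phase (forward-backward) 6th-order Butterworth bandpass."""
    sos = bandpass_sos(low, high, fs, order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


# ---------------------------------------------------------------------------
# Per-epoch features
# ---------------------------------------------------------------------------

def _band_bin_masks(
    bands: Sequence[BandDefinition], n_samples: int, fs: float
) -> list[np.ndarray]:
    """Boolean masks of STFT bins whose centre lies in [low, high) per band.

    With a single 0.5 s window the bin spacing is fs / n_samples (2 Hz at
    250 Hz); a band that captures no bin at this resolution is rejected
    outright rather than silently producing NaNs.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    masks = []
    for b in bands:
        m = (freqs >= b.low_hz) & (freqs < b.high_hz)
        if not m.any():
            raise ValueError(
                f"band {b.name} [{b.low_hz}, {b.high_hz}) Hz has no spectral bin "
                f"at {fs / n_samples:g} Hz resolution"
            )
        masks.append(m)
    return masks


def spectral_features(
    epoch: Epoch,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    fs: float = 250.0,
    reduce: str = "mean",
) -> np.ndarray:
    """Root-spectral-power per channel and band (single Hamming-tapered window).

    The power spectral density of the whole 0.5 s window is estimated with a
    one-segment STFT (periodogram, Hamming taper, no zero padding); the square
    root of the PSD is then averaged (or summed, ``reduce='sum'``) over the
    bins inside each band.
    """
    x = np.asarray(epoch.samples, dtype=float)
    masks = _band_bin_masks(bands, x.shape[-1], fs)
    _, psd = sps.periodogram(x, fs=fs, window="hamming", axis=-1)
    amp = np.sqrt(psd)
    op = np.mean if reduce == "mean" else np.sum
    return np.array([op(amp[ch, m]) for ch in range(x.shape[0]) for m in masks])


def temporal_features(
    epoch: Epoch,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    fs: float = 250.0,
    order: int = 6,
    amplitude: str = "absolute",
) -> np.ndarray:
    """Five time-domain statistics per channel and band-filtered window.

    Each channel is zero-phase bandpass filtered per band, then mean amplitude
    (mean of absolute values by default; ``amplitude='signed'`` for the raw
    mean), standard deviation, peak-to-peak, skewness and kurtosis (Pearson:
    a normal signal scores 3) are computed. Constant filtered windows have
    undefined higher moments; those entries are returned as 0.
    """
    x = np.asarray(epoch.samples, dtype=float)
    out = np.empty(x.shape[0] * len(bands) * len(TEMPORAL_STATISTICS))
    i = 0
    for ch in range(x.shape[0]):
        for b in bands:
            sos = bandpass_sos(b.low_hz, b.high_hz, fs, order)
            y = sps.sosfiltfilt(sos, x[ch])
            sd = float(np.std(y))
            if sd < _CONSTANT_TOL:
                skew = kurt = 0.0
            else:
                skew = float(spstats.skew(y))
                kurt = float(spstats.kurtosis(y, fisher=False))
            mean_amp = float(np.mean(np.abs(y)) if amplitude == "absolute" else np.mean(y))
            out[i : i + 5] = (mean_amp, sd, float(np.ptp(y)), skew, kurt)
            i += 5
    return out


def _batch_feature_rows(
    epochs: list[Epoch],
    bands: Sequence[BandDefinition],
    fs: float,
    order: int = 6,
    amplitude: str = "absolute",
    spectral_reduce: str = "mean",
) -> np.ndarray:
    """Vectorized equivalent of per-epoch spectral + temporal extraction.

    Stacks all epochs and filters each band once over the stack; the
    arithmetic is identical to :func:`spectral_features` /
    :func:`temporal_features` applied row by row (asserted in tests).
    """
    if not epochs:
        n_feat = 0 if not epochs else None
        return np.empty((0, n_feat or 0))
    stack = np.stack([ep.samples for ep in epochs])  # (n_ep, ch, n)
    n_ep, n_ch, n = stack.shape
    masks = _band_bin_masks(bands, n, fs)
    _, psd = sps.periodogram(stack, fs=fs, window="hamming", axis=-1)
    amp = np.sqrt(psd)
    op = np.mean if spectral_reduce == "mean" else np.sum
    spectral = np.stack(
        [op(amp[..., m], axis=-1) for m in masks], axis=-1
    ).reshape(n_ep, n_ch * len(bands))

    temporal_blocks = []
    flat = stack.reshape(n_ep * n_ch, n)
    for b in bands:
        sos = bandpass_sos(b.low_hz, b.high_hz, fs, order)
        y = sps.sosfiltfilt(sos, flat, axis=-1)
        mean = y.mean(axis=-1, keepdims=True)
        d = y - mean
        m2 = np.mean(d**2, axis=-1)
        m3 = np.mean(d**3, axis=-1)
        m4 = np.mean(d**4, axis=-1)
        ok = np.sqrt(m2) >= _CONSTANT_TOL
        skew = np.where(ok, m3 / np.where(ok, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(ok, m4 / np.where(ok, m2, 1.0) ** 2, 0.0)
        mean_amp = (
            np.abs(y).mean(axis=-1) if amplitude == "absolute" else y.mean(axis=-1)
        )
        stats = np.stack(
            [mean_amp, np.sqrt(m2), y.max(axis=-1) - y.min(axis=-1), skew, kurt],
            axis=-1,
        )
        temporal_blocks.append(stats.reshape(n_ep, n_ch, 5))
    # (n_ep, ch, band, stat) -> flattened in channel-major, band, stat order
    temporal = np.stack(temporal_blocks, axis=2).reshape(n_ep, -1)
    return np.hstack([spectral, temporal])


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Per-epoch feature rows with labels and grouping keys.

    ``X`` is epochs x features; ``y`` holds +1 (attentive) / -1 (rest);
    ``subject``/``run``/``trial`` identify provenance (trial -1 for rest
    epochs); ``segment`` names the contiguous stream an epoch belongs to
    (one attention stream or one rest block per run) — reservoir state is
    reset at segment boundaries; ``start_sample`` orders epochs within a
    segment.
    """

    X: np.ndarray
    y: np.ndarray
    subject: np.ndarray
    run: np.ndarray
    trial: np.ndarray
    segment: np.ndarray
    start_sample: np.ndarray
    names: list[str] = field(default_factory=feature_names)

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for arr_name in ("y", "subject", "run", "trial", "segment", "start_sample"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length does not match X rows")
        if not np.isin(self.y, (-1, 1)).all():
            raise ValueError("labels must be +1 or -1")

    @property
    def n_epochs(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        """Row subset, preserving order."""
        return FeatureMatrix(
            X=self.X[mask],
            y=self.y[mask],
            subject=self.subject[mask],
            run=self.run[mask],
            trial=self.trial[mask],
            segment=self.segment[mask],
            start_sample=self.start_sample[mask],
            names=list(self.names),
        )

    def with_X(self, X: np.ndarray) -> "FeatureMatrix":
        fm = self.select(np.ones(self.n_epochs, dtype=bool))
        fm.X = X
        return fm

    @staticmethod
    def concat(parts: Iterable["FeatureMatrix"]) -> "FeatureMatrix":
        parts = list(parts)
        return FeatureMatrix(
            X=np.concatenate([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            subject=np.concatenate([p.subject for p in parts]),
            run=np.concatenate([p.run for p in parts]),
            trial=np.concatenate([p.trial for p in parts]),
            segment=np.concatenate([p.segment for p in parts]),
            start_sample=np.concatenate([p.start_sample for p in parts]),
            names=list(parts[0].names),
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "subject": self.subject,
                "run": self.run,
                "trial": self.trial,
                "segment": self.segment,
                "start_sample": self.start_sample,
                "label": self.y,
            }
        )
        return pd.concat([meta, pd.DataFrame(self.X, columns=self.names)], axis=1)

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "FeatureMatrix":
        meta_cols = ["subject", "run", "trial", "segment", "start_sample", "label"]
        names = [c for c in df.columns if c not in meta_cols]
        return FeatureMatrix(
            X=df[names].to_numpy(dtype=float),
            y=df["label"].to_numpy(dtype=int),
            subject=df["subject"].to_numpy(dtype=str),
            run=df["run"].to_numpy(dtype=int),
            trial=df["trial"].to_numpy(dtype=int),
            segment=df["segment"].to_numpy(dtype=str),
            start_sample=df["start_sample"].to_numpy(dtype=int),
            names=names,
        )


def extract_features(
    recording: "LabeledRecording",
    epoch_s: float = 0.5,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    broadband: tuple[float, float] = (1.0, 50.0),
    order: int = 6,
    amplitude: str = "absolute",
    spectral_reduce: str = "mean",
) -> FeatureMatrix:
    """Full extraction: broadband filter, segment, 60 features per epoch."""
    fs = recording.sampling_rate_hz
    filtered = broadband_filter(recording.signal, *broadband, order=order, fs=fs)
    rec = replace_signal(recording, filtered)
    epochs = segment_epochs(rec, epoch_s)
    X = _batch_feature_rows(
        epochs, bands, fs, order=order, amplitude=amplitude,
        spectral_reduce=spectral_reduce,
    )
    subj = recording.subject_id
    seg_kind = np.array(["att" if ep.label == 1 else "rest" for ep in epochs])
    return FeatureMatrix(
        X=X,
        y=np.array([ep.label for ep in epochs], dtype=int),
        subject=np.array([subj] * len(epochs)),
        run=np.array([ep.run for ep in epochs], dtype=int),
        trial=np.array([ep.trial for ep in epochs], dtype=int),
        segment=np.array(
            [f"{subj}:r{ep.run}:{k}" for ep, k in zip(epochs, seg_kind)]
        ),
        start_sample=np.array([ep.start_sample for ep in epochs], dtype=int),
        names=feature_names(CHANNEL_NAMES[: recording.signal.shape[0]], bands),
    )


def replace_signal(recording: "LabeledRecording", signal: np.ndarray):
    from .synthetic import LabeledRecording

    return LabeledRecording(
        signal=signal,
        sampling_rate_hz=recording.sampling_rate_hz,
        labels=recording.labels,
        intervals=recording.intervals,
        reaction_times=recording.reaction_times,
        subject_id=recording.subject_id,
    )


# ---------------------------------------------------------------------------
# Standardization (training statistics only) and rescale to [-1, 1]
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    """Frozen training statistics for z-scoring plus the [-1, 1] rescale.

    ``mean``/``std`` are per-feature training moments; ``zmin``/``zmax`` are
    the post-standardization training extrema mapped linearly to -1/+1.
    Features with zero training variance are flagged and given std 1 (their
    standardized value is identically 0).
    """

    mean: np.ndarray
    std: np.ndarray
    zmin: np.ndarray
    zmax: np.ndarray
    zero_variance: np.ndarray

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]


def fit_standardizer(X: np.ndarray | FeatureMatrix) -> StandardizationParams:
    """Per-feature mean/std and standardized min/max from training rows only."""
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training epochs to standardize")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    zero_var = std == 0.0
    std = np.where(zero_var, 1.0, std)
    z = (X - mean) / std
    return StandardizationParams(
        mean=mean, std=std, zmin=z.min(axis=0), zmax=z.max(axis=0), zero_variance=zero_var
    )


def apply_standardizer(
    X: np.ndarray | FeatureMatrix, params: StandardizationParams
):
    """Standardize then rescale so training extrema map to -1/+1.

    Test rows may land outside [-1, 1]; no clipping is applied, preserving
    the invertibility of the transform.
    """
    fm = X if isinstance(X, FeatureMatrix) else None
    arr = X.X if fm is not None else np.asarray(X, dtype=float)
    if arr.shape[1] != params.n_features:
        raise ValueError(
            f"feature dimension {arr.shape[1]} does not match fitted {params.n_features}"
        )
    z = (arr - params.mean) / params.std
    span = params.zmax - params.zmin
    safe = np.where(span == 0.0, 1.0, span)
    scaled = 2.0 * (z - params.zmin) / safe - 1.0
    scaled[:, span == 0.0] = 0.0
    return fm.with_X(scaled) if fm is not None else scaled


def invert_standardizer(scaled: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Algebraic inverse of :func:`apply_standardizer` (zero-variance features
    recover the training mean)."""
    span = params.zmax - params.zmin
    safe = np.where(span == 0.0, 1.0, span)
    z = (scaled + 1.0) * safe / 2.0 + params.zmin
    raw = z * params.std + params.mean
    raw[:, span == 0.0] = params.mean[span == 0.0]
    return raw
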