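"""Cross-validation protocols, trial exclusion, grid search and sweeps.

Three validation schemes are provided: *within-subject* (leave-one-run-out:
fold i tests on run i's attention stream and its paired rest block),
*cross-subject* (leave-one-subject-out) and *k-fold* (pooled epochs randomly
partitioned). In every scheme the standardizer, hyperparameter search and
readout training see training rows only.

Attention trials whose reaction time marks a false start (< 100 ms) or a
lapse (> mean(RT) + 3 SD(RT), statistics over all of the subject's trials)
are excluded from both training and test pools; rest epochs are never
excluded.

Hyperparameters (leaking rate alpha, spectral radius lambda) are chosen by
grid search: each (alpha, lambda) cell trains `repeats` independent
reservoirs and is scored by mean training accuracy (sum of squared readout
errors available as an alternative statistic); ties break toward the smaller
spectral radius, then the smaller leaking rate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .esn import (
    ESNModel,
    ReservoirConfig,
    TrainingConfig,
    classify,
    fit_segments,
    init_reservoir,
    predict,
    smooth,
)
from .features import FeatureMatrix, apply_standardizer, fit_standardizer
from .synthetic import child_seed

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionRule",
    "GridSearchSpec",
    "SweepSpec",
    "FoldResult",
    "CVResult",
    "exclude_trials",
    "apply_exclusions",
    "accuracy",
    "segments_of",
    "grid_search",
    "reservoir_sweep",
    "within_subject_cv",
    "cross_subject_cv",
    "kfold_cv",
    "smoothing_curve",
]


# ---------------------------------------------------------------------------
# Trial exclusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionRule:
    """False-start / lapse thresholds on reaction times."""

    false_start_threshold_s: float = 0.1
    lapse_sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.false_start_threshold_s <= 0 or self.lapse_sd_multiplier <= 0:
            raise ValueError("thresholds must be positive")


def exclude_trials(
    rts: Sequence[float], rule: ExclusionRule = ExclusionRule()
) -> np.ndarray:
    """Keep mask over trials: False where the RT is a false start or a lapse.

    The lapse statistics (mean, SD with n-1 normalization) are computed over
    all of the subject's trials before any exclusion.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 1:
        raise ValueError("need at least one trial")
    sd = rts.std(ddof=1) if rts.size > 1 else 0.0
    lapse_cut = rts.mean() + rule.lapse_sd_multiplier * sd
    keep = (rts >= rule.false_start_threshold_s) & (rts <= lapse_cut)
    if not keep.any():
        raise ValueError(
            f"all {rts.size} trials excluded (mean RT {rts.mean():.3f}s); "
            "check the reaction-time stream"
        )
    return keep


def apply_exclusions(
    fm: FeatureMatrix,
    rts_by_subject: dict[str, np.ndarray],
    rule: ExclusionRule = ExclusionRule(),
) -> tuple[FeatureMatrix, dict[str, np.ndarray]]:
    """Drop attentive epochs of excluded trials; rest epochs always survive."""
    keep = np.ones(fm.n_epochs, dtype=bool)
    masks = {}
    for subj, rts in rts_by_subject.items():
        trial_keep = exclude_trials(rts, rule)
        masks[subj] = trial_keep
        rows = (fm.subject == subj) & (fm.trial >= 0)
        keep[rows] &= trial_keep[fm.trial[rows]]
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("excluded %d attentive epochs by RT rules", n_drop)
    return fm.select(keep), masks


# ---------------------------------------------------------------------------
# Scoring helpers
# ---------------------------------------------------------------------------

def accuracy(predicted: Sequence[int], true: Sequence[int]) -> float:
    """Fraction of agreeing +/-1 labels."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.size == 0 or predicted.shape != true.shape:
        raise ValueError("label vectors must be non-empty and equally long")
    return float(np.mean(predicted == true))


def segments_of(fm: FeatureMatrix) -> list[tuple[str, np.ndarray]]:
    """Row-index groups per contiguous segment, time-ordered within each.

    Segment order follows first appearance, so concatenating the groups
    reconstructs the session order of the rows.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, seg in enumerate(fm.segment):
        if seg not in groups:
            groups[seg] = []
            order.append(seg)
        groups[seg].append(i)
    out = []
    for seg in order:
        idx = np.asarray(groups[seg])
        out.append((seg, idx[np.argsort(fm.start_sample[idx], kind="stable")]))
    return out


def _train_segments(fm: FeatureMatrix) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(fm.X[idx], fm.y[idx]) for _, idx in segments_of(fm)]


def _score_model(
    model: ESNModel, fm: FeatureMatrix
) -> tuple[float, list[np.ndarray], list[np.ndarray], list[str]]:
    """Accuracy plus per-segment raw traces and aligned true labels."""
    traces, truths, seg_ids = [], [], []
    for seg, idx in segments_of(fm):
        trace = predict(model, fm.X[idx], x0=np.zeros(model.config.n_units))
        traces.append(trace)
        truths.append(fm.y[idx])
        seg_ids.append(seg)
    pred = np.concatenate([classify(t) for t in traces])
    true = np.concatenate(truths)
    return accuracy(pred, true), traces, truths, seg_ids


# ---------------------------------------------------------------------------
# Grid search and sweeps
# ---------------------------------------------------------------------------

def _default_alphas() -> np.ndarray:
    return np.round(np.arange(1, 11) * 0.1, 10)


def _default_lambdas() -> np.ndarray:
    return np.round(np.arange(1, 21) * 0.1, 10)


@dataclass(frozen=True)
class GridSearchSpec:
    """The (alpha, lambda) grid: steps of 0.1 over (0, 1] x (0, 2] by default
    (200 combinations), each cell averaged over ``repeats`` reservoirs.

    ``selection`` controls what each cell is scored on: ``"train"`` scores
    on the training rows themselves (optimistic but matching the reported
    use of maximum training accuracy); ``"holdout"`` holds out roughly one
    fifth of the training segments as an inner validation set for the
    search, then retrains the winner on the full training data.
    """

    alphas: tuple[float, ...] = field(default_factory=lambda: tuple(_default_alphas()))
    lambdas: tuple[float, ...] = field(default_factory=lambda: tuple(_default_lambdas()))
    repeats: int = 10
    statistic: str = "accuracy"  # or "sse"
    selection: str = "train"  # or "holdout"

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.statistic not in ("accuracy", "sse"):
            raise ValueError("statistic must be 'accuracy' or 'sse'")
        if self.selection not in ("train", "holdout"):
            raise ValueError("selection must be 'train' or 'holdout'")
        if not self.alphas or not self.lambdas:
            raise ValueError("empty grid")

    def combinations(self) -> list[tuple[float, float]]:
        return list(itertools.product(self.alphas, self.lambdas))


@dataclass(frozen=True)
class SweepSpec:
    """Reservoir-size / connectivity sweep cells."""

    n_units: tuple[int, ...]
    connectivities: tuple[float, ...]
    repeats: int = 10

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_units):
            raise ValueError("all reservoir sizes must be >= 1")
        if any(not 0 < c <= 1 for c in self.connectivities):
            raise ValueError("connectivities must be in (0, 1]")
        if len(set(self.n_units)) != len(self.n_units) or len(
            set(self.connectivities)
        ) != len(self.connectivities):
            raise ValueError("duplicate sweep values")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def combinations(self) -> list[tuple[int, float]]:
        return list(itertools.product(self.n_units, self.connectivities))

    @staticmethod
    def small_reservoirs() -> "SweepSpec":
        """10 sizes (10..100) x 11 connectivities (0.01, 0.1..1.0) = 110 cells."""
        return SweepSpec(
            n_units=tuple(range(10, 101, 10)),
            connectivities=(0.01,) + tuple(np.round(np.arange(1, 11) * 0.1, 10)),
        )

    @staticmethod
    def large_reservoirs() -> "SweepSpec":
        """10 sizes (100..1000) x sparse connectivities (0.01, 0.1) = 20 cells."""
        return SweepSpec(n_units=tuple(range(100, 1001, 100)), connectivities=(0.01, 0.1))


def _fit_and_score_training(
    fm: FeatureMatrix,
    cfg: ReservoirConfig,
    tc: TrainingConfig,
    statistic: str,
    eval_fm: Optional[FeatureMatrix] = None,
) -> float:
    """Train one reservoir on the training rows and score it (on itself, or
    on ``eval_fm`` when an inner validation set is supplied)."""
    model = init_reservoir(cfg, fm.n_features)
    fit_segments(model, _train_segments(fm), tc)
    score_fm = fm if eval_fm is None else eval_fm
    if statistic == "sse":
        sse = 0.0
        for _, idx in segments_of(score_fm):
            trace = predict(model, score_fm.X[idx], x0=np.zeros(cfg.n_units))
            sse += float(np.sum((trace - score_fm.y[idx]) ** 2))
        return -sse  # higher is better, uniformly with accuracy
    acc, _, _, _ = _score_model(model, score_fm)
    return acc


def _holdout_split(
    fm: FeatureMatrix, seed: int
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Hold out ~1/5 of segments (at least one) as an inner validation set."""
    segs = segments_of(fm)
    rng = np.random.default_rng(child_seed(seed, 23))
    n_hold = max(1, len(segs) // 5)
    held = set(rng.choice(len(segs), size=n_hold, replace=False).tolist())
    val_mask = np.zeros(fm.n_epochs, dtype=bool)
    for j in held:
        val_mask[segs[j][1]] = True
    if val_mask.all():
        raise ValueError("holdout selection left no inner training segments")
    return fm.select(~val_mask), fm.select(val_mask)


def grid_search(
    train_fm: FeatureMatrix,
    spec: GridSearchSpec,
    base_config: ReservoirConfig = ReservoirConfig(),
    tc: TrainingConfig = TrainingConfig(),
    seed: int = 0,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Mean-over-repeats score per (alpha, lambda) cell; argmax selection.

    Ties break toward the smaller spectral radius, then the smaller leaking
    rate (the more contractive, more stable reservoir).
    """
    if spec.selection == "holdout":
        fit_fm, eval_fm = _holdout_split(train_fm, seed)
    else:
        fit_fm, eval_fm = train_fm, None
    rows = []
    for alpha, lam in spec.combinations():
        scores = []
        for r in range(spec.repeats):
            # Seeds keyed by the parameter values (not the cell position) so
            # the same (alpha, lambda) scores identically on any grid laid
            # over it — coarse and refined searches stay comparable.
            cfg = replace(
                base_config,
                leaking_rate=alpha,
                spectral_radius=lam,
                seed=child_seed(seed, int(round(alpha * 1000)), int(round(lam * 1000)), r),
            )
            scores.append(
                _fit_and_score_training(fit_fm, cfg, tc, spec.statistic, eval_fm)
            )
        rows.append(
            {
                "alpha": alpha,
                "lambda": lam,
                "score": float(np.mean(scores)),
                "score_sd": float(np.std(scores)),
            }
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["score", "lambda", "alpha"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    return {"alpha": float(best["alpha"]), "lambda": float(best["lambda"])}, table


def reservoir_sweep(
    train_fm: FeatureMatrix,
    spec: SweepSpec,
    base_config: ReservoirConfig = ReservoirConfig(),
    tc: TrainingConfig = TrainingConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Training-side score for every (reservoir size, connectivity) cell."""
    rows = []
    for n, c in spec.combinations():
        scores = []
        for r in range(spec.repeats):
            cfg = replace(
                base_config, n_units=n, connectivity=c,
                seed=child_seed(seed, n, int(round(c * 1000)), r),
            )
            scores.append(_fit_and_score_training(train_fm, cfg, tc, "accuracy"))
        rows.append({"n_units": n, "connectivity": c, "score": float(np.mean(scores))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-validation schemes
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """One fold's trained readout and its raw per-segment test traces.

    ``test_indices`` are the row positions (in the feature matrix handed to
    the CV function) that formed this fold's test side.
    """

    fold: str
    params: dict[str, float]
    train_accuracy: float
    test_accuracy: float
    traces: list[np.ndarray]
    truths: list[np.ndarray]
    segment_ids: list[str]
    w_out: np.ndarray
    test_indices: np.ndarray


@dataclass
class CVResult:
    scheme: str
    folds: list[FoldResult]

    @property
    def test_accuracies(self) -> np.ndarray:
        return np.array([f.test_accuracy for f in self.folds])

    @property
    def mean_test_accuracy(self) -> float:
        return float(self.test_accuracies.mean())

    @property
    def sem_test_accuracy(self) -> float:
        a = self.test_accuracies
        return float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean([f.train_accuracy for f in self.folds]))


def _run_fold(
    fold_name: str,
    train_fm: FeatureMatrix,
    test_fm: FeatureMatrix,
    spec: GridSearchSpec,
    base_config: ReservoirConfig,
    tc: TrainingConfig,
    seed: int,
    test_indices: np.ndarray | None = None,
    fixed_params: Optional[dict[str, float]] = None,
) -> FoldResult:
    """Standardize, grid-search, train and evaluate one fold.

    Everything fitted here — standardizer, hyperparameters, readout — sees
    only ``train_fm``; ``test_fm`` enters after the model is frozen.
    ``fixed_params`` skips the per-fold search (pre-selected hyperparameters).
    """
    params_std = fit_standardizer(train_fm)
    train_scaled = apply_standardizer(train_fm, params_std)
    if fixed_params is None:
        best, _ = grid_search(
            train_scaled, spec, base_config, tc, seed=child_seed(seed, 11)
        )
    else:
        best = dict(fixed_params)
    cfg = replace(
        base_config,
        leaking_rate=best["alpha"],
        spectral_radius=best["lambda"],
        seed=child_seed(seed, 13),
    )
    model = init_reservoir(cfg, train_fm.n_features)
    fit_segments(model, _train_segments(train_scaled), tc)
    train_acc, _, _, _ = _score_model(model, train_scaled)
    test_scaled = apply_standardizer(test_fm, params_std)
    test_acc, traces, truths, seg_ids = _score_model(model, test_scaled)
    return FoldResult(
        fold=fold_name,
        params=best,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        traces=traces,
        truths=truths,
        segment_ids=seg_ids,
        w_out=model.w_out.copy(),
        test_indices=np.zeros(0, dtype=int) if test_indices is None else test_indices,
    )


def within_subject_cv(
    fm: FeatureMatrix,
    spec: GridSearchSpec = GridSearchSpec(),
    base_config: ReservoirConfig = ReservoirConfig(),
    tc: TrainingConfig = TrainingConfig(),
    seed: int = 0,
    grid_scope: str = "fold",
) -> CVResult:
    """Leave-one-run-out over one subject's K runs.

    Fold i tests on run i — its attention stream plus the paired rest block
    (the rest that followed the run) — and trains on the remaining runs.
    Runs left with zero surviving epochs are skipped with a warning.

    ``grid_scope='fold'`` (default) reruns the hyperparameter search inside
    every fold on that fold's training runs; ``'subject'`` selects once on
    the whole subject's data and reuses the pair across folds — cheaper and
    closer to a single per-subject optimization, but the selection then sees
    every run, which is a documented source of optimism.
    """
    subjects = np.unique(fm.subject)
    if subjects.size != 1:
        raise ValueError("within-subject validation expects a single subject")
    if grid_scope not in ("fold", "subject"):
        raise ValueError("grid_scope must be 'fold' or 'subject'")
    runs = np.unique(fm.run)
    if runs.size < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out")
    fixed_params = None
    if grid_scope == "subject":
        params_std = fit_standardizer(fm)
        fixed_params, _ = grid_search(
            apply_standardizer(fm, params_std), spec, base_config, tc,
            seed=child_seed(seed, 19),
        )
    folds = []
    for k in runs:
        test_mask = fm.run == k
        if not test_mask.any():  # pragma: no cover - runs come from the data
            logger.warning("run %s has no surviving epochs; fold skipped", k)
            continue
        folds.append(
            _run_fold(
                f"run{k}",
                fm.select(~test_mask),
                fm.select(test_mask),
                spec,
                base_config,
                tc,
                child_seed(seed, int(k)),
                test_indices=np.flatnonzero(test_mask),
                fixed_params=fixed_params,
            )
        )
    return CVResult(scheme="within_subject", folds=folds)


def cross_subject_cv(
    fm: FeatureMatrix,
    spec: GridSearchSpec = GridSearchSpec(),
    base_config: ReservoirConfig = ReservoirConfig(),
    tc: TrainingConfig = TrainingConfig(),
    seed: int = 0,
) -> CVResult:
    """Leave-one-subject-out: each subject is the test set exactly once."""
    subjects = np.unique(fm.subject)
    if subjects.size < 2:
        raise ValueError("need at least 2 subjects for cross-subject validation")
    folds = []
    for i, subj in enumerate(subjects):
        test_mask = fm.subject == subj
        folds.append(
            _run_fold(
                str(subj),
                fm.select(~test_mask),
                fm.select(test_mask),
                spec,
                base_config,
                tc,
                child_seed(seed, i),
                test_indices=np.flatnonzero(test_mask),
            )
        )
    return CVResult(scheme="cross_subject", folds=folds)


def kfold_cv(
    fm: FeatureMatrix,
    k: int = 10,
    spec: GridSearchSpec = GridSearchSpec(),
    base_config: ReservoirConfig = ReservoirConfig(),
    tc: TrainingConfig = TrainingConfig(),
    seed: int = 0,
) -> CVResult:
    """Pooled epochs randomly partitioned into k folds (sizes differ by <= 1),
    each fold tested once against a model trained on the rest.

    The partition is over epochs, so temporally adjacent epochs can straddle
    the train/test boundary — an optimism source inherent to this scheme.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if fm.n_epochs < k:
        raise ValueError("fewer epochs than folds")
    rng = np.random.default_rng(child_seed(seed, 17))
    assignment = rng.permutation(fm.n_epochs) % k
    folds = []
    for i in range(k):
        test_mask = assignment == i
        folds.append(
            _run_fold(
                f"fold{i}",
                fm.select(~test_mask),
                fm.select(test_mask),
                spec,
                base_config,
                tc,
                child_seed(seed, i),
                test_indices=np.flatnonzero(test_mask),
            )
        )
    return CVResult(scheme="kfold", folds=folds)


# ---------------------------------------------------------------------------
# Smoothing curve
# ---------------------------------------------------------------------------

def smoothing_curve(
    cv: CVResult, windows: Sequence[int] = tuple(range(1, 13))
) -> pd.DataFrame:
    """Re-threshold each fold's stored raw traces per smoothing window.

    No retraining: the causal moving average runs within each contiguous
    segment, then the sign rule is re-applied. Window 1 reproduces the
    unsmoothed accuracies exactly.
    """
    for f in cv.folds:
        if not f.traces:
            raise ValueError(f"fold {f.fold} has no stored readout traces")
    rows = []
    for n in windows:
        fold_accs = []
        for f in cv.folds:
            pred = np.concatenate([classify(smooth(t, int(n))) for t in f.traces])
            true = np.concatenate(f.truths)
            fold_accs.append(accuracy(pred, true))
        rows.append({"window": int(n), "accuracy": float(np.mean(fold_accs))})
    return pd.DataFrame(rows)
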