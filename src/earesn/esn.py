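"""Leaky echo state network with a ridge-trained linear readout.

The reservoir is a fixed random recurrent layer: input weights uniform in
[-sigma, sigma], recurrent weights sparse (connectivity c) uniform in
[-0.5, 0.5] and rescaled so the largest eigenvalue magnitude equals the
target spectral radius lambda. The state update is the leaky-integrator
recursion

    x(t) = (1 - alpha) x(t-1) + alpha tanh(W_in u(t) + W x(t-1))

with leaking rate alpha in (0, 1]. Only the readout is trained: a single
linear unit y(t) = W_out (u(t), x(t), 1) fitted by Tikhonov-regularized
least squares (ridge) on the concatenation of input, reservoir state and a
constant bias component. Positive readouts classify as attentive (+1),
non-positive as rest (-1). A causal moving-average smoother over the readout
trace trades latency for stability.

No output feedback is used and W_in / W are never altered by training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ReservoirConfig",
    "TrainingConfig",
    "SmoothingConfig",
    "ESNModel",
    "init_reservoir",
    "update_state",
    "run_sequence",
    "design_matrix",
    "train_readout",
    "fit_segments",
    "predict",
    "predict_segments",
    "classify",
    "smooth",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ReservoirConfig:
    """Fixed reservoir hyperparameters.

    ``spectral_radius`` (lambda) is searched in (0, 2]: values below 1
    guarantee the echo state property, values slightly above 1 often work in
    practice. ``leaking_rate`` (alpha) in (0, 1] slows reservoir dynamics as
    it decreases. ``input_scaling`` (sigma) scales the input weights; with
    features rescaled to [-1, 1] the default 1.0 keeps tanh in its sensitive
    range.
    """

    n_units: int = 100
    connectivity: float = 1.0
    leaking_rate: float = 0.3
    spectral_radius: float = 0.9
    input_scaling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not 0.0 < self.connectivity <= 1.0:
            raise ValueError("connectivity must be in (0, 1]")
        if not 0.0 < self.leaking_rate <= 1.0:
            raise ValueError("leaking_rate must be in (0, 1]")
        if not 0.0 < self.spectral_radius <= 2.0:
            raise ValueError("spectral_radius must be in (0, 2]")


@dataclass(frozen=True)
class TrainingConfig:
    """Readout training: ridge parameter and optional washout.

    The default beta = 1e-8 keeps the fit close to plain least squares while
    stabilizing near-singular designs.
    """

    beta: float = 1e-8
    washout: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.washout < 0:
            raise ValueError("washout must be >= 0")


@dataclass(frozen=True)
class SmoothingConfig:
    """Causal moving-average window over readout outputs (0.5 s per output)."""

    n: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("window size must be >= 1")


@dataclass
class ESNModel:
    """Reservoir weights, optional trained readout, and current state."""

    w_in: np.ndarray
    w: np.ndarray
    config: ReservoirConfig
    n_features: int
    w_out: Optional[np.ndarray] = None
    state: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def reset_state(self) -> None:
        self.state = np.zeros(self.config.n_units)


def init_reservoir(config: ReservoirConfig, n_features: int) -> ESNModel:
    """Draw and freeze the random input and recurrent weights.

    W entries are nonzero with probability ``connectivity``, uniform in
    [-0.5, 0.5], then rescaled so |largest eigenvalue| equals the target
    spectral radius. Degenerate draws (zero spectral radius, possible at tiny
    N x c) are resampled with an incremented seed.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    seed = config.seed
    for attempt in range(100):
        rng = np.random.default_rng(seed)
        w_in = rng.uniform(-config.input_scaling, config.input_scaling,
                           size=(config.n_units, n_features))
        w = rng.uniform(-0.5, 0.5, size=(config.n_units, config.n_units))
        mask = rng.random((config.n_units, config.n_units)) < config.connectivity
        w = np.where(mask, w, 0.0)
        rho = float(np.abs(np.linalg.eigvals(w)).max()) if w.any() else 0.0
        if rho > 0.0:
            break
        seed += 1
        logger.warning(
            "degenerate reservoir draw (spectral radius 0); resampling with seed %d",
            seed,
        )
    else:  # pragma: no cover - requires 100 degenerate draws in a row
        raise RuntimeError("could not sample a non-degenerate reservoir")
    w *= config.spectral_radius / rho
    model = ESNModel(w_in=w_in, w=w, config=config, n_features=n_features)
    model.reset_state()
    return model


def update_state(model: ESNModel, x_prev: np.ndarray, u: np.ndarray) -> np.ndarray:
    """One leaky-integrator step; alpha interpolates old state and tanh drive."""
    u = np.asarray(u, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    if u.shape[0] != model.n_features or x_prev.shape[0] != model.config.n_units:
        raise ValueError("dimension mismatch between model, state and input")
    if not (np.isfinite(u).all() and np.isfinite(x_prev).all()):
        raise ValueError("non-finite state or input")
    a = model.config.leaking_rate
    return (1.0 - a) * x_prev + a * np.tanh(model.w_in @ u + model.w @ x_prev)


def run_sequence(
    model: ESNModel, U: np.ndarray, x0: Optional[np.ndarray] = None
) -> np.ndarray:
    """Iterate the state update over an ordered input sequence.

    Returns the T x N matrix of states x(1)..x(T) and leaves the model's
    stored state at x(T). An empty sequence returns an empty matrix and
    leaves the state untouched.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    x = np.zeros(model.config.n_units) if x0 is None else np.asarray(x0, dtype=float)
    states = np.empty((U.shape[0], model.config.n_units))
    for t in range(U.shape[0]):
        x = update_state(model, x, U[t])
        states[t] = x
    if U.shape[0]:
        model.state = x
    return states


def design_matrix(U: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Readout design rows: concatenated (u(t), x(t)) plus a constant bias 1."""
    U = np.atleast_2d(U)
    return np.hstack([U, states, np.ones((U.shape[0], 1))])


def train_readout(
    states: np.ndarray,
    U: np.ndarray,
    targets: np.ndarray,
    tc: TrainingConfig = TrainingConfig(),
) -> np.ndarray:
    """Ridge-fit the readout on (input, state) rows.

    Solves the regularized normal equations
    (D^T D + beta I) w = D^T y on the design D = [u, x, 1]; only the readout
    is learned, reservoir weights are untouched.
    """
    states = np.atleast_2d(states)
    U = np.atleast_2d(U)
    targets = np.asarray(targets, dtype=float)
    if not (states.shape[0] == U.shape[0] == targets.shape[0]):
        raise ValueError("states, inputs and targets must have equal row counts")
    if tc.washout >= states.shape[0]:
        raise ValueError("washout leaves no training rows")
    D = design_matrix(U, states)[tc.washout :]
    y = targets[tc.washout :]
    if D.shape[0] < 1:
        raise ValueError("need at least one training row")
    A = D.T @ D + tc.beta * np.eye(D.shape[1])
    return np.linalg.solve(A, D.T @ y)


def fit_segments(
    model: ESNModel,
    segments: Sequence[tuple[np.ndarray, np.ndarray]],
    tc: TrainingConfig = TrainingConfig(),
) -> ESNModel:
    """Train the readout over several contiguous sequences.

    The reservoir state is reset to zero at every segment boundary (segments
    are independent streams; carrying state across them would couple
    unrelated intervals). Washout applies per segment.
    """
    designs, targets = [], []
    for U, y in segments:
        U = np.atleast_2d(U)
        if U.shape[0] == 0:
            continue
        states = run_sequence(model, U, x0=np.zeros(model.config.n_units))
        D = design_matrix(U, states)[tc.washout :]
        if D.shape[0]:
            designs.append(D)
            targets.append(np.asarray(y, dtype=float)[tc.washout :])
    if not designs:
        raise ValueError("no training rows after washout")
    D = np.vstack(designs)
    y = np.concatenate(targets)
    A = D.T @ D + tc.beta * np.eye(D.shape[1])
    model.w_out = np.linalg.solve(A, D.T @ y)
    return model


def predict(
    model: ESNModel, U: np.ndarray, x0: Optional[np.ndarray] = None
) -> np.ndarray:
    """Readout trace y(t) = W_out (u(t), x(t), 1) over one sequence."""
    if model.w_out is None:
        raise ValueError("model has no trained readout")
    U = np.atleast_2d(np.asarray(U, dtype=float))
    states = run_sequence(model, U, x0=x0)
    return design_matrix(U, states) @ model.w_out


def predict_segments(
    model: ESNModel, segments: Sequence[np.ndarray]
) -> list[np.ndarray]:
    """Per-segment readout traces, state reset at each boundary."""
    return [
        predict(model, U, x0=np.zeros(model.config.n_units)) for U in segments
    ]


def classify(y: np.ndarray) -> np.ndarray:
    """Sign rule: positive readout -> attentive (+1), else rest (-1).

    y = 0 breaks toward rest, the conservative class for an attention
    monitor.
    """
    y = np.asarray(y, dtype=float)
    return np.where(y > 0.0, 1, -1).astype(int)


def smooth(y: np.ndarray, sc: SmoothingConfig | int) -> np.ndarray:
    """Causal moving average: each output becomes the mean of itself and the
    n-1 previous outputs; early outputs average every available predecessor."""
    n = sc.n if isinstance(sc, SmoothingConfig) else int(sc)
    if n < 1:
        raise ValueError("window size must be >= 1")
    y = np.asarray(y, dtype=float)
    if y.size == 0 or n == 1:
        return y.copy()
    c = np.concatenate([[0.0], np.cumsum(y)])
    t = np.arange(1, y.size + 1)
    lo = np.maximum(t - n, 0)
    return (c[t] - c[lo]) / (t - lo)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: ESNModel, path) -> None:
    """Single-archive serialization (recurrent weights in sparse triplets)."""
    rows, cols = np.nonzero(model.w)
    cfg = model.config
    np.savez(
        path,
        w_in=model.w_in,
        w_rows=rows,
        w_cols=cols,
        w_vals=model.w[rows, cols],
        n_units=cfg.n_units,
        w_out=model.w_out if model.w_out is not None else np.zeros(0),
        has_readout=model.w_out is not None,
        n_features=model.n_features,
        config=np.array(
            [cfg.connectivity, cfg.leaking_rate, cfg.spectral_radius,
             cfg.input_scaling, cfg.seed]
        ),
    )


def load_model(path) -> ESNModel:
    with np.load(path) as z:
        n_units = int(z["n_units"])
        w = np.zeros((n_units, n_units))
        w[z["w_rows"], z["w_cols"]] = z["w_vals"]
        cfg = ReservoirConfig(
            n_units=n_units,
            connectivity=float(z["config"][0]),
            leaking_rate=float(z["config"][1]),
            spectral_radius=float(z["config"][2]),
            input_scaling=float(z["config"][3]),
            seed=int(z["config"][4]),
        )
        model = ESNModel(
            w_in=z["w_in"],
            w=w,
            config=cfg,
            n_features=int(z["n_features"]),
            w_out=z["w_out"] if bool(z["has_readout"]) else None,
        )
    model.reset_state()
    return model
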