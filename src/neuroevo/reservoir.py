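"""Reservoir computers and online FORCE/RLS training of their readout.

A reservoir computer here is a fixed random recurrent network of
``n_neuron`` rate units with a single linear readout that is fed back into
the network.  Internal activity ``x`` evolves as

    dx/dt = -x + Q r + B y,      r = tanh(x),   y = F r

where ``Q`` (sparse, zero diagonal) holds the recurrent weights, ``B`` the
feedback weights and ``F`` the readout weights.  Only ``F`` is ever trained.
Training uses first-order reduced FORCE learning: a recursive least squares
(RLS) update of ``F`` driven by the instantaneous readout error, with ``P``
tracking the ridge-regularised inverse correlation matrix of the firing
rates.  Training one reservoir on another's output is the copying operation
the evolutionary dynamics in :mod:`neuroevo.evolution` is built on: the
teacher supplies the target, and the learner's readout while tracking it is
the (imperfect) copy.

Integration is forward Euler with step ``dt``.  RLS updates are applied at
every integration step by default (``rls_every`` can thin them out); after
each update the corrected readout is the one fed back into the network, so
the feedback loop carries a near-target signal throughout training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import sparse

from .signals import Signal, _steps

__all__ = [
    "ReservoirParams",
    "Reservoir",
    "RLSState",
    "TrainingResult",
    "BatchTrainingResult",
    "DivergenceError",
    "init_reservoir",
    "step_dynamics",
    "run_autonomous",
    "rls_step",
    "force_train",
    "force_train_many",
    "save_reservoir",
    "load_reservoir",
]

#: Internal activity beyond this magnitude is treated as numerical divergence.
DIVERGENCE_GUARD = 1e6


class DivergenceError(RuntimeError):
    """Internal activity left the numerically meaningful range."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"reservoir state diverged at step {step}")


@dataclass(frozen=True)
class ReservoirParams:
    """Fixed structural and training parameters of a reservoir unit.

    Defaults are the full-scale simulation settings: 1000 neurons, sparse
    recurrent connectivity of density 0.1, chaoticity scale g = 1.5 (above
    the edge of chaos, so untrained reservoirs are spontaneously active),
    Euler step dt = 0.1, RLS learning rate alpha = 1, a single full-length
    training pass of 300 time units, 300 time units of signal generation and
    a 30-time-unit evaluation window.
    """

    n_neuron: int = 1000
    n_readout: int = 1
    p: float = 0.1
    g: float = 1.5
    dt: float = 0.1
    alpha: float = 1.0
    t_train: float = 300.0
    t_signal: float = 300.0
    t_evaluation: float = 30.0
    rls_every: int = 1

    def __post_init__(self) -> None:
        if self.n_neuron < 1:
            raise ValueError("n_neuron must be a positive integer")
        if self.n_readout != 1:
            raise ValueError("only a single readout neuron is supported")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("connection probability p must lie in (0, 1]")
        for name in ("g", "dt", "alpha", "t_train", "t_signal", "t_evaluation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_evaluation > self.t_signal or self.t_evaluation > self.t_train:
            raise ValueError("t_evaluation must fit inside t_signal and t_train")
        if self.rls_every < 1:
            raise ValueError("rls_every must be a positive integer")

    @property
    def n_train_steps(self) -> int:
        return _steps(self.t_train, self.dt)

    @property
    def n_signal_steps(self) -> int:
        return _steps(self.t_signal, self.dt)

    @property
    def n_eval_steps(self) -> int:
        return _steps(self.t_evaluation, self.dt)


@dataclass
class Reservoir:
    """One recurrent unit: weights plus its current internal state."""

    Q: sparse.csr_array
    F: np.ndarray  # (1, n_neuron) readout weights
    B: np.ndarray  # (n_neuron, 1) feedback weights
    x: np.ndarray  # (n_neuron,) internal activity
    params: ReservoirParams
    seed: int | None = None

    @property
    def rates(self) -> np.ndarray:
        return np.tanh(self.x)

    @property
    def readout(self) -> float:
        return float(self.F[0] @ self.rates)

    def copy(self) -> "Reservoir":
        return Reservoir(self.Q.copy(), self.F.copy(), self.B.copy(),
                         self.x.copy(), self.params, self.seed)


def init_reservoir(params: ReservoirParams, seed: int) -> Reservoir:
    """Draw a reservoir with the standard random weight ensemble.

    Readout weights are uniform on (-1, 1).  Recurrent and feedback weights
    are Gaussian with standard deviation ``g / sqrt(p * n_neuron)``; the
    recurrent matrix keeps each off-diagonal entry with probability ``p``
    and has a zero diagonal.  The internal state starts from standard
    normal coordinates.  All draws are deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = params.n_neuron
    scale = params.g / np.sqrt(params.p * n)
    F = rng.uniform(-1.0, 1.0, (1, n))
    mask = rng.random((n, n)) < params.p
    np.fill_diagonal(mask, False)
    dense = rng.normal(0.0, scale, (n, n))
    Q = sparse.csr_array(np.where(mask, dense, 0.0))
    B = rng.normal(0.0, scale, (n, 1))
    x = rng.standard_normal(n)
    return Reservoir(Q=Q, F=F, B=B, x=x, params=params, seed=int(seed))


def _check_state(x: np.ndarray, step: int) -> None:
    m = float(np.max(np.abs(x))) if x.size else 0.0
    if not np.isfinite(m) or m > DIVERGENCE_GUARD:
        raise DivergenceError(step)


def step_dynamics(reservoir: Reservoir) -> Reservoir:
    """One forward-Euler step of the autonomous dynamics, in place.

    The feedback term uses the readout evaluated at the pre-step state.
    """
    p = reservoir.params
    r = np.tanh(reservoir.x)
    y = reservoir.F[0] @ r
    dx = -reservoir.x + reservoir.Q @ r + reservoir.B[:, 0] * y
    reservoir.x = reservoir.x + p.dt * dx
    _check_state(reservoir.x, 0)
    return reservoir


def run_autonomous(reservoir: Reservoir, duration: float) -> Signal:
    """Generate the readout trace over ``duration``, advancing the state.

    Returns ``y(t_k)`` for ``k = 0..duration/dt - 1`` where ``y(t_0)`` is the
    readout at the current state; the reservoir is left in the state reached
    at the end of the run.
    """
    p = reservoir.params
    k_steps = _steps(duration, p.dt)
    out = np.empty(k_steps)
    x = reservoir.x
    Fv, Bv = reservoir.F[0], reservoir.B[:, 0]
    for k in range(k_steps):
        r = np.tanh(x)
        y = Fv @ r
        out[k] = y
        x = x + p.dt * (-x + reservoir.Q @ r + Bv * y)
        m = float(np.max(np.abs(x)))
        if not np.isfinite(m) or m > DIVERGENCE_GUARD:
            raise DivergenceError(k)
    reservoir.x = x
    return Signal(out, p.dt)


@dataclass
class RLSState:
    """Running RLS estimate ``P`` of the regularised inverse rate correlation.

    ``P`` starts from ``I / alpha`` and, after updates with rate vectors
    ``r_1..r_k``, equals ``(alpha I + sum r r^T)^(-1)``; it stays symmetric
    positive definite throughout.
    """

    P: np.ndarray
    alpha: float

    @classmethod
    def initial(cls, n_neuron: int, alpha: float) -> "RLSState":
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        return cls(np.eye(n_neuron) / alpha, float(alpha))


def rls_step(state: RLSState, r: np.ndarray, e: float
             ) -> tuple[RLSState, np.ndarray]:
    """One recursive-least-squares update.

    Returns the updated state (modified in place) and the readout weight
    increment ``dF = -e P r / (1 + r^T P r)``, with ``P`` taken pre-update.
    The matrix update is the Sherman-Morrison downdate
    ``P <- P - (P r)(P r)^T / (1 + r^T P r)``; the denominator is at least 1
    whenever ``P`` is positive semi-definite, so the step never divides by
    zero.
    """
    Pr = state.P @ r
    c = 1.0 + float(r @ Pr)
    dF = -(e / c) * Pr
    state.P -= np.outer(Pr, Pr / c)
    return state, dF


@dataclass
class TrainingResult:
    """Outcome of one FORCE training episode."""

    reservoir: Reservoir
    error: np.ndarray        # instantaneous readout error e(t), length t_train/dt
    output: np.ndarray       # readout emitted while tracking the target
    final_rms: float         # RMS of e over the final evaluation window
    rls: RLSState | None = None


def _as_target(target: Signal | np.ndarray, n_steps: int) -> np.ndarray:
    samples = target.samples if isinstance(target, Signal) else np.asarray(target, float)
    if samples.size == 0:
        raise ValueError("target signal is empty")
    if samples.size >= n_steps:
        return samples[:n_steps]
    # shorter targets are tiled periodically
    reps = -(-n_steps // samples.size)
    return np.tile(samples, reps)[:n_steps]


def force_train(learner: Reservoir, target: Signal | np.ndarray,
                *, rls_every: int | None = None,
                keep_rls: bool = False) -> TrainingResult:
    """Train the learner's readout on a target trace in a single full pass.

    The RLS state is freshly initialised for the episode.  At every
    integration step the readout error against the target is recorded; every
    ``rls_every`` steps (default taken from the params) the readout weights
    and ``P`` are updated.  The feedback loop always carries the learner's
    own readout, never the target.  Raises :class:`DivergenceError` with the
    offending step index if the internal state explodes.
    """
    p = learner.params
    cadence = p.rls_every if rls_every is None else int(rls_every)
    n_steps = p.n_train_steps
    tgt = _as_target(target, n_steps)
    state = RLSState.initial(p.n_neuron, p.alpha)
    P = state.P
    x = learner.x
    Fv = learner.F[0]
    Bv = learner.B[:, 0]
    Q = learner.Q
    dt = p.dt
    err = np.empty(n_steps)
    out = np.empty(n_steps)
    for k in range(n_steps):
        r = np.tanh(x)
        y = float(Fv @ r)
        e = y - tgt[k]
        if k % cadence == 0:
            Pr = P @ r
            c = 1.0 + float(r @ Pr)
            Fv -= (e / c) * Pr
            P -= np.outer(Pr, Pr / c)
            y_fb = float(Fv @ r)  # feedback carries the corrected readout
        else:
            y_fb = y
        x = x + dt * (-x + Q @ r + Bv * y_fb)
        m = float(np.max(np.abs(x)))
        if not np.isfinite(m) or m > DIVERGENCE_GUARD:
            raise DivergenceError(k)
        err[k] = e
        out[k] = y
    learner.x = x
    n_eval = p.n_eval_steps
    final_rms = float(np.sqrt(np.mean(err[-n_eval:] ** 2)))
    return TrainingResult(learner, err, out, final_rms,
                          rls=state if keep_rls else None)


@dataclass
class BatchTrainingResult:
    """Outcome of training several reservoirs in lock step."""

    outputs: np.ndarray       # (n_units, n_steps) readouts during training
    errors: np.ndarray        # (n_units, n_steps)
    final_rms: np.ndarray     # (n_units,)
    diverged: np.ndarray      # (n_units,) bool
    diverged_step: np.ndarray  # (n_units,) int, -1 where training succeeded


def force_train_many(reservoirs: list[Reservoir],
                     targets: np.ndarray,
                     *, dtype=np.float32,
                     check_every: int = 25) -> BatchTrainingResult:
    """Train several same-sized reservoirs simultaneously, one per target.

    This is the population-scale engine behind the evolutionary loop: the
    per-unit arithmetic is identical to :func:`force_train` (verified by a
    cross-check in the test suite) but the states, readout weights and RLS
    matrices of all learners are stacked and the integration runs inside a
    compiled kernel.  ``dtype`` selects the working precision; the default
    single precision is ample for RLS at these problem sizes and halves the
    memory traffic of the quadratic-cost updates.

    Weights and states of successfully trained reservoirs are written back;
    a diverging unit keeps its pre-training readout weights and is flagged
    together with the first step at which the guard tripped (checked every
    ``check_every`` steps).
    """
    from ._engine import train_kernel

    if not reservoirs:
        raise ValueError("no reservoirs to train")
    p = reservoirs[0].params
    n = p.n_neuron
    n_units = len(reservoirs)
    n_steps = p.n_train_steps
    dtype = np.dtype(dtype)

    tgt = np.empty((n_units, n_steps), dtype=dtype)
    for b, res in enumerate(reservoirs):
        if res.params.n_neuron != n:
            raise ValueError("all reservoirs in a batch must share a size")
        tgt[b] = _as_target(targets[b], n_steps)

    X = np.stack([r.x for r in reservoirs]).astype(dtype)
    Fm = np.stack([r.F[0] for r in reservoirs]).astype(dtype)
    Bfb = np.stack([r.B[:, 0] for r in reservoirs]).astype(dtype)

    # dense stack of the sparse recurrent matrices (see the kernel docstring)
    Q = np.stack([r.Q.toarray() for r in reservoirs]).astype(dtype)

    P = np.zeros((n_units, n, n), dtype=dtype)
    diag = np.arange(n)
    P[:, diag, diag] = 1.0 / p.alpha

    out = np.empty((n_units, n_steps), dtype=dtype)
    err = np.empty((n_units, n_steps), dtype=dtype)
    div_step = np.full(n_units, -1, dtype=np.int64)

    train_kernel(X, Fm, Bfb, Q, P, tgt,
                 dtype.type(p.dt), p.rls_every, dtype.type(DIVERGENCE_GUARD),
                 check_every, out, err, div_step)

    for b, res in enumerate(reservoirs):
        if div_step[b] < 0:
            res.F[0] = Fm[b].astype(np.float64)
            res.x = X[b].astype(np.float64)

    err64 = err.astype(np.float64)
    n_eval = p.n_eval_steps
    final_rms = np.sqrt(np.mean(err64[:, -n_eval:] ** 2, axis=1))
    return BatchTrainingResult(outputs=out.astype(np.float64), errors=err64,
                               final_rms=final_rms, diverged=div_step >= 0,
                               diverged_step=div_step)


# ---------------------------------------------------------------------------
# serialization

_FORMAT_VERSION = 1


def save_reservoir(reservoir: Reservoir, basepath: str | Path) -> None:
    """Write weights to ``<basepath>.npz`` and params/seed to ``<basepath>.json``."""
    base = Path(basepath)
    Q = reservoir.Q.tocsr()
    np.savez_compressed(
        base.with_suffix(".npz"),
        Q_data=Q.data, Q_indices=Q.indices, Q_indptr=Q.indptr,
        F=reservoir.F, B=reservoir.B, x=reservoir.x,
    )
    meta = {
        "format_version": _FORMAT_VERSION,
        "seed": reservoir.seed,
        "params": asdict(reservoir.params),
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_reservoir(basepath: str | Path) -> Reservoir:
    base = Path(basepath)
    meta = json.loads(base.with_suffix(".json").read_text())
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported reservoir file version")
    params = ReservoirParams(**meta["params"])
    n = params.n_neuron
    with np.load(base.with_suffix(".npz")) as data:
        Q = sparse.csr_array((data["Q_data"], data["Q_indices"], data["Q_indptr"]),
                             shape=(n, n))
        return Reservoir(Q=Q, F=data["F"], B=data["B"], x=data["x"],
                         params=params, seed=meta.get("seed"))
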