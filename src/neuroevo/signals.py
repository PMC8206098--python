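"""Periodic seed signals, calibrated noise mutation, and evaluation sampling.

The replicating unit throughout this package is a discretised, one-dimensional
firing-rate trace: the readout of a reservoir computer sampled on a regular
time grid.  This module constructs the random band-limited signals used to
seed a population (truncated Fourier series with uniform coefficients),
perturbs traces with white Gaussian noise whose energy over the evaluation
window is calibrated exactly, and samples trace amplitudes at the regular
"bin edge" times from which combinatorial solutions are decoded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Signal",
    "FourierSpec",
    "random_fourier_signal",
    "rescale_to_range",
    "inject_noise",
    "sample_at_intervals",
]


@dataclass
class Signal:
    """A uniformly sampled one-dimensional trace.

    Parameters
    ----------
    samples : ndarray
        Amplitudes on the grid ``t_k = k * dt``.
    dt : float
        Time step between consecutive samples.
    spec : FourierSpec, optional
        The analytic generator of the trace, when one exists.  Traces that
        went through noise injection or reservoir training lose it.
    scale : float, optional
        Multiplicative factor applied to ``spec``'s raw waveform when the
        trace was realised; needed to extend the trace analytically.
    """

    samples: np.ndarray
    dt: float
    spec: "FourierSpec | None" = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("signal samples must be one-dimensional")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("signal samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def copy(self) -> "Signal":
        return Signal(self.samples.copy(), self.dt, self.spec, self.scale)

    def evaluation_window(self, t_evaluation: float) -> np.ndarray:
        """Return the final ``t_evaluation`` time units of the trace."""
        k = _steps(t_evaluation, self.dt)
        if k > self.n_samples:
            raise ValueError("evaluation window longer than signal")
        return self.samples[self.n_samples - k:]

    def to_tsv(self, path: str | Path) -> None:
        t = np.arange(self.n_samples) * self.dt
        np.savetxt(
            path,
            np.column_stack([t, self.samples]),
            delimiter="\t",
            header="time\tamplitude",
            comments="",
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Signal":
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        data = np.atleast_2d(data)
        t, y = data[:, 0], data[:, 1]
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
        return cls(y, dt)


def _steps(duration: float, dt: float) -> int:
    """Number of grid steps in ``duration``, requiring near-commensurability."""
    k = duration / dt
    rounded = round(k)
    if abs(k - rounded) > 1e-6:
        raise ValueError(f"duration {duration} is not a multiple of dt {dt}")
    return int(rounded)


@dataclass(frozen=True)
class FourierSpec:
    """Coefficients of a random truncated Fourier series.

    The raw waveform is ``y(t) = sum_m a_m sin(m w t) + b_m cos(m w t)``
    for ``m = 1..n_fourier`` with fundamental angular frequency
    ``w = 2 pi / period``; the canonical form ``sin(m t)`` corresponds to
    the default period 2*pi.  Coefficients are drawn uniformly from
    [-0.5, 0.5].
    """

    a: np.ndarray
    b: np.ndarray
    range_value: float = 2.0
    period: float = 2.0 * np.pi

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape or self.a.ndim != 1 or self.a.size < 1:
            raise ValueError("a and b must be equal-length 1-D coefficient vectors")
        if np.any(np.abs(self.a) > 0.5 + 1e-12) or np.any(np.abs(self.b) > 0.5 + 1e-12):
            raise ValueError("Fourier coefficients must lie in [-0.5, 0.5]")
        if self.range_value <= 0:
            raise ValueError("range_value must be positive")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def n_fourier(self) -> int:
        return self.a.size

    @classmethod
    def random(cls, n_fourier: int, range_value: float,
               rng: np.random.Generator,
               period: float = 2.0 * np.pi) -> "FourierSpec":
        if n_fourier < 1:
            raise ValueError("n_fourier must be at least 1")
        a = rng.uniform(-0.5, 0.5, n_fourier)
        b = rng.uniform(-0.5, 0.5, n_fourier)
        return cls(a, b, range_value, period)

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Unscaled series evaluated at times ``t`` (analytic continuation)."""
        t = np.asarray(t, dtype=float)
        m = np.arange(1, self.n_fourier + 1)
        phase = np.multiply.outer(t * (2.0 * np.pi / self.period), m)
        return np.sin(phase) @ self.a + np.cos(phase) @ self.b


def rescale_to_range(samples: np.ndarray, range_value: float) -> np.ndarray:
    """Multiplicatively rescale so the peak-to-peak range equals ``range_value``.

    Idempotent: rescaling an already rescaled vector is a no-op up to
    floating-point rounding.  A constant vector is returned unchanged.
    """
    samples = np.asarray(samples, dtype=float)
    ptp = np.ptp(samples)
    if ptp == 0.0:
        return samples.copy()
    return samples * (range_value / ptp)


def random_fourier_signal(n_fourier: int, range_value: float, duration: float,
                          dt: float, seed: int | np.random.Generator,
                          period: float = 2.0 * np.pi) -> Signal:
    """Draw a random truncated Fourier series and realise it as a trace.

    ``2 * n_fourier`` coefficients are drawn uniformly from [-0.5, 0.5]; the
    realised trace is rescaled so its peak-to-peak range on the generated
    grid equals ``range_value``.  The fundamental period defaults to 2*pi
    in the time units of ``dt``.
    """
    rng = np.random.default_rng(seed)
    spec = FourierSpec.random(n_fourier, range_value, rng, period)
    k = _steps(duration, dt)
    t = np.arange(k) * dt
    y = spec.waveform(t)
    ptp = np.ptp(y) if k else 0.0
    scale = range_value / ptp if ptp > 0 else 1.0
    return Signal(y * scale, dt, spec=spec, scale=scale)


def inject_noise(signal: Signal, amplitude: float, t_evaluation: float,
                 seed: int | np.random.Generator) -> Signal:
    """Add white Gaussian noise with exactly calibrated energy.

    One independent Gaussian sample is added per time step over the whole
    trace.  The noise vector is rescaled so that the discrete integral
    ``sum(eta_k^2) * dt`` over the final ``t_evaluation`` time units equals
    ``amplitude`` exactly (not merely in expectation), making the noise level
    itself a noiseless control variable.
    """
    if amplitude < 0:
        raise ValueError("noise amplitude must be non-negative")
    if amplitude == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal(signal.n_samples)
    k_eval = _steps(t_evaluation, signal.dt)
    if k_eval < 1 or k_eval > signal.n_samples:
        raise ValueError("evaluation window must be positive and within the signal")
    energy = float(np.sum(eta[-k_eval:] ** 2)) * signal.dt
    eta *= np.sqrt(amplitude / energy)
    return Signal(signal.samples + eta, signal.dt)


def sample_at_intervals(signal: Signal, n_points: int,
                        window: tuple[float, float]) -> np.ndarray:
    """Amplitudes at ``n_points`` regular times within ``window``.

    The sampling times are ``t_k = start + k * (end - start) / n_points`` for
    ``k = 0..n_points-1``; each is mapped to the nearest sample index, which
    keeps the decoding bit-reproducible.
    """
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    start, end = window
    if start < -1e-9 or end > signal.duration + 1e-9 or end <= start:
        raise ValueError("sampling window must lie within the signal")
    times = start + np.arange(n_points) * ((end - start) / n_points)
    idx = np.rint(times / signal.dt).astype(int)
    idx = np.clip(idx, 0, signal.n_samples - 1)
    return signal.samples[idx]
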