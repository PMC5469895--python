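"""Exponential spike integration of gamma-motoneuron input.

Gamma-motoneuron spike trains are converted into fusimotor activation levels
f in [0, 1] with a synapse-like filter: between spikes the activation decays
exponentially with time constant tau, and each incoming spike produces an
instantaneous jump ``f <- f + r*(1 - f)`` whose size shrinks as f approaches
saturation.  Under regular input at inter-spike interval Delta the map has
the closed-form fixed point (the post-spike peak of the periodic orbit)::

    f+ = r / (1 - (1 - r) * exp(-Delta/tau))

Chain fibers share the static-channel integrator; their activation is the
bag2 static activation scaled by a constant factor (default 0.829).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FusimotorIntegrator",
    "SpikeTrain",
    "step_activation",
    "steady_state_activation",
    "chain_activation",
    "cycle_peak_average",
    "DEFAULT_CHAIN_SCALE",
]

#: averaged scaling factor of chain activation relative to bag2 static.
DEFAULT_CHAIN_SCALE = 0.829

#: default integrator constants per fusimotor channel.
DEFAULT_R_DYNAMIC = 0.08
DEFAULT_TAU_DYNAMIC_MS = 310.0
DEFAULT_R_STATIC = 0.09
DEFAULT_TAU_STATIC_MS = 425.0


@dataclass
class FusimotorIntegrator:
    """State and constants of one fusimotor spike-integration channel."""

    r_imp: float
    tau_ms: float
    f: float = 0.0
    chain_scale: float = DEFAULT_CHAIN_SCALE

    def __post_init__(self) -> None:
        if not 0.0 < self.r_imp < 1.0:
            raise ValueError(f"r_imp must be in (0, 1), got {self.r_imp}")
        if not self.tau_ms > 0:
            raise ValueError(f"tau_ms must be > 0, got {self.tau_ms}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")


@dataclass
class SpikeTrain:
    """Ordered spike events with per-event unit identifiers."""

    times: np.ndarray
    unit_ids: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids, dtype=int)
        if self.times.shape != self.unit_ids.shape:
            raise ValueError("times and unit_ids must have equal shapes")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if self.times.size and (
            self.times[0] < 0 or self.times[-1] > self.duration + 1e-12
        ):
            raise ValueError("times must lie within [0, duration]")
        if np.any(self.unit_ids < 0):
            raise ValueError("unit ids must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    def counts_per_step(self, dt: float, n_steps: int) -> np.ndarray:
        """Spike counts binned into ``n_steps`` simulation steps of width dt."""
        if self.times.size == 0:
            return np.zeros(n_steps, dtype=int)
        idx = np.minimum((self.times / dt + 1e-9).astype(int), n_steps - 1)
        return np.bincount(idx, minlength=n_steps)

    def for_unit(self, unit_id: int) -> np.ndarray:
        return self.times[self.unit_ids == unit_id]


def step_activation(
    state: FusimotorIntegrator, n_spikes: int, dt: float
) -> FusimotorIntegrator:
    """One simulation step: exponential decay, then one jump per spike.

    The decay factor is the exact ``exp(-dt/tau)``; jumps are applied
    sequentially so the activation stays in [0, 1] by construction.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if n_spikes < 0:
        raise ValueError("n_spikes must be >= 0")
    f = state.f * math.exp(-1000.0 * dt / state.tau_ms)
    for _ in range(n_spikes):
        f += state.r_imp * (1.0 - f)
    return replace(state, f=min(max(f, 0.0), 1.0))


def steady_state_activation(r_imp: float, tau_ms: float, input_rate: float) -> float:
    """Closed-form post-spike fixed point under regular input.

    ``r / (1 - (1 - r)*exp(-Delta/tau))`` with Delta = 1000/input_rate ms;
    strictly increasing in both ``input_rate`` and ``r_imp``, and tending to
    ``r_imp`` (a single isolated spike) as the rate goes to zero.
    """
    if input_rate <= 0:
        raise ValueError(f"input_rate must be > 0, got {input_rate}")
    delta_ms = 1000.0 / input_rate
    return r_imp / (1.0 - (1.0 - r_imp) * math.exp(-delta_ms / tau_ms))


def chain_activation(f_static: float, chain_scale: float = DEFAULT_CHAIN_SCALE) -> float:
    """Chain-fiber activation: the bag2 static activation scaled down."""
    if not 0.0 <= f_static <= 1.0:
        raise ValueError(f"f_static must be in [0, 1], got {f_static}")
    return chain_scale * f_static

def simulate_regular_grid(
    r: np.ndarray,
    tau_ms: np.ndarray,
    input_rate: float,
    duration: float,
    dt: float,
) -> np.ndarray:
    """Activation traces for many (r, tau) integrators under regular input.

    Vectorized across parameter combinations: ``r`` and ``tau_ms`` are
    broadcast 1-D arrays, the result has shape ``(n_params, n_steps)`` where
    row i holds the activation at the end of each step.  Used by the
    calibration grid search; a single-element array gives the plain trace.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    tau_ms = np.atleast_1d(np.asarray(tau_ms, dtype=float))
    r, tau_ms = np.broadcast_arrays(r, tau_ms)
    n_steps = int(round(duration / dt))
    n_events = int(math.floor(duration * input_rate + 1e-9))
    spike_times = np.arange(1, n_events + 1) / input_rate
    counts = np.zeros(n_steps, dtype=int)
    if n_events:
        idx = np.minimum((spike_times / dt + 1e-9).astype(int), n_steps - 1)
        counts = np.bincount(idx, minlength=n_steps)
    decay = np.exp(-1000.0 * dt / tau_ms)
    f = np.zeros_like(decay)
    out = np.empty((f.size, n_steps))
    for i in range(n_steps):
        f = f * decay
        for _ in range(counts[i]):
            f = f + r * (1.0 - f)
        out[:, i] = f
    return out


def cycle_peak_average(trace: np.ndarray) -> float:
    """Mean of the local maxima (post-spike peaks) of an activation trace.

    Under regular input the trace is a periodic sawtooth whose peaks converge
    to the closed-form fixed point of :func:`steady_state_activation`; the
    mean peak is therefore the natural simulated counterpart of that fixed
    point.  Falls back to the trace maximum when no interior peak exists.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        return float(trace.max()) if trace.size else 0.0
    interior = trace[1:-1]
    is_peak = (interior > trace[2:]) & (interior >= trace[:-2])
    peaks = interior[is_peak]
    if peaks.size == 0:
        return float(trace.max())
    return float(peaks.mean())
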