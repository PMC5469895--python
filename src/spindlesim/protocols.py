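"""Synthetic test-input generators: stretches, joint motions, gamma drives.

These reproduce the standard bench protocols for spindle models: the
ramp-and-hold fascicle stretch (hold at a shortened length, constant-speed
ramp, hold at the stretched length), sinusoidal joint motion with optional
dwells at the extremes, and regular or homogeneous-Poisson gamma-motoneuron
spike trains.  All generators are pure functions of their parameters (and
seed) and return consistent length/velocity or angle/velocity pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fusimotor import SpikeTrain
from .geometry import JointTrajectory
from .model_core import StretchInput

__all__ = [
    "RampHoldProtocol",
    "SinusoidProtocol",
    "ramp_and_hold",
    "sinusoid_joint",
    "regular_spike_train",
    "poisson_spike_train",
]


@dataclass(frozen=True)
class RampHoldProtocol:
    """Hold / constant-speed ramp / hold fascicle stretch.

    Defaults are the classic validation stretch: hold at 0.95 L0 for 1.1 s,
    ramp at 0.11 L0/s for 1.1 s, hold for 1.1 s.  The kinematic final
    plateau is ``l_start + ramp_speed*ramp_duration`` (1.071 L0 with the
    defaults); ``pin_plateau`` re-scales the ramp speed so the plateau hits
    a prescribed value instead (e.g. the nominal 1.08 L0).
    """

    l_start: float = 0.95
    ramp_speed: float = 0.11
    phase_durations: tuple[float, float, float] = (1.1, 1.1, 1.1)
    dt: float = 1e-3
    pin_plateau: float | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.l_start <= 0:
            raise ValueError("l_start must be positive")
        if self.l_end <= 0:
            raise ValueError("resulting lengths must stay positive")

    @property
    def effective_speed(self) -> float:
        if self.pin_plateau is None:
            return self.ramp_speed
        return (self.pin_plateau - self.l_start) / self.phase_durations[1]

    @property
    def l_end(self) -> float:
        return self.l_start + self.effective_speed * self.phase_durations[1]


@dataclass(frozen=True)
class SinusoidProtocol:
    """Sinusoidal joint motion (degrees) with optional dwells at the extremes.

    With ``hold_at_extremes > 0`` the motion pauses for that long each time
    it reaches an extreme, so the full period is ``1/frequency +
    2*hold_at_extremes`` (0.5 Hz with 1 s holds gives a 4 s period).
    """

    peak_to_peak: float = 45.0
    frequency: float = 0.2
    center: float = 125.0
    hold_at_extremes: float = 0.0
    duration: float = 10.0
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.peak_to_peak < 0:
            raise ValueError("peak_to_peak must be >= 0")
        if self.hold_at_extremes < 0:
            raise ValueError("hold_at_extremes must be >= 0")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")


def ramp_and_hold(p: RampHoldProtocol) -> StretchInput:
    """Sampled ramp-and-hold stretch with its exact piecewise derivative.

    The velocity samples at the phase boundaries are assigned to the
    starting phase of the half-open interval, which makes the trapezoidal
    integral of the velocity close on the total length change exactly.
    """
    d1, d2, d3 = p.phase_durations
    total = d1 + d2 + d3
    n = int(round(total / p.dt)) + 1
    t = np.arange(n) * p.dt
    v = p.effective_speed
    in_ramp_v = (t >= d1 - 1e-12) & (t < d1 + d2 - 1e-12)
    velocity = np.where(in_ramp_v, v, 0.0)
    length = np.where(
        t < d1 - 1e-12,
        p.l_start,
        np.where(
            t <= d1 + d2 + 1e-12,
            p.l_start + v * (t - d1),
            p.l_end,
        ),
    )
    return StretchInput(times=t, length=length, velocity=velocity)


def sinusoid_joint(p: SinusoidProtocol) -> JointTrajectory:
    """Sinusoidal joint trajectory in radians, dwelling at the extremes.

    The wall-clock time is mapped onto a "motion time" that pauses whenever
    the sine sits at an extreme; the angular velocity is the exact chain
    rule derivative (zero during dwells, continuous at dwell boundaries
    since cos vanishes at the extremes).
    """
    n = int(round(p.duration / p.dt)) + 1
    t = np.arange(n) * p.dt
    amp = math.radians(p.peak_to_peak / 2.0)
    center = math.radians(p.center)
    base_t = 1.0 / p.frequency
    h = p.hold_at_extremes
    period = base_t + 2.0 * h
    tc = np.mod(t, period)
    # segments of one cycle: rise T/4 | dwell h | fall T/2 | dwell h | rise T/4
    s = np.empty_like(tc)
    moving = np.ones_like(tc, dtype=bool)
    seg1 = tc < base_t / 4.0
    seg2 = (~seg1) & (tc < base_t / 4.0 + h)
    seg3 = (~seg1) & (~seg2) & (tc < 3.0 * base_t / 4.0 + h)
    seg4 = (~seg1) & (~seg2) & (~seg3) & (tc < 3.0 * base_t / 4.0 + 2.0 * h)
    seg5 = (~seg1) & (~seg2) & (~seg3) & (~seg4)
    s[seg1] = tc[seg1]
    s[seg2] = base_t / 4.0
    moving[seg2] = False
    s[seg3] = tc[seg3] - h
    s[seg4] = 3.0 * base_t / 4.0
    moving[seg4] = False
    s[seg5] = tc[seg5] - 2.0 * h
    omega = 2.0 * math.pi * p.frequency
    theta = center + amp * np.sin(omega * s)
    theta_dot = amp * omega * np.cos(omega * s) * moving
    return JointTrajectory(times=t, theta=theta, theta_dot=theta_dot)


def regular_spike_train(rate: float, duration: float, unit_id: int = 0) -> SpikeTrain:
    """Spikes at fixed intervals: events at k/rate, k = 1..floor(duration*rate)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    n = int(math.floor(duration * rate + 1e-9)) if rate > 0 else 0
    times = np.arange(1, n + 1) / rate if n else np.empty(0)
    times = np.minimum(times, duration)
    return SpikeTrain(
        times=times, unit_ids=np.full(times.size, unit_id, dtype=int),
        duration=duration,
    )


def poisson_spike_train(
    rate: float, duration: float, seed, unit_id: int = 0
) -> SpikeTrain:
    """Homogeneous Poisson spikes via cumulative exponential intervals."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return SpikeTrain(
            times=np.empty(0), unit_ids=np.empty(0, dtype=int), duration=duration
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # draw enough intervals in one go, then trim to the duration
    n_guess = max(16, int(rate * duration * 1.5 + 10 * math.sqrt(rate * duration)))
    times = np.cumsum(rng.exponential(1.0 / rate, size=n_guess))
    while times.size and times[-1] < duration:
        extra = np.cumsum(rng.exponential(1.0 / rate, size=n_guess)) + times[-1]
        times = np.concatenate([times, extra])
    times = times[times < duration]
    return SpikeTrain(
        times=times, unit_ids=np.full(times.size, unit_id, dtype=int),
        duration=duration,
    )
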