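"""Intrafusal fiber mechanics and per-fiber afferent rate contributions.

A muscle spindle contains three kinds of intrafusal fibers (bag1, bag2,
chain).  Each fiber is modelled as a sensory region (SR, a pure spring) in
series with a polar region (PR, a spring in parallel with an
activation-dependent damped contractile element).  Because the two regions
carry the same tension ``T``, eliminating the polar-region length yields a
single first-order ODE for ``T`` driven by fascicle length ``L``, stretch
velocity ``Ldot`` (both in units of the rest fascicle length L0) and the
fusimotor activations ``f_dynamic``, ``f_static``.  The polar-region force
balance is

    T = beta*C*(L_PR - R)*signpow(Ldot_PR, a) + K_PR*(L_PR - L0_PR) + Gamma

with damping exponent ``a`` (<= 1), so solving for the polar-region stretch
speed and using ``Tdot = K_SR*(Ldot - Ldot_PR)`` gives

    Tdot = K_SR * ( Ldot - signpow( (T - K_PR*(L_PR - L0_PR) - Gamma)
                                    / (beta * C * (L_PR - R)),  1/a ) )

with ``L_PR = L - L0_SR - T/K_SR`` (instantaneous sensory-region
equilibrium), damping ``beta`` and active force ``Gamma`` linear in the
fusimotor activations, and ``signpow(x, p) = sign(x)*|x|**p``.  Note the
reciprocal exponent: it is what makes the ramp response strongly
velocity-sensitive and scale the damping force as |Ldot|^a.  The fiber's
contribution to the afferent rates is then an affine function of ``T`` (and,
for bag2/chain, of ``L``).

Accelerations are not an input: the model is the first-order reduction in
which the ``Lddot`` term of the original intrafusal model is dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FiberParameters",
    "FiberState",
    "StretchInput",
    "DegenerateDenominatorWarning",
    "signpow",
    "fusimotor_coefficients",
    "tension_derivative",
    "step_fiber",
    "passive_equilibrium_tension",
    "bag1_rate",
    "bag2_chain_rate",
]

#: |L_PR - R| below this (L0 units) counts as a degenerate denominator.
DENOMINATOR_EPS = 1e-9


class DegenerateDenominatorWarning(RuntimeWarning):
    """Polar-region length hit the damping pole ``L_PR = R``."""


@dataclass(frozen=True)
class FiberParameters:
    """Physiological constants of one intrafusal fiber type.

    Stiffnesses are in force units per L0, lengths in L0 units, gains in
    spikes/s per L0 of sensory-zone stretch beyond threshold.  ``a_exp`` is
    the velocity-power exponent of the damped contractile element and
    ``c_damp`` its damping constant.  ``x_frac`` mixes the sensory-zone and
    polar-zone terms of the secondary contribution; ``l_secondary`` is the
    secondary sensory-zone length.
    """

    k_sr: float
    k_pr: float
    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    c_damp: float = 1.0
    r_thresh: float = 0.46
    a_exp: float = 0.3
    l0_sr: float = 0.04
    l0_pr: float = 0.76
    ln_sr: float = 0.0423
    ln_pr: float = 0.89
    g_gain: float = 1.0
    x_frac: float = 1.0
    l_secondary: float = 0.04
    fiber_kind: str = "bag1"

    def __post_init__(self) -> None:
        if not self.k_sr > 0:
            raise ValueError(f"k_sr must be > 0, got {self.k_sr}")
        if not self.k_pr > 0:
            raise ValueError(f"k_pr must be > 0, got {self.k_pr}")
        if not 0.0 <= self.x_frac <= 1.0:
            raise ValueError(f"x_frac must be in [0, 1], got {self.x_frac}")
        if not 0.0 < self.a_exp <= 1.0:
            raise ValueError(f"a_exp must be in (0, 1], got {self.a_exp}")
        if self.g_gain < 0:
            raise ValueError(f"g_gain must be >= 0, got {self.g_gain}")
        if not self.l_secondary > 0:
            raise ValueError(f"l_secondary must be > 0, got {self.l_secondary}")
        if self.fiber_kind not in ("bag1", "bag2", "chain"):
            raise ValueError(f"unknown fiber_kind {self.fiber_kind!r}")


@dataclass
class FiberState:
    """Current total tension of one fiber (force units) and simulation time."""

    tension: float
    time: float = 0.0


@dataclass
class StretchInput:
    """Uniformly sampled fascicle stretch trajectory.

    ``length`` is L(t) in units of the rest fascicle length L0 and
    ``velocity`` is Ldot(t) in L0/s.
    """

    times: np.ndarray
    length: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not (self.times.shape == self.length.shape == self.velocity.shape):
            raise ValueError("times, length and velocity must have equal shapes")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times must be uniformly sampled")
        if np.any(self.length <= 0):
            raise ValueError("length must be positive")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two samples to define dt")
        return float(self.times[1] - self.times[0])


def signpow(x: float, a: float) -> float:
    """Odd power ``sign(x) * |x|**a`` (defined for all real x; 0**a = 0)."""
    if a <= 0:
        raise ValueError(f"exponent must be positive, got {a}")
    return math.copysign(abs(x) ** a, x) if x != 0 else 0.0


def fusimotor_coefficients(
    p: FiberParameters, f_dyn: float, f_stat: float
) -> tuple[float, float]:
    """Damping ``beta`` and active force ``Gamma`` at the given activations.

    beta  = beta0 + beta1*f_dynamic + beta2*f_static
    Gamma = gamma1*f_dynamic + gamma2*f_static
    """
    if not 0.0 <= f_dyn <= 1.0:
        raise ValueError(f"f_dyn must be in [0, 1], got {f_dyn}")
    if not 0.0 <= f_stat <= 1.0:
        raise ValueError(f"f_stat must be in [0, 1], got {f_stat}")
    beta = p.beta0 + p.beta1 * f_dyn + p.beta2 * f_stat
    gamma_force = p.gamma1 * f_dyn + p.gamma2 * f_stat
    return beta, gamma_force


def _tension_rate(
    tension: float,
    p: FiberParameters,
    length: float,
    velocity: float,
    beta: float,
    gamma_force: float,
) -> float:
    """Right-hand side of the tension ODE at known (beta, Gamma)."""
    if beta <= 0:
        raise ValueError(f"damping beta must be positive, got {beta}")
    l_pr = length - p.l0_sr - tension / p.k_sr
    numerator = tension - p.k_pr * (l_pr - p.l0_pr) - gamma_force
    den_core = l_pr - p.r_thresh
    if abs(den_core) < DENOMINATOR_EPS:
        warnings.warn(
            f"polar-region length {l_pr:.3g} within {DENOMINATOR_EPS:g} of the "
            f"damping pole R={p.r_thresh:.3g}; clamping",
            DegenerateDenominatorWarning,
            stacklevel=3,
        )
        den_core = math.copysign(DENOMINATOR_EPS, den_core if den_core != 0 else 1.0)
    arg = numerator / (beta * p.c_damp * den_core)
    return p.k_sr * (velocity - signpow(arg, 1.0 / p.a_exp))


def tension_derivative(
    s: FiberState,
    p: FiberParameters,
    L: float,
    Ldot: float,
    f_dyn: float = 0.0,
    f_stat: float = 0.0,
) -> float:
    """Instantaneous tension rate ``Tdot`` (force/s) of one fiber."""
    beta, gamma_force = fusimotor_coefficients(p, f_dyn, f_stat)
    return _tension_rate(s.tension, p, L, Ldot, beta, gamma_force)


def step_fiber(
    s: FiberState,
    p: FiberParameters,
    L: float,
    Ldot: float,
    f_dyn: float,
    f_stat: float,
    dt: float,
    n_substeps: int = 10,
) -> FiberState:
    """Advance the fiber tension by ``dt`` with forward Euler.

    The external step is subdivided into ``n_substeps`` internal Euler steps
    (inputs held constant) for accuracy; ``n_substeps = 0`` is the identity.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if n_substeps < 0:
        raise ValueError("n_substeps must be >= 0")
    if n_substeps == 0:
        return replace(s)
    beta, gamma_force = fusimotor_coefficients(p, f_dyn, f_stat)
    h = dt / n_substeps
    tension = s.tension
    for _ in range(n_substeps):
        tension += h * _tension_rate(tension, p, L, Ldot, beta, gamma_force)
    if not math.isfinite(tension):
        raise FloatingPointError(
            f"non-finite fiber tension at t={s.time + dt:.6f} s (L={L}, Ldot={Ldot})"
        )
    return FiberState(tension=tension, time=s.time + dt)


def passive_equilibrium_tension(
    p: FiberParameters, L: float, gamma_force: float = 0.0
) -> float:
    """Stationary tension ``T*`` at constant length (Ldot = 0).

    Setting the contractile-element numerator to zero gives the polar-region
    length ``L_PR* = (K_SR*(L - L0_SR) + K_PR*L0_PR - Gamma)/(K_SR + K_PR)``
    and ``T* = K_SR*(L - L_PR* - L0_SR)``.  ``tension_derivative`` vanishes
    there.
    """
    l_pr_star = (p.k_sr * (L - p.l0_sr) + p.k_pr * p.l0_pr - gamma_force) / (
        p.k_sr + p.k_pr
    )
    return p.k_sr * (L - l_pr_star - p.l0_sr)


def bag1_rate(T: float, p: FiberParameters) -> float:
    """Bag1 contribution to the primary rate: ``G*(T/K_SR - (LN_SR - L0_SR))``.

    May be negative below the sensory-zone threshold; clamping to zero is the
    caller's responsibility (done when assembling afferent rates).
    """
    return p.g_gain * (T / p.k_sr - (p.ln_sr - p.l0_sr))


def bag2_chain_rate(T: float, L: float, p: FiberParameters) -> float:
    """Bag2/chain contribution, mixing sensory- and polar-zone stretch.

    ``G * { X*(Lsec/L0_SR)*[T/K_SR - (LN_SR - L0_SR)]
          + (1-X)*(Lsec/L0_PR)*[L - T/K_SR - L0_SR - LN_PR] }``

    The polar-zone term is normalized by the polar rest length L0_PR, which
    keeps secondary rates in the physiological range and makes the rate
    vanish for contracted fibers, as required of the intrafusal model this
    implements.
    """
    sensory = (p.l_secondary / p.l0_sr) * (T / p.k_sr - (p.ln_sr - p.l0_sr))
    polar = (p.l_secondary / p.l0_pr) * (L - T / p.k_sr - p.l0_sr - p.ln_pr)
    return p.g_gain * (p.x_frac * sensory + (1.0 - p.x_frac) * polar)
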