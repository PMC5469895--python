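"""Assembly of Ia/II afferent rates and stochastic spike-train output.

The secondary (II) rate is the direct sum of the bag2 and chain
contributions.  The primary (Ia) rate combines bag1 with the secondary sum
through partial occlusion: the larger contribution passes in full, the
smaller is scaled by the occlusion weight S,

    rate_Ia = bag1 + S*II   if bag1 > II   else   II + S*bag1

Both rates are clamped at zero before spike generation, since they drive
inhomogeneous Poisson processes.  Two spike-generation routes are provided:
a per-step Bernoulli approximation (P{spike in step} = rate*dt, the natural
choice at a fixed 1 ms step) and exponential inter-spike-interval sampling
with thinning; they are statistically equivalent as dt -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fusimotor import FusimotorIntegrator, SpikeTrain, chain_activation, step_activation
from .model_core import (
    FiberState,
    StretchInput,
    bag1_rate,
    bag2_chain_rate,
    fusimotor_coefficients,
    passive_equilibrium_tension,
    step_fiber,
)
from .params import SpindleParameters

__all__ = [
    "SpindleState",
    "PopulationConfig",
    "initial_spindle_state",
    "secondary_rate",
    "primary_rate",
    "spindle_step",
    "simulate_rates",
    "generate_spikes_bernoulli",
    "generate_spikes_isi",
    "simulate_population",
]


@dataclass
class SpindleState:
    """Tensions of the three fibers plus the two fusimotor integrators."""

    bag1: FiberState
    bag2: FiberState
    chain: FiberState
    f_dyn: FusimotorIntegrator
    f_stat: FusimotorIntegrator
    s_occl: float = 0.156


@dataclass
class PopulationConfig:
    """Spindle population layout and reproducibility settings.

    Units ``0 .. n_primary-1`` emit Ia spikes, the remainder II spikes
    (``n_primary = round(n_units*primary_fraction)``).  With
    ``shared_tension`` the fiber tensions are computed once for the whole
    population (all spindles of one muscle receive the same fusimotor
    stimulation) and each unit only draws its own spikes.
    """

    n_units: int = 200
    primary_fraction: float = 0.5
    shared_tension: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not 0.0 <= self.primary_fraction <= 1.0:
            raise ValueError("primary_fraction must be in [0, 1]")

    @property
    def n_primary(self) -> int:
        return int(round(self.n_units * self.primary_fraction))


def initial_spindle_state(
    params: SpindleParameters, L0: float, time: float = 0.0
) -> SpindleState:
    """Rest state: zero activations, tensions at the passive equilibrium.

    Starting on the equilibrium manifold avoids the startup transient a cold
    (zero-tension) start would inject into the first few hundred ms.
    """
    def eq(p):  # Gamma = 0 at zero activation
        return FiberState(tension=passive_equilibrium_tension(p, L0), time=time)

    return SpindleState(
        bag1=eq(params.bag1),
        bag2=eq(params.bag2),
        chain=eq(params.chain),
        f_dyn=FusimotorIntegrator(
            r_imp=params.r_dynamic, tau_ms=params.tau_dynamic_ms,
            chain_scale=params.chain_scale,
        ),
        f_stat=FusimotorIntegrator(
            r_imp=params.r_static, tau_ms=params.tau_static_ms,
            chain_scale=params.chain_scale,
        ),
        s_occl=params.s_occl,
    )


def secondary_rate(bag2_contrib: float, chain_contrib: float) -> float:
    """Secondary (II) rate: direct sum of bag2 and chain contributions."""
    return bag2_contrib + chain_contrib


def primary_rate(bag1_contrib: float, rate_ii: float, s_occl: float) -> float:
    """Primary (Ia) rate with partial occlusion between bag1 and the II sum.

    Continuous at bag1 == II (both branches give (1+S)*value) and never
    below the II rate when both inputs are non-negative.
    """
    if not 0.0 <= s_occl <= 1.0:
        raise ValueError(f"s_occl must be in [0, 1], got {s_occl}")
    if bag1_contrib > rate_ii:
        return bag1_contrib + s_occl * rate_ii
    return rate_ii + s_occl * bag1_contrib


def spindle_step(
    state: SpindleState,
    params: SpindleParameters,
    L: float,
    Ldot: float,
    dyn_spikes: int,
    stat_spikes: int,
    dt: float,
    n_substeps: int = 10,
) -> tuple[SpindleState, float, float]:
    """One fixed step of the whole spindle; returns (state, rate_Ia, rate_II).

    Order within the step: integrate the fusimotor spikes (dynamic acts on
    bag1 only; static on bag2 and, scaled, on chain), advance the three fiber
    tensions with the new activations, evaluate the per-fiber contributions
    and combine them.  Both output rates are clamped at zero.
    """
    f_dyn = step_activation(state.f_dyn, dyn_spikes, dt)
    f_stat = step_activation(state.f_stat, stat_spikes, dt)
    f_chain = chain_activation(f_stat.f, f_stat.chain_scale)

    bag1 = step_fiber(state.bag1, params.bag1, L, Ldot, f_dyn.f, 0.0, dt, n_substeps)
    bag2 = step_fiber(state.bag2, params.bag2, L, Ldot, 0.0, f_stat.f, dt, n_substeps)
    chain = step_fiber(state.chain, params.chain, L, Ldot, 0.0, f_chain, dt, n_substeps)

    r_bag1 = bag1_rate(bag1.tension, params.bag1)
    r_ii = secondary_rate(
        bag2_chain_rate(bag2.tension, L, params.bag2),
        bag2_chain_rate(chain.tension, L, params.chain),
    )
    r_ia = primary_rate(r_bag1, r_ii, state.s_occl)
    new_state = SpindleState(
        bag1=bag1, bag2=bag2, chain=chain,
        f_dyn=f_dyn, f_stat=f_stat, s_occl=state.s_occl,
    )
    return new_state, max(r_ia, 0.0), max(r_ii, 0.0)


def simulate_rates(
    params: SpindleParameters,
    stretch: StretchInput,
    dyn_train: SpikeTrain | None = None,
    stat_train: SpikeTrain | None = None,
    n_substeps: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Ia and II rate traces for one spindle along a stretch trajectory."""
    dt = stretch.dt
    n_steps = stretch.times.size
    dyn_counts = (
        dyn_train.counts_per_step(dt, n_steps)
        if dyn_train is not None else np.zeros(n_steps, dtype=int)
    )
    stat_counts = (
        stat_train.counts_per_step(dt, n_steps)
        if stat_train is not None else np.zeros(n_steps, dtype=int)
    )
    state = initial_spindle_state(params, float(stretch.length[0]))
    rate_ia = np.empty(n_steps)
    rate_ii = np.empty(n_steps)
    for i in range(n_steps):
        state, ia, ii = spindle_step(
            state, params,
            float(stretch.length[i]), float(stretch.velocity[i]),
            int(dyn_counts[i]), int(stat_counts[i]), dt, n_substeps,
        )
        rate_ia[i] = ia
        rate_ii[i] = ii
    return rate_ia, rate_ii


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_spikes_bernoulli(
    rate_trace: np.ndarray, dt: float, rng_seed, unit_id: int = 0
) -> SpikeTrain:
    """Per-step Bernoulli spikes: P{spike in step i} = rate_i * dt.

    Probabilities are clamped to [0, 1]; spikes are stamped at step centers.
    """
    rng = _as_rng(rng_seed)
    rate = np.asarray(rate_trace, dtype=float)
    p = np.clip(rate * dt, 0.0, 1.0)
    hits = np.nonzero(rng.random(rate.size) < p)[0]
    times = (hits + 0.5) * dt
    return SpikeTrain(
        times=times, unit_ids=np.full(times.size, unit_id), duration=rate.size * dt
    )


def generate_spikes_isi(
    rate_trace: np.ndarray, dt: float, rng_seed, unit_id: int = 0
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes by exponential ISI draws with thinning.

    Candidate events are drawn at the peak rate and accepted with
    probability rate(t)/rate_max against the piecewise-constant trace.
    """
    rng = _as_rng(rng_seed)
    rate = np.asarray(rate_trace, dtype=float)
    duration = rate.size * dt
    rate_max = float(rate.max(initial=0.0))
    if rate_max <= 0.0:
        return SpikeTrain(
            times=np.empty(0), unit_ids=np.empty(0, dtype=int), duration=duration
        )
    times = []
    t = rng.exponential(1.0 / rate_max)
    while t < duration:
        idx = min(int(t / dt), rate.size - 1)
        if rng.random() < rate[idx] / rate_max:
            times.append(t)
        t += rng.exponential(1.0 / rate_max)
    times = np.asarray(times)
    return SpikeTrain(
        times=times, unit_ids=np.full(times.size, unit_id), duration=duration
    )


def simulate_population(
    cfg: PopulationConfig,
    stretch: StretchInput,
    dyn_train: SpikeTrain | None,
    stat_train: SpikeTrain | None,
    params: SpindleParameters,
    n_substeps: int = 10,
    method: str = "bernoulli",
) -> tuple[SpikeTrain, np.ndarray, np.ndarray]:
    """Spike trains of a spindle population; returns (train, rate_Ia, rate_II).

    With ``shared_tension`` the rate traces are computed once and every unit
    draws independent spikes from the Ia or II trace according to its
    primary/secondary flag.  Per-unit RNG streams are spawned from the
    population seed, so unit i's spikes do not depend on how many other
    units exist.
    """
    if method not in ("bernoulli", "isi"):
        raise ValueError(f"unknown spike generation method {method!r}")
    gen = generate_spikes_bernoulli if method == "bernoulli" else generate_spikes_isi
    shared_ia, shared_ii = (
        simulate_rates(params, stretch, dyn_train, stat_train, n_substeps)
        if cfg.shared_tension else (None, None)
    )
    dt = stretch.dt
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_units)
    all_times, all_ids = [], []
    rate_ia = shared_ia
    rate_ii = shared_ii
    for unit in range(cfg.n_units):
        if cfg.shared_tension:
            ia, ii = shared_ia, shared_ii
        else:
            ia, ii = simulate_rates(params, stretch, dyn_train, stat_train, n_substeps)
            if rate_ia is None:
                rate_ia, rate_ii = ia, ii
        trace = ia if unit < cfg.n_primary else ii
        train = gen(trace, dt, np.random.default_rng(streams[unit]), unit_id=unit)
        all_times.append(train.times)
        all_ids.append(train.unit_ids)
    times = np.concatenate(all_times) if all_times else np.empty(0)
    ids = np.concatenate(all_ids) if all_ids else np.empty(0, dtype=int)
    order = np.argsort(times, kind="stable")
    duration = stretch.times.size * dt
    merged = SpikeTrain(times=times[order], unit_ids=ids[order], duration=duration)
    return merged, rate_ia, rate_ii
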