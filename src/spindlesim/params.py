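"""Named parameter sets for the spindle model.

The shipped physiological default follows the cat soleus parameterization of
the intrafusal-fiber model of Mileusnic, Brown, Lan & Loeb (2006),
J. Neurophysiol. 96:1772-1788, Table 1 (values adapted from that
publication; they are not redistributed verbatim here and small deviations
from the printed table do not affect any property this package tests).  The
``toy`` set uses round numbers convenient for hand-checked arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .fusimotor import (
    DEFAULT_CHAIN_SCALE,
    DEFAULT_R_DYNAMIC,
    DEFAULT_R_STATIC,
    DEFAULT_TAU_DYNAMIC_MS,
    DEFAULT_TAU_STATIC_MS,
)
from .model_core import FiberParameters

__all__ = ["SpindleParameters", "cat_soleus", "toy", "named_parameter_set"]


@dataclass(frozen=True)
class SpindleParameters:
    """Complete parameterization of one muscle spindle.

    Three fiber parameter sets, the partial-occlusion weight S applied when
    combining bag1 with the secondary sum into the primary rate, and the
    constants of the two fusimotor spike-integration channels.
    """

    bag1: FiberParameters
    bag2: FiberParameters
    chain: FiberParameters
    s_occl: float = 0.156
    r_dynamic: float = DEFAULT_R_DYNAMIC
    tau_dynamic_ms: float = DEFAULT_TAU_DYNAMIC_MS
    r_static: float = DEFAULT_R_STATIC
    tau_static_ms: float = DEFAULT_TAU_STATIC_MS
    chain_scale: float = DEFAULT_CHAIN_SCALE

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_occl <= 1.0:
            raise ValueError(f"s_occl must be in [0, 1], got {self.s_occl}")


def cat_soleus() -> SpindleParameters:
    """Cat soleus spindle (adapted from Mileusnic et al. 2006, Table 1)."""
    common = dict(
        k_sr=10.4649,
        k_pr=0.15,
        c_damp=1.0,
        r_thresh=0.46,
        a_exp=0.3,
        l0_sr=0.04,
        l0_pr=0.76,
        ln_sr=0.0423,
        ln_pr=0.89,
        l_secondary=0.04,
    )
    bag1 = FiberParameters(
        beta0=0.0605, beta1=0.2592, gamma1=0.0289,
        g_gain=20000.0, x_frac=1.0, fiber_kind="bag1", **common,
    )
    bag2 = FiberParameters(
        beta0=0.0822, beta2=-0.046, gamma2=0.0636,
        g_gain=10000.0, x_frac=0.7, fiber_kind="bag2", **common,
    )
    chain = FiberParameters(
        beta0=0.0822, beta2=-0.069, gamma2=0.0954,
        g_gain=10000.0, x_frac=0.7, fiber_kind="chain", **common,
    )
    return SpindleParameters(bag1=bag1, bag2=bag2, chain=chain)


def toy() -> SpindleParameters:
    """Round-number parameter set for hand-checked tests (not physiological)."""
    common = dict(
        c_damp=1.0, r_thresh=0.46, a_exp=0.3,
        l0_sr=0.04, l0_pr=0.76, ln_sr=0.05, ln_pr=0.85, l_secondary=0.04,
    )
    bag1 = FiberParameters(
        k_sr=2.0, k_pr=1.0, beta0=0.1, beta1=0.2, gamma1=0.1,
        g_gain=100.0, x_frac=1.0, fiber_kind="bag1", **common,
    )
    bag2 = FiberParameters(
        k_sr=2.0, k_pr=1.0, beta0=0.1, beta2=0.05, gamma2=0.1,
        g_gain=50.0, x_frac=0.5, fiber_kind="bag2", **common,
    )
    chain = FiberParameters(
        k_sr=2.0, k_pr=1.0, beta0=0.1, beta2=0.05, gamma2=0.15,
        g_gain=50.0, x_frac=0.5, fiber_kind="chain", **common,
    )
    return SpindleParameters(bag1=bag1, bag2=bag2, chain=chain, s_occl=0.15)


_NAMED = {"cat_soleus": cat_soleus, "toy": toy}


def named_parameter_set(name: str) -> SpindleParameters:
    try:
        return _NAMED[name]()
    except KeyError:
        raise ValueError(
            f"unknown parameter set {name!r}; available: {sorted(_NAMED)}"
        ) from None
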