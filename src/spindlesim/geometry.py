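"""Joint-angle to muscle-length translation for two- and three-link chains.

Motor encoders report joint angles, while the spindle model wants fascicle
length and stretch speed in rest-length units.  For a hinge joint actuated
by an agonist/antagonist muscle pair attached at the midpoints of the two
links, the law of cosines gives the muscle length as a function of the
joint angle; its exact time derivative gives the stretch speed.  A
symmetric three-link chain (e.g. shoulder-neck-head) with a fixed angle
between the first two links reduces to the same construction with an
effective first side ``a`` and offset angle ``beta``.

All angles are in radians; lengths are in the link units and are normalized
to L0 = length at the rest angle by :func:`normalize_to_rest`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import StretchInput

__all__ = [
    "GeometryError",
    "TwoLinkGeometry",
    "ThreeLinkGeometry",
    "JointTrajectory",
    "two_link_lengths",
    "three_link_length",
    "normalize_to_rest",
]


class GeometryError(ValueError):
    """Degenerate kinematic configuration (zero length, invalid arccos)."""


@dataclass(frozen=True)
class TwoLinkGeometry:
    """Agonist/antagonist pair on a two-link hinge (e.g. arm-forearm).

    The agonist spans the midpoints of the links; the antagonist length
    depends on the attachment parameter ``s_attach`` (an opaque constant of
    the antagonist routing with units of length squared).
    """

    l1: float
    l2: float
    s_attach: float
    theta_rest: float

    def __post_init__(self) -> None:
        if self.l1 <= 0 or self.l2 <= 0:
            raise ValueError("link lengths must be positive")


@dataclass(frozen=True)
class ThreeLinkGeometry:
    """Muscle spanning the midpoints of links 1 and 3 of a symmetric chain.

    ``alpha`` is the fixed angle between the first two links; the actuated
    joint is between links 2 and 3.
    """

    l1: float
    l2: float
    l3: float
    alpha: float
    theta_rest: float

    def __post_init__(self) -> None:
        if min(self.l1, self.l2, self.l3) <= 0:
            raise ValueError("link lengths must be positive")

    @property
    def a_link(self) -> float:
        """Distance from the midpoint of link 1 to the actuated joint."""
        return math.sqrt(
            (self.l1 / 2.0) ** 2 + self.l2**2 - self.l1 * self.l2 * math.cos(self.alpha)
        )

    @property
    def beta_angle(self) -> float:
        """Angle between ``a_link`` and link 2 at the actuated joint."""
        a = self.a_link
        arg = (a**2 + self.l2**2 - (self.l1 / 2.0) ** 2) / (2.0 * a * self.l2)
        if not -1.0 <= arg <= 1.0:
            raise GeometryError(f"invalid arccos argument {arg:.6g}")
        return math.acos(arg)


@dataclass
class JointTrajectory:
    """Uniformly sampled joint trajectory (radians, radians/s)."""

    times: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.theta_dot = np.asarray(self.theta_dot, dtype=float)
        if not (self.times.shape == self.theta.shape == self.theta_dot.shape):
            raise ValueError("times, theta and theta_dot must have equal shapes")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times must be uniformly sampled")


def two_link_lengths(
    g: TwoLinkGeometry,
    theta,
    theta_dot,
    printed_antagonist_speed: bool = False,
):
    """Lengths and speeds of the agonist/antagonist pair at joint angle theta.

    Agonist (midpoint attachment on both links)::

        L_ago  = sqrt(l1^2/4 + l2^2/4 - (l1*l2/2)*cos(theta))
        Ldot_ago = (l1*l2/4)*sin(theta)*theta_dot / L_ago

    Antagonist::

        L_ant  = sqrt(l1^2 + l2^2 + 2*s*sin((pi - theta)/2))
        Ldot_ant = -s*cos((pi - theta)/2)*theta_dot / (2*L_ant)

    ``Ldot_ant`` is the exact time derivative of ``L_ant``.  The historical
    variant ``-2*s*cos((pi - theta)/2)*theta_dot`` (not a consistent
    derivative of the length expression) is available with
    ``printed_antagonist_speed=True`` for replication purposes.

    Returns ``(L_ago, Ldot_ago, L_ant, Ldot_ant)``; accepts scalars or
    arrays.  Raises :class:`GeometryError` when a length degenerates to 0.
    """
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    l_ago_sq = g.l1**2 / 4.0 + g.l2**2 / 4.0 - (g.l1 * g.l2 / 2.0) * np.cos(theta)
    if np.any(l_ago_sq <= 0):
        raise GeometryError("agonist length degenerates to zero")
    l_ago = np.sqrt(l_ago_sq)
    ldot_ago = (g.l1 * g.l2 / 4.0) * np.sin(theta) * theta_dot / l_ago

    half = (np.pi - theta) / 2.0
    l_ant_sq = g.l1**2 + g.l2**2 + 2.0 * g.s_attach * np.sin(half)
    if np.any(l_ant_sq <= 0):
        raise GeometryError("antagonist length degenerates to zero")
    l_ant = np.sqrt(l_ant_sq)
    if printed_antagonist_speed:
        ldot_ant = -2.0 * g.s_attach * np.cos(half) * theta_dot
    else:
        ldot_ant = -g.s_attach * np.cos(half) * theta_dot / (2.0 * l_ant)
    return l_ago, ldot_ago, l_ant, ldot_ant


def three_link_length(g: ThreeLinkGeometry, theta, theta_dot, side: str = "left"):
    """Length and speed of the three-link muscle; ``side='right'`` mirrors.

    With ``a`` and ``beta`` from the fixed part of the chain and
    ``phi = theta + pi/2 - beta``::

        L    = sqrt((l3/2)^2 + a^2 - a*l3*cos(phi))
        Ldot = (a*l3/2)*sin(phi)*theta_dot / L

    The symmetric chain's opposite-side muscle uses (-theta, -theta_dot).
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    if side == "right":
        theta, theta_dot = -theta, -theta_dot
    a = g.a_link
    beta = g.beta_angle
    phi = theta + np.pi / 2.0 - beta
    l_sq = (g.l3 / 2.0) ** 2 + a**2 - a * g.l3 * np.cos(phi)
    if np.any(l_sq <= 0):
        raise GeometryError("muscle length degenerates to zero")
    length = np.sqrt(l_sq)
    ldot = (a * g.l3 / 2.0) * np.sin(phi) * theta_dot / length
    return length, ldot


def _lengths_for(g, theta, theta_dot, muscle: str, side: str):
    if isinstance(g, TwoLinkGeometry):
        l_ago, ld_ago, l_ant, ld_ant = two_link_lengths(g, theta, theta_dot)
        if muscle == "agonist":
            return l_ago, ld_ago
        if muscle == "antagonist":
            return l_ant, ld_ant
        raise ValueError(f"muscle must be 'agonist' or 'antagonist', got {muscle!r}")
    if isinstance(g, ThreeLinkGeometry):
        return three_link_length(g, theta, theta_dot, side=side)
    raise TypeError(f"unsupported geometry {type(g).__name__}")


def normalize_to_rest(
    g,
    trajectory: JointTrajectory,
    muscle: str = "agonist",
    side: str = "left",
) -> StretchInput:
    """Muscle length/speed along a joint trajectory, in rest-length units.

    L0 is the muscle length at the geometry's rest angle; the output length
    is L/L0 and the velocity Ldot/L0, packaged as a :class:`StretchInput`
    ready to drive the spindle model.  Scaling every link length by a common
    factor leaves the output unchanged.
    """
    l0, _ = _lengths_for(g, g.theta_rest, 0.0, muscle, side)
    l0 = float(l0)
    if l0 <= 0:
        raise GeometryError("rest length L0 degenerates to zero")
    length, ldot = _lengths_for(g, trajectory.theta, trajectory.theta_dot, muscle, side)
    return StretchInput(
        times=trajectory.times, length=length / l0, velocity=ldot / l0
    )
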