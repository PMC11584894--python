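"""Ground-contact model: stance plans, friction pyramid, GRF priors.

Contact is modelled as a no-slip point foot: while a foot is in stance its
velocity is boxed within a slack ``eps`` (a decision variable penalised in
the cost), the vertical force stays positive, and the tangential force obeys
a linearised Coulomb cone (friction pyramid, mu = 1.3 by default).
Tangential components are decomposed into nonnegative (+, -) pairs so the
pyramid becomes linear.

The sinusoidal GRF prior synthesises the template profile used by the
sinusoidal estimation mode: vertical force is a half sine over the stance
whose amplitude comes from a linear model of peak force (in body weights)
against running speed, and the fore-aft force is a cubic spline through five
control points (zero at stance start/mid/end, a braking peak of half the
vertical amplitude and a propulsive peak of a quarter of it).  Lateral force
is identically zero for straight-line trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from kfte import multibody as _mb

__all__ = [
    "ContactPlan",
    "GRFProfile",
    "GRFSynthesisParams",
    "InvalidForceError",
    "InvalidParameterError",
    "synth_sinusoidal_grf",
    "friction_pyramid_residuals",
    "friction_pyramid",
    "no_slip_residual",
    "foot_velocity",
    "split_tangential",
    "recombine_tangential",
]

SPLIT_NAMES = ("fx_pos", "fx_neg", "fy_pos", "fy_neg", "fz")


class InvalidParameterError(ValueError):
    pass


class InvalidForceError(ValueError):
    pass


@dataclass
class ContactPlan:
    """Per-foot stance intervals plus contact-force variables.

    ``stance`` maps a foot marker name to half-open node intervals
    [start, end); ``forces`` (optional) holds per-node 5-component split
    forces (fx+, fx-, fy+, fy-, fz) in newtons; ``slip_slack`` holds the
    no-slip slack eps (m/s) per (foot, interval index).
    """

    stance: Mapping[str, Sequence[tuple]]
    mu: float = 1.3
    forces: dict = field(default_factory=dict)
    slip_slack: dict = field(default_factory=dict)

    def feet(self):
        return list(self.stance.keys())

    def stance_nodes(self, foot: str) -> np.ndarray:
        """All nodes in D for one foot (sorted, unique)."""
        nodes = []
        for a, b in self.stance[foot]:
            nodes.extend(range(int(a), int(b)))
        return np.array(sorted(set(nodes)), dtype=int)

    def in_stance(self, foot: str, node: int) -> bool:
        return any(a <= node < b for a, b in self.stance[foot])

    def to_dict(self) -> dict:
        return {foot: [[int(a), int(b)] for a, b in ivs] for foot, ivs in self.stance.items()}


@dataclass
class GRFProfile:
    """Time-sampled 3-component ground reaction force for one foot's stance."""

    forces: np.ndarray  # (n, 3) newtons at the trajectory timestep
    h: float  # s between samples
    foot: str = ""
    start_node: int = 0

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, float).reshape(-1, 3)

    @property
    def stance_duration(self) -> float:
        return (len(self.forces) - 1) * self.h

    @property
    def peak_vertical(self) -> float:
        return float(self.forces[:, 2].max(initial=0.0))

    def impulse(self) -> np.ndarray:
        """Time integral of the force over stance (trapezoidal), kg m/s."""
        return np.trapezoid(self.forces, dx=self.h, axis=0)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.forces, axis=1)


@dataclass
class GRFSynthesisParams:
    """Parameters of the sinusoidal GRF template.

    ``peak_intercept``/``peak_slope`` give the per-foot peak vertical force
    in body weights as intercept + slope * speed (m/s).  The defaults are
    impulse-consistent with a duty factor of 0.6 at the reference trotting
    speed of the bundled synthetic gait; real deployments should calibrate
    them against force-plate data for the species at hand.
    ``fx_peak_fractions`` place the braking/propulsive peaks within stance;
    ``band`` is the allowed fractional deviation of the estimated force from
    the template (20%).
    """

    peak_intercept: float = 0.45
    peak_slope: float = 0.1
    fx_peak_fractions: tuple = (0.25, 0.75)
    fx_peak_scales: tuple = (-0.5, 0.25)  # braking, propulsive, in units of A
    band: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.band < 1.0:
            raise InvalidParameterError("band fraction must be in [0, 1)")

    def peak_force(self, speed: float, body_mass: float, gravity: float = 9.81) -> float:
        """Peak vertical force A in newtons predicted by the linear model."""
        bw = self.peak_intercept + self.peak_slope * speed
        return bw * body_mass * gravity


def synth_sinusoidal_grf(
    params: GRFSynthesisParams,
    speed: float,
    body_mass: float,
    stance: tuple,
    h: float,
    foot: str = "",
    gravity: float = 9.81,
) -> GRFProfile:
    """Synthesise the template GRF for one stance.

    ``stance`` is a half-open node interval (start, end); samples are placed
    at nodes start .. end-1, so the stance spans T = (end - start - 1) * h
    seconds with F_z = A sin(pi t / T), zero at the first and last stance
    instants and A at the midpoint.  F_x is a natural cubic spline through
    five control points: zero at stance start, midpoint and end, -A/2 at the
    braking peak and +A/4 at the propulsive peak.  F_y is identically zero.
    """
    k0, k1 = int(stance[0]), int(stance[1])
    n = k1 - k0
    if n < 2:
        raise InvalidParameterError("stance interval must contain at least two nodes")
    if speed <= 0:
        raise InvalidParameterError("speed must be > 0")
    A = params.peak_force(speed, body_mass, gravity)
    if A <= 0:
        raise InvalidParameterError("predicted peak vertical force is non-positive")
    T = (n - 1) * h
    t = np.arange(n) * h
    fz = A * np.sin(np.pi * t / T)
    f1, f2 = params.fx_peak_fractions
    s1, s2 = params.fx_peak_scales
    ctrl_t = np.array([0.0, f1 * T, 0.5 * T, f2 * T, T])
    ctrl_v = np.array([0.0, s1 * A, 0.0, s2 * A, 0.0])
    fx = CubicSpline(ctrl_t, ctrl_v, bc_type="natural")(t)
    forces = np.column_stack([fx, np.zeros(n), fz])
    return GRFProfile(forces=forces, h=h, foot=foot, start_node=k0)


# ---------------------------------------------------------------------------
# friction pyramid


def friction_pyramid(lmbda_split, mu: float) -> np.ndarray:
    """Pyramid residuals (mu fz - (fx+ + fx-), mu fz - (fy+ + fy-)).

    ``lmbda_split`` is (..., 5) ordered (fx+, fx-, fy+, fy-, fz); all split
    components must be nonnegative.  Both residuals >= 0 iff the force is
    inside the linearised cone.
    """
    lam = np.asarray(lmbda_split, float)
    if lam.shape[-1] != 5:
        raise InvalidForceError("split force must have 5 components")
    if np.any(lam[..., :4] < 0):
        raise InvalidForceError("split tangential components must be nonnegative")
    rx = mu * lam[..., 4] - (lam[..., 0] + lam[..., 1])
    ry = mu * lam[..., 4] - (lam[..., 2] + lam[..., 3])
    return np.stack([rx, ry], axis=-1)


def friction_pyramid_residuals(plan: ContactPlan, foot: str, node: int) -> np.ndarray:
    """Pyramid residuals for one stance node of one foot from the plan's forces."""
    if not plan.in_stance(foot, node):
        raise InvalidParameterError(f"node {node} is not a stance node for foot {foot!r}")
    lam = np.asarray(plan.forces[foot])[node]
    return friction_pyramid(lam, plan.mu)


def split_tangential(force) -> np.ndarray:
    """Minimal (+,-) decomposition of a 3-vector force into 5 components."""
    f = np.asarray(force, float)
    return np.stack(
        [
            np.maximum(f[..., 0], 0.0),
            np.maximum(-f[..., 0], 0.0),
            np.maximum(f[..., 1], 0.0),
            np.maximum(-f[..., 1], 0.0),
            f[..., 2],
        ],
        axis=-1,
    )


def recombine_tangential(lmbda_split) -> np.ndarray:
    """(fx+ - fx-, fy+ - fy-, fz) from the 5-component split."""
    lam = np.asarray(lmbda_split)
    return np.stack(
        [lam[..., 0] - lam[..., 1], lam[..., 2] - lam[..., 3], lam[..., 4]], axis=-1
    )


# ---------------------------------------------------------------------------
# no-slip


def foot_velocity(model, q, dq, foot: str) -> np.ndarray:
    """World velocity of a foot marker, J_marker(q) @ qdot."""
    J = _mb.marker_jacobians(model, q)
    m = model.marker_index(foot)
    return np.einsum("...in,...n->...i", J[..., m, :, :], np.asarray(dq))


def no_slip_residual(model, q, dq, foot: str, eps: float = 0.0) -> float:
    """|v_foot| - eps; the no-slip constraint holds when this is <= 0.

    The optimiser enforces the equivalent componentwise box
    -eps <= v_foot <= eps; this scalar form is the diagnostic contract.
    """
    v = foot_velocity(model, q, dq, foot)
    return float(np.linalg.norm(np.atleast_1d(v)) - eps)
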