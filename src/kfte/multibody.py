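"""Rigid multi-body model of a quadruped in absolute angle coordinates.

Every link is a solid cylinder described by (length, mass, radius) whose
orientation is parameterised by its *own* world-frame intrinsic X-Y-Z Euler
angles; the generalized coordinate vector is

    q = [base position (3), link_0 angles (3), ..., link_{L-1} angles (3)]

so ``nq = 3 + 3 L`` (54 for the 17-link cheetah preset).  Because angles are
absolute, joints do not remove coordinates; instead explicit geometric
constraints (see :func:`joint_constraint_residuals`) forbid the disallowed
relative rotations and carry their own constraint torques in the equation of
motion

    M(q) qdd + C(q, qd) qd = G(q) + tau + J^T lambda .

All kinematic/dynamic functions broadcast over leading batch axes of ``q``
and are safe to evaluate with complex inputs, which the estimator exploits
for complex-step differentiation.

Conventions: world x is the direction of travel, z is up; the cylinder long
axis is a per-link local unit vector (default +x, legs typically -z so their
pitch angles stay far from the X-Y-Z gimbal singularity at +-pi/2); the link
frame sits at the proximal joint; gravity acts along -z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LinkSpec",
    "JointSpec",
    "MarkerSpec",
    "SkeletonModel",
    "GeneralizedState",
    "DynamicsTerms",
    "InvalidSpecError",
    "cylinder_inertia",
    "forward_kinematics",
    "marker_jacobians",
    "angular_velocity_map",
    "dynamics_terms",
    "inverse_dynamics",
    "net_wrench",
    "dynamics_residual",
    "joint_constraint_residuals",
    "joint_constraint_jacobian",
    "kinetic_energy",
    "potential_energy",
    "passive_acceleration",
]

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


class InvalidSpecError(ValueError):
    """Raised for physically meaningless model specifications."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class LinkSpec:
    """One cylindrical link.

    ``offset`` is the attachment point of this link's proximal joint in the
    *parent's* local frame; a scalar is interpreted as metres along the
    parent's long axis.  ``axis`` is the cylinder long axis in this link's
    local frame (unit vector).
    """

    name: str
    length: float
    mass: float
    radius: float = 0.0
    parent: str | None = None
    offset: float | Sequence[float] = 0.0
    axis: Sequence[float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidSpecError(f"link {self.name!r}: length must be > 0")
        if self.mass < 0 or self.radius < 0:
            raise InvalidSpecError(f"link {self.name!r}: mass/radius must be >= 0")


@dataclass(frozen=True)
class JointSpec:
    """Geometric joint between two links.

    kind: 'revolute' (rotation about the parent's y axis only, two scalar
    residuals), 'universal' (one residual, forbids rotation about the
    parent's z axis) or 'spherical' (no residuals).
    """

    kind: str
    link_i: str
    link_j: str

    def __post_init__(self) -> None:
        if self.kind not in ("revolute", "universal", "spherical"):
            raise InvalidSpecError(f"unknown joint kind {self.kind!r}")


@dataclass(frozen=True)
class MarkerSpec:
    name: str
    link: str
    offset: Sequence[float] = (0.0, 0.0, 0.0)


_JOINT_NRES = {"revolute": 2, "universal": 1, "spherical": 0}
_JOINT_NTAU = {"revolute": 1, "universal": 2, "spherical": 3}


class SkeletonModel:
    """Tree of cylinder links + joints + marker attachment map."""

    def __init__(
        self,
        links: Sequence[LinkSpec],
        joints: Sequence[JointSpec] = (),
        markers: Sequence[MarkerSpec] = (),
        gravity: float = 9.81,
    ) -> None:
        if not links:
            raise InvalidSpecError("model needs at least one link")
        self.links = list(links)
        self.joints = list(joints)
        self.markers = list(markers)
        self.gravity = float(gravity)

        self._index = {l.name: i for i, l in enumerate(self.links)}
        if len(self._index) != len(self.links):
            raise InvalidSpecError("duplicate link names")
        roots = [l for l in self.links if l.parent is None]
        if len(roots) != 1:
            raise InvalidSpecError("exactly one base link required")
        if self.links[0].parent is not None:
            raise InvalidSpecError("the first link must be the base link")
        self.parent_index = []
        for l in self.links:
            if l.parent is None:
                self.parent_index.append(-1)
            else:
                p = self._index.get(l.parent)
                if p is None:
                    raise InvalidSpecError(f"link {l.name!r}: unknown parent {l.parent!r}")
                if p >= self._index[l.name]:
                    raise InvalidSpecError("links must be ordered parents-first")
                self.parent_index.append(p)
        for j in self.joints:
            if j.link_i not in self._index or j.link_j not in self._index:
                raise InvalidSpecError(f"joint references unknown link: {j}")
        for m in self.markers:
            if m.link not in self._index:
                raise InvalidSpecError(f"marker {m.name!r} references unknown link {m.link!r}")
        self.marker_names = [m.name for m in self.markers]
        self._marker_index = {m.name: i for i, m in enumerate(self.markers)}

        # geometric constants
        axes = np.array([np.asarray(l.axis, float) for l in self.links])
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        self._axes = axes
        offs = []
        for l in self.links:
            if np.isscalar(l.offset):
                p = self.parent_index[self._index[l.name]]
                offs.append(float(l.offset) * (axes[p] if p >= 0 else _X))
            else:
                offs.append(np.asarray(l.offset, float))
        self._offsets = np.array(offs)  # in parent local frame
        self._coms = axes * np.array([l.length for l in self.links])[:, None] / 2.0
        self._masses = np.array([l.mass for l in self.links])
        self._inertias = np.array(
            [cylinder_inertia(l.mass, l.length, l.radius, axis=axes[i]) for i, l in enumerate(self.links)]
        )
        self._marker_link = np.array([self._index[m.link] for m in self.markers], dtype=int)
        self._marker_off = np.array([np.asarray(m.offset, float) for m in self.markers]).reshape(-1, 3)

    # -- size helpers ------------------------------------------------------
    @property
    def nlinks(self) -> int:
        return len(self.links)

    @property
    def nq(self) -> int:
        """State dimension: 3 base coordinates + 3 angles per link."""
        return 3 + 3 * self.nlinks

    @property
    def total_mass(self) -> float:
        return float(self._masses.sum())

    @property
    def n_joint_residuals(self) -> int:
        return sum(_JOINT_NRES[j.kind] for j in self.joints)

    @property
    def ntau(self) -> int:
        """Number of joint-torque degrees of freedom."""
        return sum(_JOINT_NTAU[j.kind] for j in self.joints)

    def link_index(self, name: str) -> int:
        return self._index[name]

    def marker_index(self, name: str) -> int:
        return self._marker_index[name]

    def angle_slice(self, link: int | str) -> slice:
        i = link if isinstance(link, int) else self._index[link]
        return slice(3 + 3 * i, 6 + 3 * i)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "links": [
                {
                    "name": l.name,
                    "parent": l.parent,
                    "length": l.length,
                    "mass": l.mass,
                    "radius": l.radius,
                    "offset": np.asarray(l.offset, float).tolist() if not np.isscalar(l.offset) else l.offset,
                    "axis": list(l.axis),
                }
                for l in self.links
            ],
            "joints": [{"kind": j.kind, "i": j.link_i, "j": j.link_j} for j in self.joints],
            "markers": [{"name": m.name, "link": m.link, "offset_xyz": list(m.offset)} for m in self.markers],
            "gravity": self.gravity,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SkeletonModel":
        links = [
            LinkSpec(
                name=ld["name"],
                parent=ld.get("parent"),
                length=ld["length"],
                mass=ld["mass"],
                radius=ld.get("radius", 0.0),
                offset=ld.get("offset", 0.0),
                axis=tuple(ld.get("axis", (1.0, 0.0, 0.0))),
            )
            for ld in d["links"]
        ]
        joints = [JointSpec(j["kind"], j["i"], j["j"]) for j in d.get("joints", ())]
        markers = [MarkerSpec(m["name"], m["link"], tuple(m["offset_xyz"])) for m in d.get("markers", ())]
        return cls(links, joints, markers, gravity=d.get("gravity", 9.81))


@dataclass
class GeneralizedState:
    """A (q, qd, qdd) triple; dimensions must match the model."""

    q: np.ndarray
    dq: np.ndarray
    ddq: np.ndarray


@dataclass
class DynamicsTerms:
    """Terms of the equation of motion M qdd + Cv = G + B tau + J^T lambda."""

    M: np.ndarray
    Cv: np.ndarray
    G: np.ndarray
    B: np.ndarray


# ---------------------------------------------------------------------------
# inertia


def cylinder_inertia(mass: float, length: float, radius: float, axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Body-frame inertia tensor of a solid cylinder about its COM.

    Transverse moments m (3 r^2 + L^2) / 12, axial moment m r^2 / 2, long
    axis along ``axis``.
    """
    if length <= 0:
        raise InvalidSpecError("cylinder length must be > 0")
    if mass < 0 or radius < 0:
        raise InvalidSpecError("mass and radius must be >= 0")
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    it = mass * (3.0 * radius**2 + length**2) / 12.0
    ia = mass * radius**2 / 2.0
    return it * (np.eye(3) - np.outer(a, a)) + ia * np.outer(a, a)


# ---------------------------------------------------------------------------
# rotation helpers (batched, complex-safe)


def _rot(axis: int, a, order: int = 0):
    """Rotation about a coordinate axis, or its 1st/2nd angle derivative."""
    a = np.asarray(a)
    c, s = np.cos(a), np.sin(a)
    if order == 1:
        c, s = -s, c
    elif order == 2:
        c, s = -c, -s
    z = np.zeros_like(c)
    e = np.ones_like(c) if order == 0 else z
    if axis == 0:
        rows = [[e, z, z], [z, c, -s], [z, s, c]]
    elif axis == 1:
        rows = [[c, z, s], [z, e, z], [-s, z, c]]
    else:
        rows = [[c, -s, z], [s, c, z], [z, z, e]]
    return np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)


def _euler_xyz(angles):
    """R = Rx(a) Ry(b) Rz(c) for angles (..., 3)."""
    a, b, c = angles[..., 0], angles[..., 1], angles[..., 2]
    return _rot(0, a) @ _rot(1, b) @ _rot(2, c)


def _euler_xyz_dangles(angles):
    """dR/d(angle_k), stacked as (..., 3, 3, 3) with k leading the 3x3."""
    a, b, c = angles[..., 0], angles[..., 1], angles[..., 2]
    Ra, Rb, Rc = _rot(0, a), _rot(1, b), _rot(2, c)
    Da, Db, Dc = _rot(0, a, 1), _rot(1, b, 1), _rot(2, c, 1)
    return np.stack([Da @ Rb @ Rc, Ra @ Db @ Rc, Ra @ Rb @ Dc], axis=-3)


def _euler_xyz_time_derivs(angles, rates, accs):
    """R, Rdot, Rddot for per-link Euler angles with given time derivatives."""
    a, b, c = angles[..., 0], angles[..., 1], angles[..., 2]
    da, db, dc = rates[..., 0], rates[..., 1], rates[..., 2]
    dda, ddb, ddc = accs[..., 0], accs[..., 1], accs[..., 2]
    F = [_rot(0, a), _rot(1, b), _rot(2, c)]
    D = [_rot(0, a, 1), _rot(1, b, 1), _rot(2, c, 1)]
    S = [_rot(0, a, 2), _rot(1, b, 2), _rot(2, c, 2)]
    r = [da, db, dc]
    w = [dda, ddb, ddc]
    R = F[0] @ F[1] @ F[2]

    def m(i, mats):
        return mats[0] @ mats[1] @ mats[2]

    Rd = sum(
        r[i][..., None, None] * m(i, [D[k] if k == i else F[k] for k in range(3)]) for i in range(3)
    )
    Rdd = sum(
        w[i][..., None, None] * m(i, [D[k] if k == i else F[k] for k in range(3)])
        + (r[i] ** 2)[..., None, None] * m(i, [S[k] if k == i else F[k] for k in range(3)])
        for i in range(3)
    )
    for i in range(3):
        for j in range(i + 1, 3):
            mats = [D[k] if k in (i, j) else F[k] for k in range(3)]
            Rdd = Rdd + 2.0 * (r[i] * r[j])[..., None, None] * m(0, mats)
    return R, Rd, Rdd


def angular_velocity_map(angles):
    """E(angles) with world angular velocity omega = E @ angle_rates.

    Columns are [x_hat, Rx(a) y_hat, Rx(a) Ry(b) z_hat] for intrinsic X-Y-Z
    angles.  Shape (..., 3, 3).
    """
    a, b = angles[..., 0], angles[..., 1]
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    one = np.ones_like(ca)
    zero = np.zeros_like(ca)
    col0 = np.stack([one, zero, zero], axis=-1)
    col1 = np.stack([zero, ca, sa], axis=-1)
    col2 = np.stack([sb, -sa * cb, ca * cb], axis=-1)
    return np.stack([col0, col1, col2], axis=-1)


def _vee(W):
    return np.stack([W[..., 2, 1], W[..., 0, 2], W[..., 1, 0]], axis=-1)


# ---------------------------------------------------------------------------
# forward kinematics


def _link_angles(model: SkeletonModel, q):
    q = np.asarray(q)
    return q[..., 3:].reshape(q.shape[:-1] + (model.nlinks, 3))


def _link_frames(model: SkeletonModel, q):
    """World rotation R (..., L, 3, 3) and origin o (..., L, 3) per link."""
    q = np.asarray(q)
    ang = _link_angles(model, q)
    R = _euler_xyz(ang)
    origins = [None] * model.nlinks
    origins[0] = q[..., 0:3]
    for i in range(1, model.nlinks):
        p = model.parent_index[i]
        origins[i] = origins[p] + (R[..., p, :, :] @ model._offsets[i]).reshape(origins[p].shape)
    o = np.stack(origins, axis=-2)
    return R, o


@dataclass
class ForwardKinematics:
    """World-frame link frames and marker positions for one (batch of) q."""

    link_rotations: np.ndarray  # (..., L, 3, 3)
    link_origins: np.ndarray  # (..., L, 3)
    markers: np.ndarray  # (..., M, 3)
    marker_names: list = field(default_factory=list)

    def marker(self, name: str, model: SkeletonModel | None = None) -> np.ndarray:
        return self.markers[..., self.marker_names.index(name), :]


def forward_kinematics(model: SkeletonModel, q) -> ForwardKinematics:
    """Positions of all markers and link frames in world coordinates."""
    q = np.asarray(q)
    if q.shape[-1] != model.nq:
        raise ValueError(f"q has dimension {q.shape[-1]}, model expects {model.nq}")
    R, o = _link_frames(model, q)
    if model.markers:
        Rm = R[..., model._marker_link, :, :]
        om = o[..., model._marker_link, :]
        markers = om + np.einsum("...ij,...j->...i", Rm, model._marker_off)
    else:
        markers = np.zeros(q.shape[:-1] + (0, 3), dtype=q.dtype)
    return ForwardKinematics(R, o, markers, list(model.marker_names))


def _point_jacobians(model: SkeletonModel, q):
    """d(link origin)/dq (..., L, 3, nq) and dR/dangles (..., L, 3, 3, 3)."""
    q = np.asarray(q)
    ang = _link_angles(model, q)
    dR = _euler_xyz_dangles(ang)  # (..., L, 3(k), 3, 3)
    batch = q.shape[:-1]
    P = np.zeros(batch + (model.nlinks, 3, model.nq), dtype=q.dtype)
    P[..., 0, :, 0:3] = np.eye(3)
    for i in range(1, model.nlinks):
        p = model.parent_index[i]
        P[..., i, :, :] = P[..., p, :, :]
        # parent rotation contributes through its own three angles
        cols = np.einsum("...kij,j->...ik", dR[..., p, :, :, :], model._offsets[i])
        P[..., i, :, 3 + 3 * p : 6 + 3 * p] += cols
    return P, dR


def marker_jacobians(model: SkeletonModel, q) -> np.ndarray:
    """d(marker position)/dq, shape (..., M, 3, nq)."""
    q = np.asarray(q)
    P, dR = _point_jacobians(model, q)
    J = P[..., model._marker_link, :, :].copy()
    for m, li in enumerate(model._marker_link):
        cols = np.einsum("...kij,j->...ik", dR[..., li, :, :, :], model._marker_off[m])
        J[..., m, :, 3 + 3 * li : 6 + 3 * li] += cols
    return J


def _com_jacobians(model: SkeletonModel, q):
    """COM position Jacobians (..., L, 3, nq) plus frames."""
    P, dR = _point_jacobians(model, q)
    J = P.copy()
    for i in range(model.nlinks):
        cols = np.einsum("...kij,j->...ik", dR[..., i, :, :, :], model._coms[i])
        J[..., i, :, 3 + 3 * i : 6 + 3 * i] += cols
    return J


# ---------------------------------------------------------------------------
# dynamics


def _omega_jacobians(model: SkeletonModel, q):
    """J_omega (..., L, 3, nq): world angular velocity = J_omega @ qdot."""
    q = np.asarray(q)
    ang = _link_angles(model, q)
    E = angular_velocity_map(ang)  # (..., L, 3, 3)
    batch = q.shape[:-1]
    Jw = np.zeros(batch + (model.nlinks, 3, model.nq), dtype=q.dtype)
    for i in range(model.nlinks):
        Jw[..., i, :, 3 + 3 * i : 6 + 3 * i] = E[..., i, :, :]
    return Jw


def inverse_dynamics(model: SkeletonModel, q, dq, ddq) -> np.ndarray:
    """Generalized force M qdd + C qd - G required by the motion (no inputs).

    Newton-Euler of each cylinder projected through its COM and angular
    Jacobians; gravity included.  Broadcasts and accepts complex input.
    """
    q, dq, ddq = np.broadcast_arrays(np.asarray(q), np.asarray(dq), np.asarray(ddq))
    ang = _link_angles(model, q)
    rates = _link_angles(model, dq)
    accs = _link_angles(model, ddq)
    R, Rd, Rdd = _euler_xyz_time_derivs(ang, rates, accs)

    # chain positions / velocities / accelerations of link origins
    o = [None] * model.nlinks
    vo = [None] * model.nlinks
    ao = [None] * model.nlinks
    o[0], vo[0], ao[0] = q[..., 0:3], dq[..., 0:3], ddq[..., 0:3]
    for i in range(1, model.nlinks):
        p = model.parent_index[i]
        d = model._offsets[i]
        o[i] = o[p] + np.einsum("...ij,j->...i", R[..., p, :, :], d)
        vo[i] = vo[p] + np.einsum("...ij,j->...i", Rd[..., p, :, :], d)
        ao[i] = ao[p] + np.einsum("...ij,j->...i", Rdd[..., p, :, :], d)

    RT = np.swapaxes(R, -1, -2)
    W = Rd @ RT
    omega = _vee(W)
    alpha = _vee(Rdd @ RT + Rd @ np.swapaxes(Rd, -1, -2))

    Jv = _com_jacobians(model, q)
    Jw = _omega_jacobians(model, q)

    g_vec = np.array([0.0, 0.0, -model.gravity])
    f = np.zeros(q.shape, dtype=q.dtype)
    for i in range(model.nlinks):
        a_com = ao[i] + np.einsum("...ij,j->...i", Rdd[..., i, :, :], model._coms[i])
        F = model._masses[i] * (a_com - g_vec)
        Iw = R[..., i, :, :] @ model._inertias[i] @ RT[..., i, :, :]
        Iww = np.einsum("...ij,...j->...i", Iw, omega[..., i, :])
        N = np.einsum("...ij,...j->...i", Iw, alpha[..., i, :]) + np.cross(omega[..., i, :], Iww)
        f = f + np.einsum("...in,...i->...n", Jv[..., i, :, :], F)
        f = f + np.einsum("...in,...i->...n", Jw[..., i, :, :], N)
    return f


def net_wrench(model: SkeletonModel, q, dq, ddq):
    """Net external (contact) force and moment about the world origin.

    Sums the Newton-Euler wrenches of all links with gravity included, so
    the result equals the total contact wrench a trajectory demands:
    F = sum m_i (a_i - g),  M = sum p_i x m_i (a_i - g) + I_w alpha
    + omega x I_w omega.  Uses the same chain-rule accelerations as
    :func:`inverse_dynamics`, which matters when matching a gait to a force
    template under a backward-difference discretisation.
    """
    q, dq, ddq = np.broadcast_arrays(np.asarray(q), np.asarray(dq), np.asarray(ddq))
    ang = _link_angles(model, q)
    rates = _link_angles(model, dq)
    accs = _link_angles(model, ddq)
    R, Rd, Rdd = _euler_xyz_time_derivs(ang, rates, accs)
    o = [None] * model.nlinks
    ao = [None] * model.nlinks
    o[0], ao[0] = q[..., 0:3], ddq[..., 0:3]
    for i in range(1, model.nlinks):
        p = model.parent_index[i]
        d = model._offsets[i]
        o[i] = o[p] + np.einsum("...ij,j->...i", R[..., p, :, :], d)
        ao[i] = ao[p] + np.einsum("...ij,j->...i", Rdd[..., p, :, :], d)
    RT = np.swapaxes(R, -1, -2)
    omega = _vee(Rd @ RT)
    alpha = _vee(Rdd @ RT + Rd @ np.swapaxes(Rd, -1, -2))
    g_vec = np.array([0.0, 0.0, -model.gravity])
    F = np.zeros(q.shape[:-1] + (3,), dtype=q.dtype)
    M = np.zeros_like(F)
    for i in range(model.nlinks):
        p_com = o[i] + np.einsum("...ij,j->...i", R[..., i, :, :], model._coms[i])
        a_com = ao[i] + np.einsum("...ij,j->...i", Rdd[..., i, :, :], model._coms[i])
        Fi = model._masses[i] * (a_com - g_vec)
        Iw = R[..., i, :, :] @ model._inertias[i] @ RT[..., i, :, :]
        Iww = np.einsum("...ij,...j->...i", Iw, omega[..., i, :])
        Ni = np.einsum("...ij,...j->...i", Iw, alpha[..., i, :]) + np.cross(
            omega[..., i, :], Iww
        )
        F = F + Fi
        M = M + np.cross(p_com, Fi) + Ni
    return F, M


def mass_matrix(model: SkeletonModel, q) -> np.ndarray:
    """Joint-space inertia matrix M(q) = sum_i Jv^T m Jv + Jw^T I_w Jw."""
    q = np.asarray(q)
    R, _ = _link_frames(model, q)
    RT = np.swapaxes(R, -1, -2)
    Jv = _com_jacobians(model, q)
    Jw = _omega_jacobians(model, q)
    M = np.zeros(q.shape[:-1] + (model.nq, model.nq), dtype=q.dtype)
    for i in range(model.nlinks):
        M = M + model._masses[i] * np.einsum("...im,...in->...mn", Jv[..., i, :, :], Jv[..., i, :, :])
        Iw = R[..., i, :, :] @ model._inertias[i] @ RT[..., i, :, :]
        M = M + np.einsum("...im,...ij,...jn->...mn", Jw[..., i, :, :], Iw, Jw[..., i, :, :])
    return M


def input_map(model: SkeletonModel, q) -> np.ndarray:
    """B(q) mapping per-joint-DOF torques to generalized forces.

    Each joint torque acts as an equal-and-opposite pure torque pair on the
    two links it connects, entering the generalized equations through the
    links' angular-velocity maps.  Revolute joints are actuated about the
    parent's y axis, universal joints about the parent's x and y axes,
    spherical joints by a free world-frame torque vector.
    """
    q = np.asarray(q)
    R, _ = _link_frames(model, q)
    ang = _link_angles(model, q)
    E = angular_velocity_map(ang)
    ET = np.swapaxes(E, -1, -2)
    B = np.zeros(q.shape[:-1] + (model.nq, model.ntau), dtype=q.dtype)
    col = 0
    eye = np.eye(3)
    for j in model.joints:
        i_p, i_c = model.link_index(j.link_i), model.link_index(j.link_j)
        if j.kind == "revolute":
            axes = [R[..., i_p, :, 1]]
        elif j.kind == "universal":
            axes = [R[..., i_p, :, 0], R[..., i_p, :, 1]]
        else:
            axes = [np.broadcast_to(eye[k], q.shape[:-1] + (3,)) for k in range(3)]
        for u in axes:
            gen_c = np.einsum("...ij,...j->...i", ET[..., i_c, :, :], u)
            gen_p = np.einsum("...ij,...j->...i", ET[..., i_p, :, :], u)
            B[..., 3 + 3 * i_c : 6 + 3 * i_c, col] += gen_c
            B[..., 3 + 3 * i_p : 6 + 3 * i_p, col] -= gen_p
            col += 1
    return B


def dynamics_terms(model: SkeletonModel, q, dq) -> DynamicsTerms:
    """M, C(q,qd)qd, G and the input map B at one (or a batch of) states."""
    q = np.asarray(q, float)
    dq = np.asarray(dq, float)
    if q.shape[-1] != model.nq or dq.shape[-1] != model.nq:
        raise ValueError("state dimension mismatch")
    zero = np.zeros_like(q)
    f0 = inverse_dynamics(model, q, zero, zero)  # = -G
    fv = inverse_dynamics(model, q, dq, zero)  # = Cv - G
    M = mass_matrix(model, q)
    return DynamicsTerms(M=M, Cv=fv - f0, G=-f0, B=input_map(model, q))


# ---------------------------------------------------------------------------
# joint geometry constraints


def joint_constraint_residuals(model: SkeletonModel, q) -> np.ndarray:
    """Scalar residuals enforcing joint geometry (2 per revolute, 1 per universal).

    For a revolute joint the child may rotate about the parent's y axis only:
    r_{i,y} . r_{j,x} = 0 and r_{i,y} . r_{j,z} = 0.  A universal joint keeps
    only the first residual, forbidding relative rotation about z.
    """
    q = np.asarray(q)
    R, _ = _link_frames(model, q)
    res = []
    for j in model.joints:
        if j.kind == "spherical":
            continue
        i_p, i_c = model.link_index(j.link_i), model.link_index(j.link_j)
        ry = R[..., i_p, :, 1]
        rx = R[..., i_c, :, 0]
        res.append(np.einsum("...i,...i->...", ry, rx))
        if j.kind == "revolute":
            rz = R[..., i_c, :, 2]
            res.append(np.einsum("...i,...i->...", ry, rz))
    if not res:
        return np.zeros(q.shape[:-1] + (0,), dtype=q.dtype)
    return np.stack(res, axis=-1)


def joint_constraint_jacobian(model: SkeletonModel, q) -> np.ndarray:
    """J_c = d(joint residuals)/dq, shape (..., nr, nq).

    Analytic (and itself complex-safe, so the estimator can complex-step
    through J_c^T lambda_c products).
    """
    q = np.asarray(q)
    ang = _link_angles(model, q)
    R = _euler_xyz(ang)
    dR = _euler_xyz_dangles(ang)  # (..., L, 3(k), 3, 3)
    nr = model.n_joint_residuals
    J = np.zeros(q.shape[:-1] + (nr, model.nq), dtype=q.dtype)
    row = 0
    for j in model.joints:
        if j.kind == "spherical":
            continue
        i_p, i_c = model.link_index(j.link_i), model.link_index(j.link_j)
        ry = R[..., i_p, :, 1]
        d_ry = dR[..., i_p, :, :, 1]  # (..., k, 3)
        for _, col in (("x", 0),) if j.kind == "universal" else (("x", 0), ("z", 2)):
            rc = R[..., i_c, :, col]
            d_rc = dR[..., i_c, :, :, col]
            J[..., row, 3 + 3 * i_p : 6 + 3 * i_p] = np.einsum("...ki,...i->...k", d_ry, rc)
            J[..., row, 3 + 3 * i_c : 6 + 3 * i_c] = np.einsum("...i,...ki->...k", ry, d_rc)
            row += 1
    return J


# ---------------------------------------------------------------------------
# equation-of-motion residual


def dynamics_residual(
    model: SkeletonModel,
    state: GeneralizedState,
    tau=None,
    contact_forces: Mapping[str, np.ndarray] | None = None,
    joint_forces=None,
) -> np.ndarray:
    """Disturbance w = M qdd + C qd - (G + B tau + J_c^T lambda_c + J_g^T lambda_g).

    ``tau`` are per-joint-DOF torques (length ``model.ntau``);
    ``contact_forces`` maps marker names to world-frame 3-vectors applied at
    those markers; ``joint_forces`` are multipliers of the joint geometry
    constraints.  w vanishes exactly on states satisfying the equation of
    motion.
    """
    q, dq, ddq = np.asarray(state.q), np.asarray(state.dq), np.asarray(state.ddq)
    if not (q.shape[-1] == dq.shape[-1] == ddq.shape[-1] == model.nq):
        raise ValueError("state dimension mismatch")
    w = inverse_dynamics(model, q, dq, ddq)
    if tau is not None:
        tau = np.asarray(tau)
        if tau.shape[-1] != model.ntau:
            raise ValueError(f"tau has {tau.shape[-1]} entries, model has {model.ntau} torque DOFs")
        w = w - np.einsum("...nk,...k->...n", input_map(model, q), tau)
    if contact_forces:
        J = marker_jacobians(model, q)
        for name, F in contact_forces.items():
            m = model.marker_index(name)
            w = w - np.einsum("...in,...i->...n", J[..., m, :, :], np.asarray(F))
    if joint_forces is not None:
        Jc = joint_constraint_jacobian(model, q)
        w = w - np.einsum("...rn,...r->...n", Jc, np.asarray(joint_forces))
    return w


# ---------------------------------------------------------------------------
# energies & passive simulation helpers


def kinetic_energy(model: SkeletonModel, q, dq) -> np.ndarray:
    M = mass_matrix(model, q)
    dq = np.asarray(dq)
    return 0.5 * np.einsum("...i,...ij,...j->...", dq, M, dq)


def potential_energy(model: SkeletonModel, q) -> np.ndarray:
    q = np.asarray(q)
    R, o = _link_frames(model, q)
    com = o + np.einsum("...lij,lj->...li", R, model._coms)
    return model.gravity * np.einsum("l,...l->...", model._masses, com[..., 2])


def passive_acceleration(model: SkeletonModel, q, dq) -> np.ndarray:
    """qdd of the unactuated, contact-free model (for fine-step simulation)."""
    t = dynamics_terms(model, q, dq)
    return np.linalg.solve(t.M, t.G - t.Cv)


# ---------------------------------------------------------------------------
# generic complex-step differentiation (shared with the estimator)


def complex_step_jacobian(f, x: np.ndarray, h: float = 1e-200) -> np.ndarray:
    """Jacobian of ``f`` at ``x`` (last axis = inputs) by one batched call.

    ``f`` must be complex-analytic in ``x`` (true of all FK/dynamics code in
    this package).  Returns shape ``(..., m, n)`` for f: (..., n) -> (..., m).
    """
    x = np.asarray(x, float)
    n = x.shape[-1]
    X = x[..., None, :] + 1j * h * np.eye(n)
    out = f(X)  # (..., n, m)
    return np.swapaxes(out.imag, -1, -2) / h
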