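"""Synthetic trials: ground-truth gait, torques and GRFs plus rendered 2D keypoints.

The generator builds a complete, exactly dynamically consistent trial for
the reduced 9-link quadruped so that every other module can be tested with
zero downloads:

1. a lateral-sequence walk (duty factor 0.75, at least three
   non-collinear feet grounded at every node, so the per-node force map is
   full rank) is laid out in task space — stance feet pinned to the
   ground, swing feet following C3-smooth arcs — and turned into joint
   angles by closed-form two-link inverse kinematics (planar within a
   rolled leg plane, which satisfies the knee constraints identically);
2. the torso trajectory is shaped by wrench matching: fore-aft, vertical
   and lateral velocity plus small pitch/yaw oscillations (and fore-aft /
   lateral foot-placement shifts for secular moments) are iterated until
   the net contact wrench the kinematics demands tracks the wrench implied
   by the summed sinusoidal GRF templates of the stance feet;
3. exact joint torques, joint-constraint torques and per-foot ground
   reaction forces are recovered at every node by an equality-constrained
   least-squares problem that drives the *discrete* (backward-Euler)
   dynamics residual to zero; double-support indeterminacy is resolved by
   the same minimum-torque criterion the estimator's cost uses, with a
   weak pull toward the GRF template.

The truth therefore satisfies ``w = 0`` under the estimator's own
discretisation, and truth GRFs stay near (but, as in real locomotion, not
exactly on) the sinusoidal template.  Observations are rendered through
four synthetic fisheye cameras (two near-side, two far-side with
confidence down-weighting) with isotropic pixel noise and dropout;
observations regenerate bit-identically from (config, seed) and the truth
kinematics are seed-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from kfte import io as _io
from kfte import multibody as _mb
from kfte.camera import BehindCameraError, CameraModel, Observation2D, project
from kfte.contact import ContactPlan, GRFProfile, GRFSynthesisParams, synth_sinusoidal_grf
from kfte.estimator import KFTEProblem
from kfte.multibody import SkeletonModel
from kfte.presets import quadruped9

__all__ = [
    "GaitParams",
    "GenerationError",
    "SyntheticTrial",
    "generate_gait",
    "render_observations",
    "generate_trial",
    "make_camera_rig",
]

# lateral-sequence footfall: stance start as a fraction of the stride
_LEG_OFFSET = {"lh": 0.0, "lf": 0.25, "rh": 0.5, "rf": 0.75}
_LEGS = ("lf", "rf", "lh", "rh")


class GenerationError(RuntimeError):
    """Dynamically or geometrically infeasible gait parameters."""


def _longest_run(nodes):
    """Longest contiguous run in a sorted integer list."""
    best, cur = [], []
    for k in nodes:
        if cur and k == cur[-1] + 1:
            cur.append(k)
        else:
            cur = [k]
        if len(cur) > len(best):
            best = cur
    return best


@dataclass
class GaitParams:
    """Stride parameters of the synthetic walk.

    Defaults describe a dog-sized quadruped in a lateral-sequence walk at
    0.7 m/s with a 0.6 s stride and duty factor 0.75 (at least three feet
    always grounded), sampled at 80 Hz over one stride (48 nodes).
    """

    speed: float = 0.7  # m/s
    stride_time: float = 0.6  # s
    duty: float = 0.75
    h: float = 0.0125  # s per node
    n_nodes: int = 48
    base_height: float = 0.42  # nominal hip height, m
    swing_lift: float = 0.05  # swing foot apex, m
    momentum_iters: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.duty < 1:
            raise GenerationError("duty factor must be in (0, 1)")
        if self.speed <= 0 or self.h <= 0:
            raise GenerationError("speed and h must be > 0")

    @property
    def stance_time(self) -> float:
        return self.duty * self.stride_time

    @property
    def stance_nodes(self) -> int:
        return int(round(self.stance_time / self.h))


def _smoothstep7(s):
    """Seventh-order smoothstep: zero value/vel/acc/jerk at both ends."""
    s = np.clip(s, 0.0, 1.0)
    return s**4 * (35.0 - 84.0 * s + 70.0 * s**2 - 20.0 * s**3)


def _swing_bump(s):
    """C3 vertical swing profile, peak 1 at midswing."""
    return np.sin(np.pi * np.clip(s, 0.0, 1.0)) ** 4


class _Gait:
    """Closed-form task-space gait: foot targets + per-foot GRF templates."""

    def __init__(self, model: SkeletonModel, params: GaitParams, grf: GRFSynthesisParams):
        self.model = model
        self.p = params
        self.grf = grf
        self.hip_local = {}
        self.leg_lengths = {}
        self.bend = {}
        for leg in _LEGS:
            up = model.links[model.link_index(f"{leg}_upper")]
            low = model.links[model.link_index(f"{leg}_lower")]
            off = np.asarray(up.offset, float)
            self.hip_local[leg] = off
            self.leg_lengths[leg] = (up.length, low.length)
            self.bend[leg] = 1.0 if leg.endswith("f") else -1.0
        self.placements = {}  # (leg, cycle) -> stance foot (x, y); default nominal line
        torso = model.links[0]
        self._half_torso = np.asarray(torso.axis, float) * torso.length / 2.0
        self.A = grf.peak_force(params.speed, model.total_mass, model.gravity)
        T_st = params.stance_time
        f1, f2 = grf.fx_peak_fractions
        s1, s2 = grf.fx_peak_scales
        self._fx_spline = CubicSpline(
            np.array([0.0, f1, 0.5, f2, 1.0]) * T_st,
            np.array([0.0, s1, 0.0, s2, 0.0]) * self.A,
            bc_type="natural",
        )

    # -- schedule ----------------------------------------------------------
    def stance_phase(self, leg: str, t: float):
        """(cycle index, seconds into stance) or (cycle, None) when swinging."""
        p = self.p
        u = t / p.stride_time - _LEG_OFFSET[leg]
        n = int(np.floor(u))
        s = (u - n) * p.stride_time
        if s <= p.stance_time + 1e-12:
            return n, s
        return n, None

    def _placement(self, leg: str, n: int) -> np.ndarray:
        """Ground (x, y) of a stance foot for cycle n."""
        p = self.p
        if (leg, n) in self.placements:
            return self.placements[(leg, n)]
        t_n = (n + _LEG_OFFSET[leg]) * p.stride_time
        return np.array(
            [
                self.hip_local[leg][0]
                - self._half_torso[0]
                + p.speed * (t_n + 0.5 * p.stance_time),
                self.hip_local[leg][1],
            ]
        )

    def foot_position(self, leg: str, t: float) -> np.ndarray:
        p = self.p
        n, s = self.stance_phase(leg, t)
        t_n = (n + _LEG_OFFSET[leg]) * p.stride_time
        xy_n = self._placement(leg, n)
        if s is not None:
            return np.array([xy_n[0], xy_n[1], 0.0])
        sw = (t - (t_n + p.stance_time)) / (p.stride_time - p.stance_time)
        xy = xy_n + (self._placement(leg, n + 1) - xy_n) * _smoothstep7(sw)
        return np.array([xy[0], xy[1], p.swing_lift * _swing_bump(sw)])

    def template_force(self, leg: str, t: float) -> np.ndarray:
        """Per-foot sinusoidal GRF template evaluated in continuous time."""
        _, s = self.stance_phase(leg, t)
        if s is None:
            return np.zeros(3)
        T_st = self.p.stance_time
        fz = self.A * np.sin(np.pi * s / T_st)
        return np.array([float(self._fx_spline(s)), 0.0, fz])

    # -- inverse kinematics --------------------------------------------------
    def leg_angles(self, leg: str, hip_world: np.ndarray, foot_world: np.ndarray):
        """(roll, upper pitch, lower pitch) of a 2-segment leg.

        Both segments share one roll angle (the leg plane tilts about x to
        contain the hip-to-foot vector), which keeps the revolute knee
        constraint satisfied exactly; pitches come from planar two-link IK
        inside that plane.
        """
        l1, l2 = self.leg_lengths[leg]
        d = foot_world - hip_world
        phi = float(np.arctan2(d[1], -d[2]))
        # rotate into the leg plane: Rx(-phi) d has zero y-component
        dz = -np.sin(phi) * d[1] + np.cos(phi) * d[2]
        dx = d[0]
        D = float(np.hypot(dx, dz))
        if D > 0.999 * (l1 + l2) or D < 1.02 * abs(l1 - l2):
            raise GenerationError(
                f"leg {leg}: foot target at distance {D:.3f} m unreachable "
                f"(limb lengths {l1}+{l2})"
            )
        alpha = np.arctan2(-dx, -dz)
        cosb = (l1**2 + D**2 - l2**2) / (2 * l1 * D)
        beta = np.arccos(np.clip(cosb, -1.0, 1.0))
        th1 = alpha + self.bend[leg] * beta
        ex = dx - l1 * (-np.sin(th1))
        ez = dz - l1 * (-np.cos(th1))
        th2 = np.arctan2(-ex, -ez)
        return phi, float(th1), float(th2)

    def pose(self, t: float, centre_xyz, pitch: float = 0.0, yaw: float = 0.0) -> np.ndarray:
        """Generalized coordinates at time t given the torso-centre position,
        pitch and yaw (the torso rotates about its geometric centre)."""
        m = self.model
        q = np.zeros(m.nq)
        centre = np.asarray(centre_xyz, float)
        cp, sp = np.cos(pitch), np.sin(pitch)
        cy, sy = np.cos(yaw), np.sin(yaw)
        Ry = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
        Rz = np.array([[cy, -sy, 0.0], [sy, cy, 0.0], [0.0, 0.0, 1.0]])
        Rt = Ry @ Rz
        base = centre - Rt @ self._half_torso
        q[0:3] = base
        q[m.angle_slice("torso")] = [0.0, pitch, yaw]
        for leg in _LEGS:
            hip = base + Rt @ self.hip_local[leg]
            phi, th1, th2 = self.leg_angles(leg, hip, self.foot_position(leg, t))
            q[m.angle_slice(f"{leg}_upper")] = [phi, th1, 0.0]
            q[m.angle_slice(f"{leg}_lower")] = [phi, th2, 0.0]
        return q


def _cumtrapz(y, dt):
    return np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * dt)])


def _detrend(e, t):
    """Remove the best linear fit (periodic channels must not drift)."""
    b, a = np.polyfit(t, e, 1)
    return e - (a + b * t)


def _shape_base(gait: _Gait, t_grid: np.ndarray):
    """Shape base x/y/z and torso pitch so whole-body linear momentum and the
    roll/pitch angular momentum track what the summed GRF templates imply.

    Walking under the staggered per-foot templates requires left-right load
    imbalance, hence real lateral sway (roll momentum) and a small pitch
    oscillation (fore-hind alternation); without them the exact per-node
    force recovery would sit far from the template.  Fixed-point iteration:
    legs follow the base through IK, so each channel is updated with the
    torso as the free momentum reservoir and re-integrated.
    """
    p, m = gait.p, gait.model
    M_tot, g = m.total_mass, m.gravity
    m_torso = m._masses[0]
    n = len(t_grid)
    dt = np.diff(t_grid)

    totF = np.array([sum(gait.template_force(l, t) for l in _LEGS) for t in t_grid])

    x = p.speed * t_grid.copy()
    y = np.zeros(n)
    z = np.full(n, p.base_height)
    pitch = np.zeros(n)
    yaw = np.zeros(n)
    I_pitch = 1.0  # effective whole-body pitch/yaw inertias (relaxed fixed point)
    I_yaw = 1.7
    shift_x = 0.0  # fore-aft/lateral support shift balancing secular moments
    shift_y = 0.0

    def cumback(yv):
        # backward-rectangle cumulative sum matching the backward-Euler
        # readout of the generated trajectory
        out = np.zeros(n)
        out[1:] = np.cumsum(yv[1:] * dt)
        return out

    for _ in range(p.momentum_iters):
        Q = np.array(
            [gait.pose(t, (x[i], y[i], z[i]), pitch[i], yaw[i]) for i, t in enumerate(t_grid)]
        )
        # backward differences: the same discretisation the dynamics
        # readout uses, so the wrench match carries over exactly
        qd_g = np.zeros_like(Q)
        qd_g[1:] = (Q[1:] - Q[:-1]) / dt[:, None]
        qd_g[0] = qd_g[1]
        qdd_g = np.zeros_like(Q)
        qdd_g[2:] = (qd_g[2:] - qd_g[1:-1]) / dt[1:, None]
        qdd_g[:2] = qdd_g[2]
        F_net, M_net = _mb.net_wrench(m, Q, qd_g, qdd_g)

        # template contact wrench (moments about the world origin)
        M_tpl = np.zeros((n, 3))
        for i, t in enumerate(t_grid):
            for leg in _LEGS:
                M_tpl[i] += np.cross(gait.foot_position(leg, t), gait.template_force(leg, t))

        # integrated wrench mismatches play the role of momentum residuals
        Ex = cumback(totF[:, 0] - F_net[:, 0])
        Ez = cumback(totF[:, 2] - F_net[:, 2])
        EMx = cumback(M_tpl[:, 0] - M_net[:, 0])
        EMy = cumback(M_tpl[:, 1] - M_net[:, 1])
        EMz = cumback(M_tpl[:, 2] - M_net[:, 2])

        vx = np.zeros(n)
        vx[1:] = (x[1:] - x[:-1]) / dt
        vx[0] = vx[1]
        vy = np.zeros(n)
        vy[1:] = (y[1:] - y[:-1]) / dt
        vy[0] = vy[1]
        vz = np.zeros(n)
        vz[1:] = (z[1:] - z[:-1]) / dt
        vz[0] = vz[1]
        wp = np.zeros(n)
        wp[1:] = (pitch[1:] - pitch[:-1]) / dt
        wp[0] = wp[1]
        wy = np.zeros(n)
        wy[1:] = (yaw[1:] - yaw[:-1]) / dt
        wy[0] = wy[1]

        # channel updates: torso velocity absorbs the wrench mismatch
        R, o = _mb._link_frames(m, Q)
        com = o + np.einsum("klij,lj->kli", R, m._coms)
        vx_new = vx + 0.8 * Ex / m_torso
        vz_new = vz + 0.8 * _detrend(Ez, t_grid) / m_torso
        c_roll = -float(np.einsum("l,kl->k", m._masses, com[..., 2]).mean())
        vy_new = vy + 0.7 * _detrend(EMx, t_grid) / c_roll
        wp_new = wp + 0.5 * _detrend(EMy, t_grid) / I_pitch
        wy_new = wy + 0.5 * _detrend(EMz, t_grid) / I_yaw
        # secular moment biases cannot be absorbed by periodic motion: they
        # are balanced by shifting the support (foot placements) relative to
        # the hips — e.g. a net-braking template demands the ZMP ahead of
        # the COM, exactly as in decelerating animals
        b_pitch = np.polyfit(t_grid, EMy, 1)[0]
        b_roll = np.polyfit(t_grid, EMx, 1)[0]
        shift_x += 0.7 * b_pitch / (M_tot * g)
        shift_y += -0.7 * b_roll / (M_tot * g)

        def back_int(vv, x0=0.0):
            out = np.zeros(n)
            out[0] = x0
            out[1:] = x0 + np.cumsum(vv[1:] * dt)
            return out

        x = back_int(vx_new, p.speed * t_grid[0])
        y = back_int(vy_new - vy_new.mean())
        y -= y.mean()
        z = back_int(vz_new - vz_new.mean())
        z += p.base_height - z.mean()
        pitch = back_int(wp_new - wp_new.mean())
        pitch -= pitch.mean()
        yaw = back_int(wy_new - wy_new.mean())
        yaw -= yaw.mean()
        if max(np.abs(pitch).max(), np.abs(yaw).max()) > 0.5:
            raise GenerationError("pitch/yaw shaping diverged; adjust gait parameters")

        # re-place stance feet under the actual hip at mid-stance
        def interp_edge(tq, arr):
            if tq < t_grid[0]:
                return arr[0] + (arr[1] - arr[0]) / dt[0] * (tq - t_grid[0])
            if tq > t_grid[-1]:
                return arr[-1] + (arr[-1] - arr[-2]) / dt[-1] * (tq - t_grid[-1])
            return float(np.interp(tq, t_grid, arr))

        for leg in _LEGS:
            off = _LEG_OFFSET[leg]
            for cyc in range(-3, 4):
                t_mid = (cyc + off) * p.stride_time + 0.5 * p.stance_time
                xb = interp_edge(t_mid, x)
                yb = interp_edge(t_mid, y)
                gait.placements[(leg, cyc)] = np.array(
                    [
                        xb + gait.hip_local[leg][0] - gait._half_torso[0] + shift_x,
                        yb + gait.hip_local[leg][1] + shift_y,
                    ]
                )
    return x, y, z, pitch, yaw


def _node_kinetics(B, Jc, Jg_list, rhs, tpls, mu, band, band_floor):
    """Exact torque/force recovery at one node (all quantities normalised).

    Minimises ||tau||^2 (plus tiny regularisers and a weak pull of the
    ground forces toward their templates) subject to the exact dynamics
    equality, the friction pyramid, positive vertical force and — when
    ``band`` is given — the +-band box around the template on the x/z
    components.  Mirrors the estimator's own tie-break so double-support
    indeterminacy resolves identically.  Returns None when infeasible.
    """
    from scipy.optimize import minimize as _minimize

    ntau = B.shape[1]
    nr = Jc.shape[0]
    nf = len(Jg_list)
    cols = [B, Jc.T] + [Jg.T for Jg in Jg_list]
    A = np.concatenate(cols, axis=1)
    neq, nx = A.shape
    wdiag = np.concatenate([np.ones(ntau), 1e-6 * np.ones(nr), 1e-4 * np.ones(3 * nf)])
    xref = np.zeros(nx)
    for j in range(nf):
        xref[ntau + nr + 3 * j : ntau + nr + 3 * j + 3] = tpls[j]

    # reduce onto the null space of the exact-dynamics equality: the
    # equality then holds to machine precision for every candidate
    U, s, Vt = np.linalg.svd(A, full_matrices=True)
    rank = int(np.sum(s > 1e-10 * s[0]))
    if rank < neq:
        return None  # support not full rank (should not happen with 3 feet)
    x_p = Vt[:rank].T @ ((U.T @ rhs)[:rank] / s[:rank])
    Z = Vt[rank:].T  # (nx, ndof)
    ndof = Z.shape[1]

    lo = np.full(nx, -np.inf)
    hi = np.full(nx, np.inf)
    G_rows = []
    for j in range(nf):
        o = ntau + nr + 3 * j
        tx, tz = tpls[j][0], tpls[j][2]
        if band is not None:
            dz = band * abs(tz) + band_floor
            dx = band * abs(tx) + band_floor
            lo[o], hi[o] = tx - dx, tx + dx
            lo[o + 2] = max(1e-6, tz - dz)
            hi[o + 2] = tz + dz
        else:
            lo[o + 2] = 1e-6
        for comp in (0, 1):  # friction pyramid on x and y
            for sgn in (1.0, -1.0):
                g = np.zeros(nx)
                g[o + 2] = mu
                g[o + comp] = sgn
                G_rows.append(g)
    G = np.array(G_rows)

    # inequalities in reduced coordinates u (x = x_p + Z u)
    C_list = [Z[np.isfinite(hi)] * -1.0, Z[np.isfinite(lo)], (G @ Z)]
    d_list = [
        (x_p - hi)[np.isfinite(hi)],
        (lo - x_p)[np.isfinite(lo)],
        -(G @ x_p),
    ]
    C = np.concatenate([c for c in C_list if len(c)])
    d = np.concatenate([dd for dd in d_list if len(dd)])
    # constraint: C u + (-d') >= 0 in the form c(u) = C@u - d >= 0
    # (rows built so that feasibility is C @ u >= d)

    H = Z.T @ (wdiag[:, None] * Z)
    gvec = Z.T @ (wdiag * (x_p - xref))

    def viol(x, tol):
        vb = max(
            float(np.maximum(lo - x, 0).max(initial=0.0)),
            float(np.maximum(x - hi, 0).max(initial=0.0)),
        )
        vg = float(np.maximum(-(G @ x), 0).max(initial=0.0)) if G.size else 0.0
        return max(vb, vg)

    u0 = np.linalg.solve(H + 1e-12 * np.eye(ndof), -gvec)
    if viol(x_p + Z @ u0, 0.0) <= 1e-9:
        return x_p + Z @ u0

    res = _minimize(
        lambda u: float(u @ H @ u) + 2.0 * float(gvec @ u),
        u0,
        jac=lambda u: 2.0 * (H @ u + gvec),
        constraints=[{"type": "ineq", "fun": lambda u: C @ u - d, "jac": lambda u: C}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-16},
    )
    x = x_p + Z @ res.x
    if viol(x, 0.0) > 1e-5:
        return None
    return x


@dataclass
class SyntheticTrial:
    """One complete synthetic trial (truth + rendered observations)."""

    model: SkeletonModel
    params: GaitParams
    grf_params: GRFSynthesisParams
    contact: ContactPlan
    Q: np.ndarray  # (N+1, nq) truth coordinates
    dq0: np.ndarray
    qd: np.ndarray  # (N+1, nq) backward differences (row 0 = dq0)
    qdd: np.ndarray  # (N, nq) nodes 1..N
    tau: np.ndarray  # (N, ntau) newton-metres
    lambda_c: np.ndarray  # (N, nr)
    lam_world: dict  # (foot, node) -> world 3-vector, newtons
    truth_forces: dict  # foot -> GRFProfile (truth, nodes >= 1)
    prior_forces: dict  # foot -> GRFProfile (template over the main stance)
    cameras: dict
    observations: list
    prior_all: dict | None = None  # foot -> [GRFProfile] covering every stance
    seed: int = 0
    noise_px: float = 0.0
    dropout: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    @property
    def markers(self) -> np.ndarray:
        return _mb.forward_kinematics(self.model, self.Q).markers

    def problem(self, mode: str = "sinusoidal", **kwargs) -> KFTEProblem:
        """Wrap the trial into an estimation problem."""
        return KFTEProblem(
            model=self.model,
            cameras=self.cameras,
            observations=self.observations,
            contact=self.contact,
            n_nodes=self.params.n_nodes,
            h=self.params.h,
            grf_prior=(self.prior_all or self.prior_forces) if mode == "sinusoidal" else None,
            **kwargs,
        )

    def save(self, root) -> None:
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        _io.write_skeleton(root / "skeleton.json", self.model)
        _io.write_cameras(root / "cameras.json", self.cameras)
        _io.write_keypoints(root / "keypoints.csv", self.observations)
        _io.write_contacts(root / "contacts.json", self.contact)
        _io.write_forces(root / "truth_forces.csv", self.truth_forces)
        n, nq = self.Q.shape
        import pandas as pd

        cols = {"frame": np.arange(n)}
        for i in range(nq):
            cols[f"q{i}"] = self.Q[:, i]
        pd.DataFrame(cols).to_csv(root / "truth_trajectory.csv", index=False)
        _io.write_manifest(
            root / "manifest.json",
            {
                "gait": asdict(self.params),
                "grf": asdict(self.grf_params),
                "noise_px": self.noise_px,
                "dropout": self.dropout,
                "frame_rate": 1.0 / self.params.h,
            },
            seed=self.seed,
        )


def generate_gait(
    model: SkeletonModel | None = None,
    params: GaitParams | None = None,
    grf_params: GRFSynthesisParams | None = None,
    w_tol: float = 1e-6,
):
    """Build the truth trajectory, torques, GRFs and contact schedule.

    Returns a partially filled :class:`SyntheticTrial` (no cameras or
    observations).  Raises :class:`GenerationError` when the requested
    parameters are geometrically unreachable, leave fewer than two feet
    grounded at some node (exact consistency would need ballistic flight),
    or fail to zero the dynamics residual.
    """
    model = model or quadruped9()
    params = params or GaitParams()
    grf_params = grf_params or GRFSynthesisParams()
    p = params
    N, h = p.n_nodes, p.h
    gait = _Gait(model, params, grf_params)

    # contact schedule in node intervals
    stance = {}
    n_st = p.stance_nodes  # samples span stance_nodes + 1 nodes
    for leg in _LEGS:
        k0 = int(round(_LEG_OFFSET[leg] * p.stride_time / h))
        ivs = []
        for rep in (-1, 0, 1):  # periodic tiling clipped to the trial window
            a = k0 + rep * int(round(p.stride_time / h))
            b = a + n_st + 1
            a2, b2 = max(a, 0), min(b, N + 1)
            if a2 < b2:
                ivs.append((a2, b2))
        stance[f"{leg}_foot"] = ivs
    plan = ContactPlan(stance=stance)
    counts = np.zeros(N + 1, int)
    for foot in plan.feet():
        counts[plan.stance_nodes(foot)] += 1
    if counts.min() < 3:
        raise GenerationError(
            "schedule leaves fewer than three feet grounded at some node; "
            "the exact-consistency construction needs a full-rank support "
            "(flight or two-point support would require ballistic shaping)"
        )

    # base motion by momentum shaping on a padded grid (edges are shaped on
    # out-of-trial nodes so one-sided differences never touch the trial)
    pad = 6
    t_grid = (np.arange(-pad, N + pad + 1)) * h
    x_b, y_b, z_b, pitch_b, yaw_b = _shape_base(gait, t_grid)
    Q_ext = np.array(
        [
            gait.pose(t, (x_b[i], y_b[i], z_b[i]), pitch_b[i], yaw_b[i])
            for i, t in enumerate(t_grid)
        ]
    )
    Q = Q_ext[pad : pad + N + 1]  # nodes 0..N
    qd_ext = (Q_ext[1:] - Q_ext[:-1]) / h  # index i = velocity at node i+1-pad
    qd = qd_ext[pad - 1 : pad + N]  # nodes 0..N (row 0 = dq0)
    qdd = (qd_ext[pad : pad + N] - qd_ext[pad - 1 : pad + N - 1]) / h  # nodes 1..N
    dq0 = qd[0]

    # exact kinetics per node
    nq, ntau, nr = model.nq, model.ntau, model.n_joint_residuals
    fs = model.total_mass * model.gravity
    tau = np.zeros((N, ntau))
    lamc = np.zeros((N, nr))
    lam_world = {}
    feet = plan.feet()
    foot_mi = {f: model.marker_index(f) for f in feet}
    Q1 = Q[1:]
    rhs = _mb.inverse_dynamics(model, Q1, qd[1:], qdd)
    B = _mb.input_map(model, Q1)
    Jc = _mb.joint_constraint_jacobian(model, Q1)
    Jm = _mb.marker_jacobians(model, Q1)
    band_dev = 0.0
    min_fz = np.inf
    band_relaxed = 0
    relaxed_nodes = []
    max_inflation = 1.0
    for k in range(1, N + 1):
        i = k - 1
        here = [f for f in feet if plan.in_stance(f, k)]
        tpls = np.array([gait.template_force(f[:2], k * h) for f in here]) / fs
        # escalate the template band gradually when the exact wrench cannot
        # be met inside it, so the truth stays as close to the template as
        # the dynamics allow instead of wandering to the min-torque spread
        x = None
        for rho in (1.0, 1.5, 2.0, 4.0, 8.0, 16.0, None):
            x = _node_kinetics(
                B[i],
                Jc[i],
                [Jm[i, foot_mi[f]] for f in here],
                rhs[i] / fs,
                tpls,
                mu=plan.mu,
                band=None if rho is None else grf_params.band * rho,
                band_floor=(1.0 if rho is None else rho) / fs,
            )
            if x is not None:
                if rho is None or rho > 1.0:
                    band_relaxed += 1
                    relaxed_nodes.append((k, rho))
                    max_inflation = max(max_inflation, np.inf if rho is None else rho)
                break
        if x is None:
            raise GenerationError(f"node {k}: no feasible exact force distribution")
        x = x * fs
        tau[i] = x[:ntau]
        lamc[i] = x[ntau : ntau + nr]
        for j, f in enumerate(here):
            lam = x[ntau + nr + 3 * j : ntau + nr + 3 * j + 3]
            lam_world[(f, k)] = lam
            min_fz = min(min_fz, lam[2])
            band_dev = max(band_dev, float(np.abs(lam - tpls[j] * fs).max()))

    # verify the residual actually vanishes
    w = rhs - np.einsum("kni,ki->kn", B, tau) - np.einsum("krn,kr->kn", Jc, lamc)
    for (f, k), lam in lam_world.items():
        w[k - 1] -= Jm[k - 1, foot_mi[f]].T @ lam
    w_max = float(np.abs(w).max() / fs)
    if w_max > w_tol:
        raise GenerationError(f"dynamics residual {w_max:.2e} exceeds tolerance {w_tol:.1e}")
    if min_fz < -1e-6:
        raise GenerationError(f"truth vertical GRF dips to {min_fz:.3f} N (< 0)")

    # truth profile per foot over the main (longest) stance; the template
    # prior covers every scheduled stance (start nodes may be negative for
    # stances already under way at the trial start)
    truth_forces, prior_forces, prior_all = {}, {}, {}
    stride_nodes = int(round(p.stride_time / h))
    for f in feet:
        nodes = _longest_run([k for k in plan.stance_nodes(f) if 1 <= k <= N])
        arr = np.array([lam_world[(f, k)] for k in nodes])
        truth_forces[f] = GRFProfile(arr, h, foot=f, start_node=nodes[0])
        k0 = int(round(_LEG_OFFSET[f[:2]] * p.stride_time / h))
        profs = []
        for rep in (-1, 0, 1):
            a = k0 + rep * stride_nodes
            b = a + n_st + 1
            if b <= 0 or a > N:
                continue
            profs.append(
                synth_sinusoidal_grf(
                    grf_params,
                    p.speed,
                    model.total_mass,
                    (a, b),
                    h,
                    foot=f,
                    gravity=model.gravity,
                )
            )
        prior_all[f] = profs
        main_iv = max(plan.stance[f], key=lambda ab: ab[1] - ab[0])
        prior_forces[f] = max(
            profs, key=lambda pr: min(pr.start_node + len(pr.forces), N + 1) - max(pr.start_node, 0)
        )
    trial = SyntheticTrial(
        model=model,
        params=params,
        grf_params=grf_params,
        contact=plan,
        Q=Q,
        dq0=dq0,
        qd=qd,
        qdd=qdd,
        tau=tau,
        lambda_c=lamc,
        lam_world=lam_world,
        truth_forces=truth_forces,
        prior_forces=prior_forces,
        prior_all=prior_all,
        cameras={},
        observations=[],
        diagnostics={
            "max_w_normalised": w_max,
            "min_truth_fz_n": float(min_fz),
            "max_template_deviation_n": band_dev,
            "band_relaxed_nodes": band_relaxed,
            "relaxed_node_ids": relaxed_nodes,
        },
    )
    return trial


def make_camera_rig(image_size=(1920, 1080), focal: float = 1400.0) -> dict:
    """Four synthetic fisheye cameras: two near-side, two far-side (0.6 weight)."""

    def lookat(pos, target):
        pos, target = np.asarray(pos, float), np.asarray(target, float)
        fwd = target - pos
        fwd /= np.linalg.norm(fwd)
        right = np.cross(fwd, [0.0, 0.0, 1.0])
        right /= np.linalg.norm(right)
        down = np.cross(fwd, right)
        R = np.stack([right, down, fwd])
        return R, -R @ pos

    target = (0.55, 0.0, 0.35)
    spots = {
        "near1": ((0.0, -3.0, 0.8), 1.0),
        "near2": ((1.1, -3.0, 0.8), 1.0),
        "far1": ((0.2, 3.0, 1.1), 0.6),
        "far2": ((0.9, 3.0, 1.1), 0.6),
    }
    cams = {}
    for name, (pos, conf) in spots.items():
        R, t = lookat(pos, target)
        cams[name] = CameraModel(
            K=(focal, focal, image_size[0] / 2, image_size[1] / 2),
            R=R,
            t=t,
            dist=(-0.04, 0.008, 0.0, 0.0),
            image_size=image_size,
            confidence_scale=conf,
            name=name,
        )
    return cams


def render_observations(
    trial: SyntheticTrial,
    cameras: dict,
    noise_px: float = 0.0,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list:
    """Project truth markers into every camera with noise and dropout.

    Markers behind a camera or outside its image are absent; visible ones
    get isotropic pixel noise and a confidence score that decays with the
    noise actually drawn (1.0 at zero noise).
    """
    rng = rng or np.random.default_rng(0)
    X = trial.markers
    names = trial.model.marker_names
    obs = []
    for cam_name, cam in cameras.items():
        for k in range(X.shape[0]):
            try:
                px = project(cam, X[k])
            except BehindCameraError:
                continue
            for j, name in enumerate(names):
                u, v = px[j]
                if not (0 <= u < cam.image_size[0] and 0 <= v < cam.image_size[1]):
                    continue
                if dropout > 0 and rng.random() < dropout:
                    continue
                if noise_px > 0:
                    eta = rng.normal(0.0, noise_px, 2)
                    conf = float(np.exp(-(eta @ eta) / (4.0 * noise_px**2)))
                    u, v = u + eta[0], v + eta[1]
                else:
                    conf = 1.0
                obs.append(
                    Observation2D(
                        frame=k,
                        camera=cam_name,
                        marker=name,
                        pixel=(float(u), float(v)),
                        confidence=conf,
                        visible=True,
                    )
                )
    return obs


def generate_trial(
    seed: int = 0,
    noise_px: float = 0.0,
    dropout: float = 0.0,
    model: SkeletonModel | None = None,
    params: GaitParams | None = None,
    grf_params: GRFSynthesisParams | None = None,
) -> SyntheticTrial:
    """Full trial: truth gait + camera rig + rendered noisy observations.

    The truth is seed-independent; the seed drives only observation noise
    and dropout, and the trial regenerates bit-identically from
    (parameters, seed).
    """
    trial = generate_gait(model=model, params=params, grf_params=grf_params)
    trial.cameras = make_camera_rig()
    rng = np.random.default_rng(seed)
    trial.observations = render_observations(
        trial, trial.cameras, noise_px=noise_px, dropout=dropout, rng=rng
    )
    trial.seed = seed
    trial.noise_px = noise_px
    trial.dropout = dropout
    return trial
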