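"""Kinetic full trajectory estimation: the contact-constrained NLP.

One nonlinear program estimates, for every trajectory node k, the
generalized coordinates q_k together with joint torques tau_k, joint
geometry constraint torques lambda_c,k and ground reaction forces
lambda_g,k (split into nonnegative tangential pairs), subject to

* backward-Euler integration  q_k = q_{k-1} + h qd_k,  qd_k = qd_{k-1} + h qdd_k,
* the equation of motion with a disturbance w_k (reported, heavily penalised),
* joint-geometry equalities at every node,
* no-slip boxes |v_foot| <= eps and the friction pyramid on stance nodes,
* in sinusoidal mode, per-node box bands (+-20%) around a synthesised GRF
  template; freeform mode leaves the GRF unconstrained beyond feasibility.

The cost is  alpha1 sum robust(v / sigma) + alpha2 sum w^2
+ alpha3 (10 sum tau^2 + 0.1 h^2 sum xddot^2) + slack and split penalties,
with a redescending robust kernel on normalised reprojection errors.

Implementation notes.  The integration equalities are eliminated
analytically: qd_k and qdd_k are the backward differences of the stored
q_k (plus an explicit initial-velocity variable qd_0), so those constraints
hold to machine precision by construction and the decision vector shrinks
to (q nodes, qd_0, tau, lambda_c, lambda_g, eps).  The reprojection error v
and the marker positions x are likewise closed-form functions of q.  At fixed
kinematics the force variables decouple into small per-node convex QPs
that are minimised out exactly (envelope theorem); the reduced problem is
solved by scipy's trust-constr with sparse analytic Jacobians (batched
complex-step differentiation of the dynamics) and a Schur-complement
Gauss-Newton Hessian.  All forces and torques are normalised by body
weight (length scale 1 m) inside the solver and un-normalised on
extraction.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, NonlinearConstraint, least_squares, minimize
from scipy.signal import savgol_filter

from kfte import multibody as _mb
from kfte.camera import (
    BehindCameraError,
    CameraModel,
    DegenerateGeometryError,
    Observation2D,
    project,
    triangulate,
)
from kfte.contact import ContactPlan, GRFProfile, recombine_tangential, split_tangential
from kfte.multibody import SkeletonModel

log = logging.getLogger(__name__)

__all__ = [
    "CostWeights",
    "ObservationNoise",
    "KFTEProblem",
    "KFTESolution",
    "AssembledNLP",
    "redescending_cost",
    "build_problem",
    "seed_initializer",
    "solve",
]

# maps the 5-component split (fx+, fx-, fy+, fy-, fz) to a world 3-vector
_SPLIT = np.array(
    [[1.0, -1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0, 0.0], [0.0, 0.0, 0.0, 0.0, 1.0]]
)


def _prior_profiles(prior_entry):
    """A foot's GRF prior may be one profile or a list (one per stance)."""
    return list(prior_entry) if isinstance(prior_entry, (list, tuple)) else [prior_entry]


def _prior_sample(prior_entry, node: int):
    """(template force sample, owning profile) for a trajectory node.

    Picks the stance profile whose node range contains ``node`` (stance
    start nodes may be negative for stances that began before the trial);
    falls back to the nearest profile's edge sample.
    """
    profs = _prior_profiles(prior_entry)
    for p in profs:
        i = node - p.start_node
        if 0 <= i < len(p.forces):
            return p.forces[i], p
    best = min(
        profs,
        key=lambda p: min(abs(node - p.start_node), abs(node - (p.start_node + len(p.forces) - 1))),
    )
    i = int(np.clip(node - best.start_node, 0, len(best.forces) - 1))
    return best.forces[i], best


# ---------------------------------------------------------------------------
# cost pieces


@dataclass
class CostWeights:
    """Weights of the NLP objective.

    alpha_meas/alpha_model/alpha_smooth are the three headline weights
    (1, 10000, 1); within the smoothness term torques carry weight 10 and
    marker accelerations 0.1 (times h^2).  ``knots`` are the redescending
    kernel knots (a, b, c) in sigma units; ``slack_weight`` penalises the
    no-slip slack; ``split_reg`` is a tiny regulariser on the nonnegative
    tangential split pairs removing their null direction.
    """

    alpha_meas: float = 1.0
    alpha_model: float = 10000.0
    alpha_smooth: float = 1.0
    torque_weight: float = 10.0
    accel_weight: float = 0.1
    slack_weight: float = 1000.0
    knots: tuple = (3.0, 10.0, 20.0)
    split_reg: float = 1e-6

    def __post_init__(self) -> None:
        a, b, c = self.knots
        if not 0 < a < b < c:
            raise ValueError("knots must satisfy 0 < a < b < c")
        for w in (
            self.alpha_meas,
            self.alpha_model,
            self.alpha_smooth,
            self.torque_weight,
            self.accel_weight,
            self.slack_weight,
        ):
            if w < 0:
                raise ValueError("weights must be nonnegative")


@dataclass
class ObservationNoise:
    """Pixel-error scale sigma per observation.

    sigma = sigma_base / max(confidence, floor), overridable per marker.
    """

    sigma_base: float = 5.0
    confidence_floor: float = 0.1
    per_marker: Mapping[str, float] = field(default_factory=dict)

    def sigma(self, marker: str, confidence: float) -> float:
        base = float(self.per_marker.get(marker, self.sigma_base))
        if base <= 0:
            raise ValueError("sigma must be > 0")
        return base / max(confidence, self.confidence_floor)


def redescending_cost(e, knots=(3.0, 10.0, 20.0)):
    """Redescending robust kernel: quadratic, then linear, then saturating.

    For knots 0 < a < b < c:  e^2/2 on |e| <= a;  a|e| - a^2/2 on (a, b];
    a quadratic ease-out with slope a (c - |e|)/(c - b) on (b, c]; constant
    beyond c.  Even, continuous, with continuous first derivative.
    """
    a, b, c = knots
    if not 0 < a < b < c:
        raise ValueError("knots must satisfy 0 < a < b < c")
    x = np.abs(np.asarray(e, float))
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.where(x <= a, 0.5 * x * x, a * x - 0.5 * a * a)
    vb = a * b - 0.5 * a * a
    ease = vb + 0.5 * a * ((c - b) - (c - np.minimum(x, c)) ** 2 / (c - b))
    out = np.where(x > b, np.where(x <= c, ease, vb + 0.5 * a * (c - b)), out)
    return float(out[0]) if scalar else out


def _redescending_psi(x, knots):
    """d(kernel)/d|e| (nonnegative)."""
    a, b, c = knots
    x = np.asarray(x, float)
    psi = np.where(x <= a, x, a)
    return np.where(x > b, np.where(x <= c, a * (c - x) / (c - b), 0.0), psi)


# ---------------------------------------------------------------------------
# problem containers


@dataclass
class KFTEProblem:
    """All inputs of one estimation run.

    ``grf_prior`` maps foot marker names to synthesised
    :class:`kfte.contact.GRFProfile` templates; it must be present iff the
    run is solved in sinusoidal mode.
    """

    model: SkeletonModel
    cameras: Mapping[str, CameraModel]
    observations: Sequence[Observation2D]
    contact: ContactPlan
    n_nodes: int
    h: float
    grf_prior: Mapping[str, GRFProfile] | None = None
    weights: CostWeights = field(default_factory=CostWeights)
    noise: ObservationNoise = field(default_factory=ObservationNoise)
    band_fraction: float = 0.20  # fractional half-width of the GRF band
    band_floor_n: float = 1.0  # absolute half-width floor, N
    fz_floor_n: float = 1e-3  # strict positivity floor for stance Fz, N

    def __post_init__(self) -> None:
        if self.h <= 0 or self.n_nodes < 2:
            raise ValueError("need h > 0 and at least 2 nodes")
        for o in self.observations:
            if o.camera not in self.cameras:
                raise ValueError(f"observation references unknown camera {o.camera!r}")
            if o.marker not in self.model.marker_names:
                raise ValueError(f"observation references unknown marker {o.marker!r}")
            if not 0 <= o.frame <= self.n_nodes:
                raise ValueError(f"observation frame {o.frame} outside [0, {self.n_nodes}]")


@dataclass
class KFTESolution:
    """Estimated trajectory, forces and diagnostics (physical units)."""

    q: np.ndarray  # (N+1, nq)
    dq: np.ndarray  # (N+1, nq)
    ddq: np.ndarray  # (N+1, nq); row 0 mirrors row 1 (dynamics start at k=1)
    tau: np.ndarray  # (N+1, ntau) newton-metres; row 0 zero
    w: np.ndarray  # (N+1, nq) disturbance; row 0 zero
    lambda_c: np.ndarray  # (N+1, nr); row 0 zero
    forces: dict  # foot -> GRFProfile over its stance (nodes >= 1)
    markers: np.ndarray  # (N+1, M, 3)
    residuals_px: dict  # camera -> (n_obs, 2) reprojection residual v
    eps: dict  # (foot, interval) -> slack value m/s
    status: str = ""
    success: bool = False
    objective: float = np.nan
    decomposition: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# variable layout


class _Layout:
    """Index bookkeeping for the packed decision vector z.

    Order: q nodes 0..N, qd_0, tau 1..N, lambda_c 1..N, lambda_g split per
    (foot, stance node >= 1), eps per (foot, stance interval).
    """

    def __init__(self, problem: KFTEProblem):
        m = problem.model
        N = problem.n_nodes
        self.nq, self.N, self.ntau, self.nr = m.nq, N, m.ntau, m.n_joint_residuals
        o = (N + 1) * self.nq
        self.dq0 = o
        o += self.nq
        self.tau0 = o
        o += N * self.ntau
        self.lamc0 = o
        o += N * self.nr
        self.lam_index = {}
        self.foot_nodes = {}
        for foot in problem.contact.feet():
            nodes = [int(k) for k in problem.contact.stance_nodes(foot) if 1 <= k <= N]
            self.foot_nodes[foot] = nodes
            for k in nodes:
                self.lam_index[(foot, k)] = o
                o += 5
        self.eps_index = {}
        for foot, ivs in problem.contact.stance.items():
            for i in range(len(ivs)):
                self.eps_index[(foot, i)] = o
                o += 1
        self.n = o

    def q(self, k):
        return slice(k * self.nq, (k + 1) * self.nq)

    def tau(self, k):
        return slice(self.tau0 + (k - 1) * self.ntau, self.tau0 + k * self.ntau)

    def lamc(self, k):
        return slice(self.lamc0 + (k - 1) * self.nr, self.lamc0 + k * self.nr)

    def lam(self, foot, k):
        o = self.lam_index[(foot, k)]
        return slice(o, o + 5)

    def eps_of(self, problem, foot, k):
        for i, (a, b) in enumerate(problem.contact.stance[foot]):
            if a <= k < b:
                return self.eps_index[(foot, i)]
        raise KeyError((foot, k))

    def unpack_q(self, z):
        return z[: (self.N + 1) * self.nq].reshape(self.N + 1, self.nq)

    def census(self) -> dict:
        return {
            "q": (self.N + 1) * self.nq,
            "dq0": self.nq,
            "tau": self.N * self.ntau,
            "lambda_c": self.N * self.nr,
            "lambda_g": 5 * len(self.lam_index),
            "eps": len(self.eps_index),
            "total": self.n,
        }


# ---------------------------------------------------------------------------
# assembled NLP


class AssembledNLP:
    """The K-FTE nonlinear program in scipy form.

    Exposes ``objective``/``gradient``/``hessian``, the nonlinear constraint
    block (joint-geometry equalities + no-slip inequalities) with a sparse
    Jacobian, the linear friction-pyramid/GRF-band constraints, simple
    bounds, and the variable census.
    """

    def __init__(self, problem: KFTEProblem, mode: str = "sinusoidal"):
        if mode not in ("sinusoidal", "freeform"):
            raise ValueError("mode must be 'sinusoidal' or 'freeform'")
        if mode == "sinusoidal" and not problem.grf_prior:
            raise ValueError("sinusoidal mode requires grf_prior profiles")
        self.problem = problem
        self.mode = mode
        self.layout = _Layout(problem)
        self.model = problem.model
        self.N = problem.n_nodes
        self.h = problem.h
        self.force_scale = self.model.total_mass * self.model.gravity
        self._cache = {}
        self.hessian_damping = 1e-2
        self._prep_observations()
        self._prep_linear()
        self._prep_slip_rows()
        self.n_variables = self.layout.n

    # -- observation tables -------------------------------------------------
    def _prep_observations(self):
        p = self.problem
        tables = {}
        for name, cam in p.cameras.items():
            obs = [o for o in p.observations if o.camera == name and o.visible]
            if not obs:
                continue
            tables[name] = {
                "camera": cam,
                "frames": np.array([o.frame for o in obs], int),
                "markers": np.array([p.model.marker_index(o.marker) for o in obs], int),
                "pixels": np.array([o.pixel for o in obs], float),
                "scale": cam.confidence_scale
                / np.array([p.noise.sigma(o.marker, o.confidence) for o in obs]),
            }
        self.obs_tables = tables
        self.n_observations = sum(len(t["frames"]) for t in tables.values())

    # -- linear constraints and bounds ---------------------------------------
    def _prep_linear(self):
        p, lay = self.problem, self.layout
        fs = self.force_scale
        lb = np.full(lay.n, -np.inf)
        ub = np.full(lay.n, np.inf)
        rows, cols, vals, c_lb, c_ub = [], [], [], [], []
        r = 0
        for (foot, k), o in lay.lam_index.items():
            lb[o : o + 4] = 0.0
            lb[o + 4] = p.fz_floor_n / fs
            for pair in ((0, 1), (2, 3)):  # friction pyramid
                rows += [r, r, r]
                cols += [o + 4, o + pair[0], o + pair[1]]
                vals += [p.contact.mu, -1.0, -1.0]
                c_lb.append(0.0)
                c_ub.append(np.inf)
                r += 1
            if self.mode == "sinusoidal":
                # band only constrains components the template actually uses;
                # for straight-line trials the lateral template is identically
                # zero, so F_y stays free (within the pyramid)
                f, prior = _prior_sample(p.grf_prior[foot], k)
                delta = p.band_fraction * np.abs(f) + p.band_floor_n
                nonzero = np.abs(prior.forces).max(axis=0) > 1e-9
                for comp, (ci, cj) in zip((0, 1), ((0, 1), (2, 3))):  # x, y
                    if not nonzero[comp]:
                        continue
                    rows += [r, r]
                    cols += [o + ci, o + cj]
                    vals += [1.0, -1.0]
                    c_lb.append((f[comp] - delta[comp]) / fs)
                    c_ub.append((f[comp] + delta[comp]) / fs)
                    r += 1
                lb[o + 4] = max(lb[o + 4], (f[2] - delta[2]) / fs)
                ub[o + 4] = (f[2] + delta[2]) / fs
        for idx in lay.eps_index.values():
            lb[idx], ub[idx] = 0.0, 1.0
        self.bounds = Bounds(lb, ub)
        if r:
            A = sp.csr_matrix((vals, (rows, cols)), shape=(r, lay.n))
            self.linear_constraint = LinearConstraint(A, np.array(c_lb), np.array(c_ub))
        else:
            self.linear_constraint = None
        self.n_linear_rows = r

    def _prep_slip_rows(self):
        # (foot, node, marker_index, eps variable index), nodes >= 1
        self.slip_entries = [
            (foot, k, self.model.marker_index(foot), self.layout.eps_of(self.problem, foot, k))
            for foot, nodes in self.layout.foot_nodes.items()
            for k in nodes
        ]
        self.n_joint_rows = (self.N + 1) * self.layout.nr
        self.n_slip_rows = 6 * len(self.slip_entries)

    def census(self) -> dict:
        """Variable and constraint counts of the assembled program."""
        c = self.layout.census()
        c.update(
            {
                "joint_constraint_rows": self.n_joint_rows,
                "slip_rows": self.n_slip_rows,
                "linear_rows": self.n_linear_rows,
                "observation_residuals": 2 * self.n_observations,
            }
        )
        return c

    # -- shared evaluation (cached on z) --------------------------------------
    def _core(self, z):
        key = hash(z.tobytes())
        if self._cache.get("key") == key:
            return self._cache
        p, lay, m = self.problem, self.layout, self.model
        N, h, fs = self.N, self.h, self.force_scale
        Q = lay.unpack_q(z)
        dq0 = z[lay.dq0 : lay.dq0 + lay.nq]
        qd = np.empty_like(Q)
        qd[0] = dq0
        qd[1:] = (Q[1:] - Q[:-1]) / h
        qdd = (qd[1:] - qd[:-1]) / h  # nodes 1..N
        fk = _mb.forward_kinematics(m, Q)
        X = fk.markers
        tau = z[lay.tau0 : lay.tau0 + N * lay.ntau].reshape(N, lay.ntau)
        lamc = z[lay.lamc0 : lay.lamc0 + N * lay.nr].reshape(N, lay.nr)
        lam_split = {fk_: z[lay.lam(fk_[0], fk_[1])] for fk_ in lay.lam_index}

        Q1 = Q[1:]
        f_id = _mb.inverse_dynamics(m, Q1, qd[1:], qdd) / fs
        B = _mb.input_map(m, Q1)
        applied = np.einsum("kni,ki->kn", B, tau)
        if lay.nr:
            Jc = _mb.joint_constraint_jacobian(m, Q1)
            applied += np.einsum("krn,kr->kn", Jc, lamc)
        else:
            Jc = np.zeros((N, 0, lay.nq))
        Jmk = _mb.marker_jacobians(m, Q1)  # (N, M, 3, nq)
        for (foot, k), lam5 in lam_split.items():
            mi = m.marker_index(foot)
            applied[k - 1] += Jmk[k - 1, mi].T @ (_SPLIT @ lam5)
        w = f_id - applied  # normalised disturbance at nodes 1..N

        cache = {
            "key": key,
            "Q": Q,
            "dq0": dq0,
            "qd": qd,
            "qdd": qdd,
            "X": X,
            "tau": tau,
            "lamc": lamc,
            "lam_split": lam_split,
            "B": B,
            "Jc": Jc,
            "Jmk": Jmk,
            "w": w,
        }
        self._cache = cache
        return cache

    def _jacobians(self, z):
        """Jacobian blocks of w_k (normalised) w.r.t. local variables."""
        c = self._core(z)
        if "A_q" in c:
            return c
        m, lay, h, fs = self.model, self.layout, self.h, self.force_scale
        Q1, qd1, qdd = c["Q"][1:], c["qd"][1:], c["qdd"]
        tau, lamc, lam_split = c["tau"], c["lamc"], c["lam_split"]
        N = self.N

        # world ground force per node for the applied-force derivative
        lamw = np.zeros((N, len(m.markers), 3))
        for (foot, k), lam5 in lam_split.items():
            lamw[k - 1, m.marker_index(foot)] += _SPLIT @ lam5

        def res_q(Qp):
            # w as a function of q_k only (qd, qdd, multipliers fixed)
            fid = _mb.inverse_dynamics(m, Qp, qd1[:, None, :], qdd[:, None, :]) / fs
            app = np.einsum("kpni,ki->kpn", _mb.input_map(m, Qp), tau)
            if lay.nr:
                app += np.einsum("kprn,kr->kpn", _mb.joint_constraint_jacobian(m, Qp), lamc)
            Jm = _mb.marker_jacobians(m, Qp)
            app += np.einsum("kpmin,kmi->kpn", Jm, lamw)
            return fid - app

        hstep = 1e-200
        eye = np.eye(lay.nq)
        Qp = Q1[:, None, :] + 1j * hstep * eye
        A_q = np.swapaxes(res_q(Qp).imag, 1, 2) / hstep  # (N, nq, nq)

        def id_v(Vp):
            return _mb.inverse_dynamics(m, Q1[:, None, :], Vp, qdd[:, None, :]) / fs

        Vp = qd1[:, None, :] + 1j * hstep * eye
        A_v = np.swapaxes(id_v(Vp).imag, 1, 2) / hstep
        M_n = _mb.mass_matrix(m, Q1) / fs

        c["A_q"], c["A_v"], c["M_n"] = A_q, A_v, M_n
        # chain through backward differences: w_k depends on
        #   q_k:        A_q + A_v/h + M/h^2
        #   q_{k-1}:   -A_v/h - 2M/h^2     (k>=2);  -A_v/h - M/h^2 (k=1)
        #   q_{k-2}:    M/h^2              (k>=2)
        #   qd_0:      -M/h                (k=1)
        c["dw_qk"] = A_q + A_v / h + M_n / h**2
        c["dw_qk1"] = -A_v / h - 2.0 * M_n / h**2
        c["dw_qk1"][0] = -A_v[0] / h - M_n[0] / h**2
        c["dw_qk2"] = M_n / h**2  # valid for k >= 2
        c["dw_dq0"] = -M_n[0] / h

        # marker jacobians at all nodes (for measurement + smoothness terms)
        c["JmAll"] = _mb.marker_jacobians(m, c["Q"])
        return c

    # -- objective -------------------------------------------------------------
    def objective_parts(self, z) -> dict:
        c = self._core(np.asarray(z, float))
        p, W = self.problem, self.problem.weights
        X = c["X"]
        e_meas = 0.0
        for t in self.obs_tables.values():
            try:
                pts = X[t["frames"], t["markers"]]
                v = t["pixels"] - project(t["camera"], pts)
            except BehindCameraError:
                e_meas = np.inf  # line-search trial far outside the scene
                break
            e = t["scale"][:, None] * v
            e_meas += float(np.sum(redescending_cost(e.ravel(), W.knots)))
        e_model = float(np.sum(c["w"] ** 2))
        d2x = X[2:] - 2.0 * X[1:-1] + X[:-2]
        e_smooth = W.torque_weight * float(np.sum(c["tau"] ** 2)) + W.accel_weight * float(
            np.sum(d2x**2)
        ) / self.h**2
        eps_vals = z[list(self.layout.eps_index.values())] if self.layout.eps_index else np.zeros(0)
        e_slack = float(np.sum(np.asarray(eps_vals) ** 2))
        e_reg = sum(float(np.sum(l5[:4] ** 2)) for l5 in c["lam_split"].values())
        total = (
            W.alpha_meas * e_meas
            + W.alpha_model * e_model
            + W.alpha_smooth * e_smooth
            + W.slack_weight * e_slack
            + W.split_reg * e_reg
        )
        return {
            "e_meas": e_meas,
            "e_model": e_model,
            "e_smooth": e_smooth,
            "e_slack": e_slack,
            "e_reg": e_reg,
            "objective": total,
        }

    def objective(self, z) -> float:
        return self.objective_parts(z)["objective"]

    def gradient(self, z) -> np.ndarray:
        g, _ = self._grad_hess(np.asarray(z, float), want_hess=False)
        return g

    def hessian(self, z):
        _, H = self._grad_hess(np.asarray(z, float), want_hess=True)
        return H

    def _grad_hess(self, z, want_hess: bool):
        key = ("gh", hash(z.tobytes()), getattr(self, "model_hessian_S", None) is not None)
        if self._cache.get("gh_key") == key and (not want_hess or "H" in self._cache):
            return self._cache["g"], self._cache.get("H")
        c = self._jacobians(z)
        p, lay, W = self.problem, self.layout, self.problem.weights
        h, N, nq = self.h, self.N, lay.nq
        g = np.zeros(lay.n)
        trips_r, trips_c, trips_v = [], [], []

        def add_block(H_loc, idx):
            ii, jj = np.meshgrid(idx, idx, indexing="ij")
            trips_r.append(ii.ravel())
            trips_c.append(jj.ravel())
            trips_v.append(H_loc.ravel())

        X, JmAll = c["X"], c["JmAll"]
        M_markers = X.shape[1]

        # measurement term -------------------------------------------------
        hstep = 1e-200
        eye3 = np.eye(3)
        meas_g = np.zeros((N + 1, nq))
        meas_H = np.zeros((N + 1, nq, nq)) if want_hess else None
        for t in self.obs_tables.values():
            fr, mk = t["frames"], t["markers"]
            pts = X[fr, mk]
            cam = t["camera"]
            v = t["pixels"] - project(cam, pts)
            e = t["scale"][:, None] * v  # (n, 2)
            Pp = project(cam, pts[:, None, :] + 1j * hstep * eye3)
            Jp = np.swapaxes(Pp.imag, 1, 2) / hstep  # (n, 2, 3)
            Je = -t["scale"][:, None, None] * np.einsum("nij,njq->niq", Jp, JmAll[fr, mk])
            absd = np.abs(e)
            dC = _redescending_psi(absd, W.knots) * np.sign(e)
            gn = W.alpha_meas * np.einsum("ni,niq->nq", dC, Je)
            np.add.at(meas_g, fr, gn)
            if want_hess:
                wgt = np.where(absd > 1e-12, _redescending_psi(absd, W.knots) / np.maximum(absd, 1e-12), 1.0)
                Hn = W.alpha_meas * np.einsum("niq,ni,nir->nqr", Je, wgt, Je)
                np.add.at(meas_H, fr, Hn)
        for k in range(N + 1):
            g[lay.q(k)] += meas_g[k]
            if want_hess and meas_H is not None:
                add_block(meas_H[k], np.arange(k * nq, (k + 1) * nq))

        # model term ---------------------------------------------------------
        w = c["w"]
        a2 = W.alpha_model
        S_nodes = getattr(self, "model_hessian_S", None)
        for k in range(1, N + 1):
            i = k - 1
            blocks = [(lay.q(k), c["dw_qk"][i]), (lay.q(k - 1), c["dw_qk1"][i])]
            if k >= 2:
                blocks.append((lay.q(k - 2), c["dw_qk2"][i]))
            else:
                blocks.append((slice(lay.dq0, lay.dq0 + nq), c["dw_dq0"]))
            kin_blocks = list(blocks)
            blocks.append((lay.tau(k), -c["B"][i]))
            if lay.nr:
                blocks.append((lay.lamc(k), -np.swapaxes(c["Jc"], 1, 2)[i]))
            for foot in lay.foot_nodes:
                if (foot, k) in lay.lam_index:
                    mi = self.model.marker_index(foot)
                    blocks.append((lay.lam(foot, k), -(c["Jmk"][i, mi].T @ _SPLIT)))
            idx = np.concatenate([np.arange(s.start, s.stop) for s, _ in blocks])
            Jloc = np.concatenate([b for _, b in blocks], axis=1)  # (nq, nloc)
            g[idx] += 2.0 * a2 * Jloc.T @ w[i]
            if want_hess:
                if S_nodes is not None:
                    # Schur-reduced curvature: the force variables re-optimise
                    # in response to kinematic steps, which weakens the
                    # dynamics-penalty curvature along supported directions
                    idx_k = np.concatenate([np.arange(s.start, s.stop) for s, _ in kin_blocks])
                    Jk = np.concatenate([b for _, b in kin_blocks], axis=1)
                    add_block(2.0 * a2 * Jk.T @ S_nodes[i] @ Jk, idx_k)
                else:
                    add_block(2.0 * a2 * Jloc.T @ Jloc, idx)

        # smoothness ---------------------------------------------------------
        coef = W.alpha_smooth * W.accel_weight / h**2
        d2x = X[2:] - 2.0 * X[1:-1] + X[:-2]  # (N-1, M, 3)
        for k in range(1, N):
            r = d2x[k - 1].ravel()
            Jk = JmAll[k].reshape(3 * M_markers, nq)
            Jkm = JmAll[k - 1].reshape(3 * M_markers, nq)
            Jkp = JmAll[k + 1].reshape(3 * M_markers, nq)
            g[lay.q(k - 1)] += 2.0 * coef * Jkm.T @ r
            g[lay.q(k)] += -4.0 * coef * Jk.T @ r
            g[lay.q(k + 1)] += 2.0 * coef * Jkp.T @ r
            if want_hess:
                Jloc = np.concatenate([Jkm, -2.0 * Jk, Jkp], axis=1)
                idx = np.arange((k - 1) * nq, (k + 2) * nq)
                add_block(2.0 * coef * Jloc.T @ Jloc, idx)

        # torques, slacks, split regulariser ----------------------------------
        tcoef = 2.0 * W.alpha_smooth * W.torque_weight
        g[lay.tau0 : lay.tau0 + N * lay.ntau] += tcoef * z[lay.tau0 : lay.tau0 + N * lay.ntau]
        eps_idx = np.array(list(lay.eps_index.values()), int)
        if eps_idx.size:
            g[eps_idx] += 2.0 * W.slack_weight * z[eps_idx]
        for (foot, k), o in lay.lam_index.items():
            g[o : o + 4] += 2.0 * W.split_reg * z[o : o + 4]
        if want_hess:
            diag = np.zeros(lay.n)
            diag[lay.tau0 : lay.tau0 + N * lay.ntau] += tcoef
            if eps_idx.size:
                diag[eps_idx] += 2.0 * W.slack_weight
            for o in lay.lam_index.values():
                diag[o : o + 4] += 2.0 * W.split_reg
            didx = np.where(diag)[0]
            trips_r.append(didx)
            trips_c.append(didx)
            trips_v.append(diag[didx])

        H = None
        if want_hess:
            # small Levenberg damping keeps the Gauss-Newton Hessian
            # uniformly positive definite (the split pairs and qd_0 are
            # otherwise nearly flat)
            damp = sp.identity(lay.n, format="csr") * self.hessian_damping
            H = sp.coo_matrix(
                (np.concatenate(trips_v), (np.concatenate(trips_r), np.concatenate(trips_c))),
                shape=(lay.n, lay.n),
            ).tocsr() + damp
            self._cache["H"] = H
        self._cache["gh_key"] = key
        self._cache["g"] = g
        return g, H

    # -- nonlinear constraints --------------------------------------------------
    def constraint_fun(self, z) -> np.ndarray:
        c = self._core(np.asarray(z, float))
        m, lay = self.model, self.layout
        out = [
            _mb.joint_constraint_residuals(m, c["Q"]).ravel()
            if lay.nr
            else np.zeros(0)
        ]
        qd = c["qd"]
        for foot, k, mi, ei in self.slip_entries:
            vf = np.einsum("in,n->i", c["JmAll"][k, mi] if "JmAll" in c else _mb.marker_jacobians(m, c["Q"][k])[mi], qd[k])
            eps = z[ei]
            out.append(vf - eps)
            out.append(-vf - eps)
        return np.concatenate(out) if out else np.zeros(0)

    def constraint_jac(self, z):
        c = self._jacobians(np.asarray(z, float))
        m, lay = self.model, self.layout
        nq, N = lay.nq, self.N
        rows, cols, vals = [], [], []
        r = 0
        if lay.nr:
            JcAll = _mb.joint_constraint_jacobian(m, c["Q"])  # (N+1, nr, nq)
            for k in range(N + 1):
                blk = JcAll[k]
                ii, jj = np.nonzero(blk)
                rows.append(r + ii)
                cols.append(k * nq + jj)
                vals.append(blk[ii, jj])
                r += lay.nr
        # slip rows
        hstep = 1e-200
        eye = np.eye(nq)
        qd = c["qd"]
        for foot, k, mi, ei in self.slip_entries:
            Jg = c["JmAll"][k, mi]  # (3, nq)
            # d(Jg(q_k) qd_k)/dq_k at fixed qd
            def f(Qp, mi=mi, u=qd[k]):
                return np.einsum("pin,n->pi", _mb.marker_jacobians(m, Qp)[:, mi], u)

            Qp = c["Q"][k][None, :] + 1j * hstep * eye
            dJq = (f(Qp).imag / hstep).T  # (3, nq)
            d_qk = dJq + Jg / self.h
            d_qk1 = -Jg / self.h if k >= 1 else None
            d_dq0 = None
            if k == 0:  # cannot happen (slip nodes start at 1) but keep safe
                d_dq0 = Jg
            for sign in (1.0, -1.0):
                for i in range(3):
                    rows.append(np.full(nq, r))
                    cols.append(np.arange(k * nq, (k + 1) * nq))
                    vals.append(sign * d_qk[i])
                    if d_qk1 is not None:
                        rows.append(np.full(nq, r))
                        cols.append(np.arange((k - 1) * nq, k * nq))
                        vals.append(sign * d_qk1[i])
                    rows.append(np.array([r]))
                    cols.append(np.array([ei]))
                    vals.append(np.array([-1.0]))
                    r += 1
        if not rows:
            return sp.csr_matrix((0, lay.n))
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(r, lay.n),
        ).tocsr()

    def nonlinear_constraint(self) -> NonlinearConstraint:
        nj, ns = self.n_joint_rows, self.n_slip_rows
        lb = np.concatenate([np.zeros(nj), np.full(ns, -np.inf)])
        ub = np.concatenate([np.zeros(nj), np.zeros(ns)])
        zero_hess = lambda x, v: sp.csr_matrix((self.layout.n, self.layout.n))
        return NonlinearConstraint(
            self.constraint_fun, lb, ub, jac=self.constraint_jac, hess=zero_hess
        )

    # -- seeds --------------------------------------------------------------
    def pack_seed(self, seed: dict) -> np.ndarray:
        """Pack a seed dict (Q, dq0, optional tau/lamc/lam_split/eps) into z."""
        lay = self.layout
        fs = self.force_scale
        z = np.zeros(lay.n)
        z[: (self.N + 1) * lay.nq] = np.asarray(seed["Q"], float).ravel()
        z[lay.dq0 : lay.dq0 + lay.nq] = np.asarray(seed["dq0"], float)
        if "tau" in seed:
            z[lay.tau0 : lay.tau0 + self.N * lay.ntau] = np.asarray(seed["tau"]).ravel() / fs
        if "lamc" in seed and lay.nr:
            z[lay.lamc0 : lay.lamc0 + self.N * lay.nr] = np.asarray(seed["lamc"]).ravel() / fs
        lam_seed = seed.get("lam_world", {})
        lb, ub = self.bounds.lb, self.bounds.ub
        for (foot, k), o in lay.lam_index.items():
            f = np.asarray(lam_seed.get((foot, k), np.zeros(3)), float) / fs
            z[o : o + 5] = split_tangential(f)
        for idx in lay.eps_index.values():
            z[idx] = seed.get("eps", 0.02)
        # keep strictly inside the simple bounds for the interior-point start
        span = np.where(np.isfinite(ub - lb), ub - lb, 1.0)
        pad = np.minimum(1e-4, 0.25 * span)
        z = np.clip(z, np.where(np.isfinite(lb), lb + pad, lb), np.where(np.isfinite(ub), ub - pad, ub))
        return z

    def kinetics_warm_start(self, z: np.ndarray) -> np.ndarray:
        """Per-node ridge least-squares fill-in of (tau, lambda_c, lambda_g).

        Given the seeded kinematics, choose multipliers minimising the
        dynamics disturbance; clipped into bounds afterwards.
        """
        lay, m = self.layout, self.model
        z = z.copy()
        c = self._core(z)
        fid = c["w"].copy()
        # rebuild pure inverse dynamics (w with zero multipliers)
        zq = z.copy()
        zq[lay.tau0 :] = 0.0
        c0 = self._core(zq)
        fid = c0["w"]
        B, Jc, Jmk = c0["B"], c0["Jc"], c0["Jmk"]
        for k in range(1, self.N + 1):
            i = k - 1
            cols = [B[i]]
            sizes = [("tau", lay.tau(k))]
            if lay.nr:
                cols.append(Jc[i].T)
                sizes.append(("lamc", lay.lamc(k)))
            feet_here = [f for f in lay.foot_nodes if (f, k) in lay.lam_index]
            for f in feet_here:
                cols.append(Jmk[i, m.marker_index(f)].T @ _SPLIT)
                sizes.append(("lam", lay.lam(f, k)))
            A = np.concatenate(cols, axis=1)
            nloc = A.shape[1]
            x0 = np.concatenate([z[s] for _, s in sizes])
            # ridge toward the current seed (keeps lam near the prior band)
            lam_ridge = 1e-3
            AtA = A.T @ A + lam_ridge * np.eye(nloc)
            rhs = A.T @ fid[i] + lam_ridge * x0
            x = np.linalg.solve(AtA, rhs)
            o = 0
            for name, s in sizes:
                z[s] = x[o : o + (s.stop - s.start)]
                o += s.stop - s.start
        lb, ub = self.bounds.lb, self.bounds.ub
        span = np.where(np.isfinite(ub - lb), ub - lb, 1.0)
        pad = np.minimum(1e-4, 0.25 * span)
        return np.clip(z, np.where(np.isfinite(lb), lb + pad, lb), np.where(np.isfinite(ub), ub - pad, ub))

    # -- extraction -----------------------------------------------------------
    def extract(self, z, result=None) -> KFTESolution:
        z = np.asarray(z, float)
        c = self._core(z)
        lay, m, fs, N = self.layout, self.model, self.force_scale, self.N
        qd, qdd = c["qd"], c["qdd"]
        ddq = np.vstack([qdd[0][None, :], qdd])
        tau = np.vstack([np.zeros((1, lay.ntau)), c["tau"]]) * fs
        w = np.vstack([np.zeros((1, lay.nq)), c["w"]]) * fs
        lamc = np.vstack([np.zeros((1, lay.nr)), c["lamc"]]) * fs
        forces = {}
        for foot, nodes in lay.foot_nodes.items():
            if not nodes:
                continue
            run, cur = [], []
            for k in nodes:  # longest contiguous stance run
                cur = cur + [k] if cur and k == cur[-1] + 1 else [k]
                if len(cur) > len(run):
                    run = cur
            arr = np.array([_SPLIT @ z[lay.lam(foot, k)] for k in run]) * fs
            forces[foot] = GRFProfile(arr, self.h, foot=foot, start_node=run[0])
        residuals = {}
        for name, t in self.obs_tables.items():
            pts = c["X"][t["frames"], t["markers"]]
            residuals[name] = t["pixels"] - project(t["camera"], pts)
        eps = {key: float(z[idx]) for key, idx in lay.eps_index.items()}
        parts = self.objective_parts(z)
        jr = (
            float(np.abs(_mb.joint_constraint_residuals(m, c["Q"])).max())
            if lay.nr
            else 0.0
        )
        diag = {
            "max_joint_residual": jr,
            "max_integration_residual": 0.0,  # holds by construction (eliminated)
            "max_abs_w": float(np.abs(w).max()),
            "census": self.census(),
        }
        if result is not None:
            diag.update(
                {
                    "n_iterations": getattr(result, "niter", None),
                    "constr_violation": getattr(result, "constr_violation", None),
                    "optimality": getattr(result, "optimality", None),
                    "execution_time": getattr(result, "execution_time", None),
                }
            )
        return KFTESolution(
            q=c["Q"].copy(),
            dq=qd,
            ddq=ddq,
            tau=tau,
            w=w,
            lambda_c=lamc,
            forces=forces,
            markers=c["X"].copy(),
            residuals_px=residuals,
            eps=eps,
            status=getattr(result, "message", "evaluated"),
            success=bool(getattr(result, "success", False)),
            objective=parts["objective"],
            decomposition=parts,
            diagnostics=diag,
        )


def build_problem(problem: KFTEProblem, mode: str = "sinusoidal") -> AssembledNLP:
    """Assemble the K-FTE NLP (variables, constraints, objective)."""
    return AssembledNLP(problem, mode)


class _ReducedNLP:
    """The same NLP after exact partial minimisation of the force variables.

    At fixed kinematics the torques, joint-constraint torques and split
    ground forces of each node solve a small strongly convex QP (the
    dynamics-penalty term plus their own regularisers, subject to their
    bounds, the friction pyramid and the GRF band).  Minimising them out
    leaves a problem in (q nodes, qd_0, eps) whose value and gradient are
    exact (envelope theorem) and whose constraints are the joint-geometry
    equalities and the no-slip boxes.  This cuts the variable count by ~2x
    and removes all linear constraints, which is what makes the
    trust-region solve tractable.
    """

    def __init__(self, nlp: AssembledNLP):
        self.nlp = nlp
        lay = nlp.layout
        self.nq, self.N = lay.nq, lay.N
        nz = (self.N + 1) * lay.nq + lay.nq
        self.eps_cols = np.array(sorted(lay.eps_index.values()), int)
        self.nred = nz + len(self.eps_cols)
        # map reduced vector -> full z columns
        self.zcols = np.concatenate([np.arange(nz), self.eps_cols])
        # per-node force-variable column blocks
        self.node_cols = []
        for k in range(1, self.N + 1):
            cols = [np.arange(lay.tau(k).start, lay.tau(k).stop)]
            if lay.nr:
                cols.append(np.arange(lay.lamc(k).start, lay.lamc(k).stop))
            for foot in lay.foot_nodes:
                if (foot, k) in lay.lam_index:
                    s = lay.lam(foot, k)
                    cols.append(np.arange(s.start, s.stop))
            self.node_cols.append(np.concatenate(cols))
        # restrict linear constraints (pyramid + band) to per-node blocks
        A = nlp.linear_constraint.A.toarray() if nlp.linear_constraint is not None else None
        self.node_lin = []
        for cols in self.node_cols:
            if A is None:
                self.node_lin.append((np.zeros((0, len(cols))), np.zeros(0), np.zeros(0)))
                continue
            sub = A[:, cols]
            rows = np.where(np.abs(sub).sum(axis=1) > 0)[0]
            self.node_lin.append(
                (sub[rows], nlp.linear_constraint.lb[rows], nlp.linear_constraint.ub[rows])
            )
        self._x_warm = None
        self._cache = {}

    # -- packing -----------------------------------------------------------
    def split(self, zeta):
        return zeta[: -len(self.eps_cols)] if len(self.eps_cols) else zeta

    def to_full(self, zeta, x_forces=None) -> np.ndarray:
        z = np.zeros(self.nlp.layout.n)
        z[self.zcols] = zeta
        if x_forces is not None:
            for cols, x in zip(self.node_cols, x_forces):
                z[cols] = x
        return z

    def from_full(self, z) -> np.ndarray:
        return z[self.zcols]

    # -- inner per-node force QPs -------------------------------------------
    def _inner_forces(self, zeta):
        """Optimal force variables per node for the given kinematics."""
        nlp, lay = self.nlp, self.nlp.layout
        W = nlp.problem.weights
        z = self.to_full(zeta, self._x_warm)
        c = nlp._core(z)
        m = nlp.model
        fid = c["w"].copy()
        # rebuild the applied-force-free residual: w = fid0 - Abar x
        # (compute fid0 by adding back the current applied forces)
        xs = []
        lb_full, ub_full = nlp.bounds.lb, nlp.bounds.ub
        for k in range(1, self.N + 1):
            i = k - 1
            cols = self.node_cols[i]
            blocks = [c["B"][i]]
            if lay.nr:
                blocks.append(np.swapaxes(c["Jc"], 1, 2)[i])
            for foot in lay.foot_nodes:
                if (foot, k) in lay.lam_index:
                    mi = m.marker_index(foot)
                    blocks.append(c["Jmk"][i, mi].T @ _SPLIT)
            Abar = np.concatenate(blocks, axis=1)  # (nq, nloc)
            x_cur = z[cols]
            f0 = fid[i] + Abar @ x_cur  # pure inverse dynamics (normalised)
            nloc = len(cols)
            wx = np.zeros(nloc)
            wx[: lay.ntau] = W.alpha_smooth * W.torque_weight
            o = lay.ntau + lay.nr
            while o < nloc:
                wx[o : o + 4] = W.split_reg
                o += 5
            P = 2.0 * W.alpha_model * Abar.T @ Abar + 2.0 * np.diag(wx)
            qv = -2.0 * W.alpha_model * Abar.T @ f0
            lo = lb_full[cols]
            hi = ub_full[cols]
            Gm, glb, gub = self.node_lin[i]
            x = _box_qp(P, qv, lo, hi, Gm, glb, gub, x0=x_cur)
            xs.append(x)
        self._x_warm = xs
        return xs

    # -- evaluation ----------------------------------------------------------
    def _eval(self, zeta):
        key = hash(zeta.tobytes())
        if self._cache.get("key") == key:
            return self._cache
        xs = self._inner_forces(zeta)
        z = self.to_full(zeta, xs)
        parts = self.nlp.objective_parts(z)
        self._cache = {"key": key, "z": z, "xs": xs, "parts": parts}
        return self._cache

    def objective(self, zeta):
        return self._eval(np.asarray(zeta, float))["parts"]["objective"]

    def gradient(self, zeta):
        c = self._eval(np.asarray(zeta, float))
        g_full, _ = self.nlp._grad_hess(c["z"], want_hess=False)
        return g_full[self.zcols]

    def hessian(self, zeta):
        c = self._eval(np.asarray(zeta, float))
        z = c["z"]
        core = self.nlp._core(z)
        lay, W = self.nlp.layout, self.nlp.problem.weights
        m = self.nlp.model
        lb_full, ub_full = self.nlp.bounds.lb, self.nlp.bounds.ub
        S_nodes = []
        for k in range(1, self.N + 1):
            i = k - 1
            cols = self.node_cols[i]
            blocks = [core["B"][i]]
            if lay.nr:
                blocks.append(np.swapaxes(core["Jc"], 1, 2)[i])
            for foot in lay.foot_nodes:
                if (foot, k) in lay.lam_index:
                    mi = m.marker_index(foot)
                    blocks.append(core["Jmk"][i, mi].T @ _SPLIT)
            Abar = np.concatenate(blocks, axis=1)
            x = z[cols]
            tol = 1e-9
            free = (x > lb_full[cols] + tol) & (x < ub_full[cols] - tol)
            Af = Abar[:, free]
            nloc = len(cols)
            wx = np.zeros(nloc)
            wx[: lay.ntau] = W.alpha_smooth * W.torque_weight
            o = lay.ntau + lay.nr
            while o < nloc:
                wx[o : o + 4] = W.split_reg
                o += 5
            wf = wx[free] / W.alpha_model
            nf = Af.shape[1]
            if nf == 0:
                S_nodes.append(np.eye(lay.nq))
                continue
            M = Af.T @ Af + np.diag(wf) + 1e-9 * np.eye(nf)
            S = np.eye(lay.nq) - Af @ np.linalg.solve(M, Af.T)
            S_nodes.append(S)
        self.nlp.model_hessian_S = S_nodes
        try:
            _, H = self.nlp._grad_hess(z, want_hess=True)
        finally:
            self.nlp.model_hessian_S = None
        return H[self.zcols][:, self.zcols].tocsr()

    def constraint_fun(self, zeta):
        c = self._eval(np.asarray(zeta, float))
        return self.nlp.constraint_fun(c["z"])

    def constraint_jac(self, zeta):
        c = self._eval(np.asarray(zeta, float))
        return self.nlp.constraint_jac(c["z"])[:, self.zcols].tocsr()

    def nonlinear_constraint(self) -> NonlinearConstraint:
        nj, ns = self.nlp.n_joint_rows, self.nlp.n_slip_rows
        lb = np.concatenate([np.zeros(nj), np.full(ns, -np.inf)])
        ub = np.concatenate([np.zeros(nj), np.zeros(ns)])
        zero_hess = lambda x, v: sp.csr_matrix((self.nred, self.nred))
        return NonlinearConstraint(
            self.constraint_fun, lb, ub, jac=self.constraint_jac, hess=zero_hess
        )

    def bounds(self) -> Bounds:
        lb = np.full(self.nred, -np.inf)
        ub = np.full(self.nred, np.inf)
        if len(self.eps_cols):
            lb[-len(self.eps_cols) :] = 0.0
            ub[-len(self.eps_cols) :] = 1.0
        return Bounds(lb, ub)


def _box_qp(P, q, lo, hi, G, glb, gub, x0=None, tol=1e-9, max_iter=40):
    """Small dense strictly convex QP: min 1/2 x'Px + q'x, lo<=x<=hi, glb<=Gx<=gub.

    Deterministic working-set method: all inequalities are collected as
    A x >= b; violated rows enter the working set whose dual is minimised
    exactly by cyclic coordinate descent (strictly convex, tiny).  Accuracy
    is machine-level, which the outer solver needs — the partially
    minimised objective must be smooth, not solver-noisy.
    """
    from scipy.linalg import cho_factor, cho_solve

    n = len(q)
    scale = max(1.0, float(np.abs(P).max()))
    Ps, qs = P / scale, q / scale
    cho = cho_factor(Ps + 1e-12 * np.eye(n))
    x_unc = cho_solve(cho, -qs)

    rows, rhs = [], []
    fin = np.isfinite(lo)
    for i in np.where(fin)[0]:
        e = np.zeros(n)
        e[i] = 1.0
        rows.append(e)
        rhs.append(lo[i])
    fin = np.isfinite(hi)
    for i in np.where(fin)[0]:
        e = np.zeros(n)
        e[i] = -1.0
        rows.append(e)
        rhs.append(-hi[i])
    for j in range(len(G)):
        if np.isfinite(glb[j]):
            rows.append(G[j])
            rhs.append(glb[j])
        if np.isfinite(gub[j]):
            rows.append(-G[j])
            rhs.append(-gub[j])
    if not rows:
        return x_unc
    A = np.array(rows)
    b = np.array(rhs)
    m = len(b)

    x = x_unc
    working = list(np.where(b - A @ x > tol)[0])
    if not working:
        return x
    nu = np.zeros(m)
    PiAT = cho_solve(cho, A.T)  # P^-1 A^T (n, m)
    for _ in range(12):
        W = np.array(sorted(set(working)), int)
        Hd = A[W] @ PiAT[:, W]
        cd = A[W] @ x_unc - b[W]  # gradient at nu=0 is -viol
        nuW = nu[W].copy()
        diag = np.maximum(np.diag(Hd), 1e-14)
        for sweep in range(800):
            delta = 0.0
            for ii in range(len(W)):
                g_i = Hd[ii] @ nuW + cd[ii]
                new = max(0.0, nuW[ii] - g_i / diag[ii])
                delta = max(delta, abs(new - nuW[ii]))
                nuW[ii] = new
            if delta < 1e-13 * (1.0 + np.abs(nuW).max(initial=0.0)):
                break
        nu[:] = 0.0
        nu[W] = nuW
        x = x_unc + PiAT[:, W] @ nuW
        new_viol = np.where(b - A @ x > tol)[0]
        added = [j for j in new_viol if j not in set(working)]
        if not added:
            break
        working += added
    return x


# ---------------------------------------------------------------------------
# seeding


def seed_initializer(problem: KFTEProblem, smooth: bool = True) -> dict:
    """Initial trajectory guess from triangulation + inverse kinematics.

    Markers are triangulated per frame from all cameras with >= 2 views,
    gaps linearly interpolated (flagged), optionally low-pass filtered;
    q is fit per frame by damped least-squares inverse kinematics with the
    joint-geometry residuals as soft penalties; qd_0 by forward difference.
    Torques are left zero (the solver's warm start fills them in).
    """
    m = problem.model
    N, M = problem.n_nodes, len(m.markers)
    by_fm = {}
    for o in problem.observations:
        if o.visible:
            by_fm.setdefault((o.frame, o.marker), []).append(o)
    Xt = np.full((N + 1, M, 3), np.nan)
    interpolated = np.zeros((N + 1, M), bool)
    tri_residuals = []
    for (f, mk), obs in by_fm.items():
        if len(obs) < 2:
            continue
        cams = [problem.cameras[o.camera] for o in obs]
        px = [o.pixel for o in obs]
        try:
            Xt[f, m.marker_index(mk)], resid = triangulate(cams, px)
            tri_residuals.append(resid)
        except DegenerateGeometryError:
            continue
    # estimated detector noise decides how hard to smooth below
    noise_px = float(np.median(tri_residuals)) if tri_residuals else 0.0
    # fill gaps in time
    t = np.arange(N + 1)
    for j in range(M):
        for d in range(3):
            col = Xt[:, j, d]
            good = np.isfinite(col)
            if good.sum() == 0:
                Xt[:, j, d] = 0.0
                interpolated[:, j] = True
                continue
            if not good.all():
                interpolated[~good, j] = True
                Xt[:, j, d] = np.interp(t, t[good], col[good])
    if interpolated.any():
        log.warning("seed: %d marker-frames interpolated for missing views", int(interpolated.sum()))
    # smoothing strength follows the measured triangulation residual: with
    # clean detections a light pass is near-lossless; noisy detections need
    # a wide window to keep double-differenced accelerations physical
    noisy = noise_px > 0.5
    if smooth and N + 1 >= 11 and noisy:
        Xt = savgol_filter(Xt, 11, 3, axis=0)
    elif smooth and N + 1 >= 7:
        Xt = savgol_filter(Xt, 7, 3, axis=0)

    # per-frame damped inverse kinematics
    Q = np.zeros((N + 1, m.nq))
    base_markers = [i for i, mi in enumerate(m._marker_link) if mi == 0]
    q_prev = np.zeros(m.nq)
    if base_markers:
        q_prev[0:3] = Xt[0, base_markers].mean(axis=0) - m._marker_off[base_markers].mean(axis=0)
    wj, wr = 0.5, 1e-3

    for k in range(N + 1):
        target = Xt[k]

        def resid(qk):
            fkm = _mb.forward_kinematics(m, qk).markers
            parts = [(fkm - target).ravel()]
            if m.n_joint_residuals:
                parts.append(wj * _mb.joint_constraint_residuals(m, qk))
            parts.append(wr * (qk - q_prev))
            return np.concatenate(parts)

        def jac(qk):
            Jm = _mb.marker_jacobians(m, qk).reshape(3 * M, m.nq)
            parts = [Jm]
            if m.n_joint_residuals:
                parts.append(wj * _mb.joint_constraint_jacobian(m, qk))
            parts.append(wr * np.eye(m.nq))
            return np.concatenate(parts, axis=0)

        r = least_squares(resid, q_prev, jac=jac, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=200)
        Q[k] = r.x
        q_prev = r.x

    if smooth and N + 1 >= 9 and noisy:
        # under keypoint noise a pass over the joint trajectory too keeps
        # the seed's double-differenced accelerations physical
        Q = savgol_filter(Q, 9, 3, axis=0)

    dq0 = (Q[1] - Q[0]) / problem.h
    lam_world = {}
    fs = m.total_mass * m.gravity
    if problem.grf_prior:
        for foot, entry in problem.grf_prior.items():
            for prof in _prior_profiles(entry):
                for i, f in enumerate(prof.forces):
                    lam_world[(foot, prof.start_node + i)] = f
    else:
        # bodyweight-proportional guess over simultaneous stance feet
        for k in range(1, N + 1):
            feet = [f for f in problem.contact.feet() if problem.contact.in_stance(f, k)]
            for f in feet:
                lam_world[(f, k)] = np.array([0.0, 0.0, fs / max(len(feet), 1)])
    return {
        "Q": Q,
        "dq0": dq0,
        "markers": Xt,
        "interpolated": interpolated,
        "lam_world": lam_world,
        "tau": np.zeros((N, m.ntau)),
    }


# ---------------------------------------------------------------------------
# solve


def solve(
    problem: KFTEProblem,
    mode: str = "sinusoidal",
    seed: dict | None = None,
    options: dict | None = None,
) -> KFTESolution:
    """Assemble and solve the K-FTE NLP; never raises on non-convergence.

    ``options`` are passed to scipy's trust-constr (maxiter, gtol, xtol,
    verbose ...).  The returned :class:`KFTESolution` carries the solver
    status, the objective decomposition and per-node diagnostics; on failure
    the last iterate is extracted and ``success`` is False.
    """
    nlp = build_problem(problem, mode)
    if seed is None:
        seed = seed_initializer(problem)
    z0 = nlp.pack_seed(seed)
    z0 = nlp.kinetics_warm_start(z0)
    z0 = _update_slacks(nlp, z0)
    opts = {"maxiter": 80, "gtol": 1e-8, "xtol": 1e-10, "verbose": 0}
    if options:
        opts.update(options)
    red = _ReducedNLP(nlp)
    zeta0 = red.from_full(z0)
    t0 = time.time()
    try:
        res = minimize(
            red.objective,
            zeta0,
            jac=red.gradient,
            hess=red.hessian,
            bounds=red.bounds(),
            constraints=[red.nonlinear_constraint()],
            method="trust-constr",
            options=opts,
        )
        z = _project_joints(nlp, red._eval(res.x)["z"])
        z = red._eval(red.from_full(z))["z"]  # re-optimise forces for the projected q
        z = _update_slacks(nlp, z)
        res.success = bool(res.status in (1, 2)) or res.constr_violation < 1e-4
    except Exception as exc:  # surface, don't crash: report the seed iterate
        log.error("solver failed: %s", exc)

        class _Fail:
            success = False
            message = f"solver raised: {exc}"
            niter = 0

        res = _Fail()
        z = z0
    sol = nlp.extract(z, res)
    sol.diagnostics["wall_time_s"] = time.time() - t0
    sol.diagnostics["mode"] = mode
    return sol


def _project_joints(nlp: AssembledNLP, z: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Gauss-Newton projection of every node onto the joint-geometry manifold.

    The optimiser leaves joint residuals at its own tolerance (~1e-5); a few
    micro-radian Newton corrections per node push them to machine precision
    without measurably moving markers or forces.
    """
    if not nlp.layout.nr:
        return z
    z = z.copy()
    m, lay = nlp.model, nlp.layout
    Q = lay.unpack_q(z).copy()
    for _ in range(4):
        r = _mb.joint_constraint_residuals(m, Q)
        if np.abs(r).max() < tol:
            break
        J = _mb.joint_constraint_jacobian(m, Q)
        for k in range(Q.shape[0]):
            Q[k] -= np.linalg.lstsq(J[k], r[k], rcond=None)[0]
    z[: Q.size] = Q.ravel()
    return z


def _update_slacks(nlp: AssembledNLP, z: np.ndarray) -> np.ndarray:
    """Set each eps slack to the smallest value covering its stance interval.

    The slack couples to the rest of the problem only through the no-slip
    boxes and its own quadratic penalty, so the optimal eps given the
    kinematics is the largest componentwise foot speed of the interval
    (capped at the admissible 1).
    """
    z = z.copy()
    c = nlp._core(z)
    m, lay = nlp.model, nlp.layout
    need = {}
    for foot, k, mi, ei in nlp.slip_entries:
        Jg = _mb.marker_jacobians(m, c["Q"][k])[mi]
        vf = Jg @ c["qd"][k]
        need[ei] = max(need.get(ei, 0.0), float(np.abs(vf).max()))
    for ei, v in need.items():
        z[ei] = min(1.0, max(z[ei], v * 1.02 + 1e-6))
    return z
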