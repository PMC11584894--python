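"""Dynamics and kinematics of the cylinder-link model.

The load-bearing check is the finite-difference Lagrangian oracle: the
inertia matrix, Coriolis vector and gravity vector produced by the package
must agree with numerical differentiation of independently computed kinetic
and potential energies.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from conftest import make_chain
from kfte import multibody as mb
from kfte.multibody import (
    GeneralizedState,
    InvalidSpecError,
    JointSpec,
    LinkSpec,
    MarkerSpec,
    SkeletonModel,
)


# ---------------------------------------------------------------------------
# independent finite-difference Lagrangian oracle


def fd_energy(model, q, dq, eps=1e-6):
    """Kinetic energy from FD-in-q of the forward kinematics only.

    Velocities come from (FK(q + eps dq) - FK(q - eps dq)) / 2 eps, so the
    oracle never touches the package's velocity propagation or dynamics.
    """
    R0, o0 = mb._link_frames(model, q - eps * dq)
    R1, o1 = mb._link_frames(model, q + eps * dq)
    Rm, om = mb._link_frames(model, q)
    vo = (o1 - o0) / (2 * eps)
    com_v = vo + np.einsum("lij,lj->li", (R1 - R0) / (2 * eps), model._coms)
    W = np.einsum("lij,lkj->lik", (R1 - R0) / (2 * eps), Rm)
    om_w = np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=-1)
    ke = 0.0
    for i in range(model.nlinks):
        Iw = Rm[i] @ model._inertias[i] @ Rm[i].T
        ke += 0.5 * model._masses[i] * com_v[i] @ com_v[i] + 0.5 * om_w[i] @ Iw @ om_w[i]
    return ke


def fd_potential(model, q):
    R, o = mb._link_frames(model, q)
    com = o + np.einsum("lij,lj->li", R, model._coms)
    return model.gravity * float(model._masses @ com[:, 2])


def oracle_M(model, q):
    """Inertia matrix by polarisation of the FD kinetic energy."""
    n = model.nq
    I = np.eye(n)
    Mo = np.zeros((n, n))
    t_single = [fd_energy(model, q, I[i]) for i in range(n)]
    for i in range(n):
        for j in range(i, n):
            tij = fd_energy(model, q, I[i] + I[j])
            Mo[i, j] = Mo[j, i] = tij - t_single[i] - t_single[j]
    return Mo


def _d4(f, h):
    """Fourth-order central difference of a callable of one step multiplier."""
    return (8.0 * (f(1) - f(-1)) - (f(2) - f(-2))) / (12.0 * h)


def oracle_terms(model, q, dq, eps=1e-3):
    """M, Cv, G by numerical differentiation of the energies.

    M by polarisation (T is exactly quadratic in qdot); G = -dV/dq;
    Cv = [dM/dq along qd] qd - dT/dq, the Lagrangian identity with the
    configuration derivatives taken by fourth-order central differences.
    """
    n = model.nq
    I = np.eye(n)
    M = oracle_M(model, q)
    G = np.array(
        [-_d4(lambda s, i=i: fd_potential(model, q + s * eps * I[i]), eps) for i in range(n)]
    )
    dM_dir = _d4(lambda s: oracle_M(model, q + s * eps * dq), eps)
    dTdq = np.array(
        [_d4(lambda s, i=i: fd_energy(model, q + s * eps * I[i], dq), eps) for i in range(n)]
    )
    Cv = dM_dir @ dq - dTdq
    return M, Cv, G


@pytest.mark.parametrize("n_links", [1, 2, 3])
def test_dynamics_terms_match_fd_lagrangian_oracle(n_links):
    """M, C qd and G agree with the finite-difference Lagrangian oracle."""
    model = make_chain(n_links)
    rng = np.random.default_rng(10 + n_links)
    for _ in range(4):
        q = rng.normal(0.0, 0.5, model.nq)
        dq = rng.normal(0.0, 1.0, model.nq)
        t = mb.dynamics_terms(model, q, dq)
        Mo, Cvo, Go = oracle_terms(model, q, dq)
        scale = max(np.abs(Mo).max(), 1.0)
        assert np.abs(t.M - Mo).max() / scale < 1e-6
        assert np.abs(t.G - Go).max() / max(np.abs(Go).max(), 1.0) < 1e-6
        assert np.abs(t.Cv - Cvo).max() / max(np.abs(Cvo).max(), 1.0) < 1e-5


def test_mass_matrix_symmetric_positive_definite(chain3):
    rng = np.random.default_rng(0)
    Q = rng.normal(0.0, 0.6, (200, chain3.nq))
    M = mb.mass_matrix(chain3, Q)
    assert np.abs(M - np.swapaxes(M, -1, -2)).max() < 1e-10
    for Mk in M[:50]:
        assert np.linalg.eigvalsh(Mk).min() > 0


def test_coriolis_vanishes_at_rest(chain3):
    rng = np.random.default_rng(1)
    q = rng.normal(size=chain3.nq)
    t = mb.dynamics_terms(chain3, q, np.zeros(chain3.nq))
    assert np.abs(t.Cv).max() == 0.0


def test_gravity_depends_on_configuration_only(chain2):
    rng = np.random.default_rng(2)
    q = rng.normal(size=chain2.nq)
    g1 = mb.dynamics_terms(chain2, q, rng.normal(size=chain2.nq)).G
    g2 = mb.dynamics_terms(chain2, q, rng.normal(size=chain2.nq)).G
    np.testing.assert_allclose(g1, g2, atol=1e-12)


# ---------------------------------------------------------------------------
# cylinder inertia


def test_cylinder_inertia_closed_forms():
    thin_rod = mb.cylinder_inertia(1.0, 1.0, 0.0)
    np.testing.assert_allclose(np.diag(thin_rod), [0.0, 1.0 / 12.0, 1.0 / 12.0], atol=1e-15)
    t = mb.cylinder_inertia(2.0, 0.3, 0.05)
    np.testing.assert_allclose(np.diag(t), [0.0025, 0.01625, 0.01625], atol=1e-15)
    assert np.abs(mb.cylinder_inertia(0.0, 0.2, 0.1)).max() == 0.0
    with pytest.raises(InvalidSpecError):
        mb.cylinder_inertia(1.0, 0.0, 0.1)


def test_cylinder_inertia_respects_axis():
    t = mb.cylinder_inertia(2.0, 0.3, 0.05, axis=(0, 0, -1))
    np.testing.assert_allclose(np.diag(t), [0.01625, 0.01625, 0.0025], atol=1e-15)


# ---------------------------------------------------------------------------
# forward kinematics


def test_fk_zero_pose_lays_chain_along_reference_axis(chain3):
    fk = mb.forward_kinematics(chain3, np.zeros(chain3.nq))
    np.testing.assert_allclose(
        fk.link_origins, [[0, 0, 0], [0.5, 0, 0], [0.9, 0, 0]], atol=1e-15
    )


def test_fk_equivariant_under_base_translation(chain3):
    rng = np.random.default_rng(3)
    q = rng.normal(0, 0.4, chain3.nq)
    q2 = q.copy()
    q2[:3] += [1.0, 2.0, 3.0]
    d = mb.forward_kinematics(chain3, q2).markers - mb.forward_kinematics(chain3, q).markers
    np.testing.assert_allclose(d, np.broadcast_to([1.0, 2.0, 3.0], d.shape), atol=1e-12)


def test_fk_single_link_rotated_about_vertical():
    model = make_chain(1)
    q = np.zeros(model.nq)
    q[model.angle_slice(0)] = [0.0, 0.0, np.pi / 2]  # yaw about world z
    fk = mb.forward_kinematics(model, q)
    np.testing.assert_allclose(fk.marker("tip"), [0.0, 0.5, 0.0], atol=1e-12)


def test_fk_rejects_wrong_dimension(chain2):
    with pytest.raises(ValueError):
        mb.forward_kinematics(chain2, np.zeros(chain2.nq + 1))


def test_marker_jacobian_matches_complex_step(chain3):
    rng = np.random.default_rng(4)
    q = rng.normal(0, 0.5, chain3.nq)
    J = mb.marker_jacobians(chain3, q)
    Jc = mb.complex_step_jacobian(
        lambda x: mb.forward_kinematics(chain3, x).markers.reshape(x.shape[:-1] + (-1,)), q
    )
    np.testing.assert_allclose(J.reshape(-1, chain3.nq), Jc, atol=1e-12)


# ---------------------------------------------------------------------------
# joint geometry


def test_joint_residuals_zero_for_identical_orientation(chain2):
    assert np.abs(mb.joint_constraint_residuals(chain2, np.zeros(chain2.nq))).max() == 0.0


def test_revolute_permits_rotation_about_parent_y(chain2):
    q = np.zeros(chain2.nq)
    q[chain2.angle_slice(1)] = [0.0, 0.7, 0.0]
    assert np.abs(mb.joint_constraint_residuals(chain2, q)).max() < 1e-14


def test_revolute_blocks_rotation_about_parent_x(chain2):
    q = np.zeros(chain2.nq)
    q[chain2.angle_slice(1)] = [np.pi / 2, 0.0, 0.0]
    r = mb.joint_constraint_residuals(chain2, q)
    np.testing.assert_allclose(r, [0.0, -1.0], atol=1e-12)


def test_universal_keeps_one_residual():
    model = SkeletonModel(
        [LinkSpec("a", 1, 1), LinkSpec("b", 1, 1, parent="a", offset=1)],
        [JointSpec("universal", "a", "b")],
    )
    assert model.n_joint_residuals == 1
    q = np.zeros(model.nq)
    q[model.angle_slice("b")] = [0.0, 0.5, 0.0]  # pure pitch permitted
    assert np.abs(mb.joint_constraint_residuals(model, q)).max() < 1e-12
    q[model.angle_slice("b")] = [0.4, 0.0, 0.0]  # pure roll permitted
    assert np.abs(mb.joint_constraint_residuals(model, q)).max() < 1e-12
    q[model.angle_slice("b")] = [0.0, 0.0, 0.6]  # yaw forbidden
    assert np.abs(mb.joint_constraint_residuals(model, q)).max() > 0.1


def test_joint_constraint_jacobian_matches_complex_step(chain3):
    rng = np.random.default_rng(5)
    q = rng.normal(0, 0.5, chain3.nq)
    J = mb.joint_constraint_jacobian(chain3, q)
    Jc = mb.complex_step_jacobian(lambda x: mb.joint_constraint_residuals(chain3, x), q)
    np.testing.assert_allclose(J, Jc, atol=1e-12)


# ---------------------------------------------------------------------------
# equation-of-motion residual


def test_free_fall_has_zero_disturbance(chain1):
    """Ballistic flight with gravity-consistent acceleration gives w = 0."""
    q = np.zeros(chain1.nq)
    q[2] = 1.0
    dq = np.zeros(chain1.nq)
    dq[0] = 2.0  # horizontal drift
    ddq = np.zeros(chain1.nq)
    ddq[2] = -chain1.gravity
    w = mb.dynamics_residual(chain1, GeneralizedState(q, dq, ddq))
    assert np.abs(w).max() < 1e-8


def test_static_support_balances_gravity():
    """A vertical link at rest with lambda_z = m g at the support has w = 0."""
    model = SkeletonModel(
        [LinkSpec("rod", 0.5, 2.0, 0.02, axis=(0, 0, -1))],
        markers=[MarkerSpec("foot", "rod", (0, 0, -0.5))],
    )
    q = np.zeros(model.nq)
    q[2] = 0.5  # proximal end above the support point
    state = GeneralizedState(q, np.zeros(model.nq), np.zeros(model.nq))
    F = np.array([0.0, 0.0, model.total_mass * model.gravity])
    w = mb.dynamics_residual(model, state, contact_forces={"foot": F})
    assert np.abs(w).max() < 1e-8


def test_disturbance_linear_in_acceleration(chain2):
    rng = np.random.default_rng(6)
    q = rng.normal(0, 0.4, chain2.nq)
    dq = rng.normal(size=chain2.nq)
    ddq = rng.normal(size=chain2.nq)
    delta = np.zeros(chain2.nq)
    delta[4] = 0.37
    w0 = mb.dynamics_residual(chain2, GeneralizedState(q, dq, ddq))
    w1 = mb.dynamics_residual(chain2, GeneralizedState(q, dq, ddq + delta))
    M = mb.mass_matrix(chain2, q)
    np.testing.assert_allclose(w1 - w0, M @ delta, atol=1e-9)


def test_dynamics_residual_rejects_bad_tau(chain2):
    state = GeneralizedState(np.zeros(chain2.nq), np.zeros(chain2.nq), np.zeros(chain2.nq))
    with pytest.raises(ValueError):
        mb.dynamics_residual(chain2, state, tau=np.zeros(chain2.ntau + 2))


# ---------------------------------------------------------------------------
# energy conservation of the passive model


def test_passive_simulation_conserves_energy(chain2):
    """Unactuated, contact-free fine-step integration keeps E within 0.1%."""
    rng = np.random.default_rng(7)
    q0 = rng.normal(0, 0.3, chain2.nq)
    dq0 = rng.normal(0, 0.5, chain2.nq)

    def rhs(_, y):
        q, dq = np.split(y, 2)
        return np.concatenate([dq, mb.passive_acceleration(chain2, q, dq)])

    e0 = float(mb.kinetic_energy(chain2, q0, dq0) + mb.potential_energy(chain2, q0))
    sol = solve_ivp(rhs, (0.0, 0.5), np.concatenate([q0, dq0]), rtol=1e-9, atol=1e-9, dense_output=True)
    assert sol.success
    q1, dq1 = np.split(sol.y[:, -1], 2)
    e1 = float(mb.kinetic_energy(chain2, q1, dq1) + mb.potential_energy(chain2, q1))
    assert abs(e1 - e0) / abs(e0) < 1e-3


# ---------------------------------------------------------------------------
# model validation


def test_skeleton_rejects_bad_specs():
    with pytest.raises(InvalidSpecError):
        SkeletonModel([LinkSpec("a", 1, 1), LinkSpec("b", 1, 1)])  # two roots
    with pytest.raises(InvalidSpecError):
        SkeletonModel([LinkSpec("a", 1, 1)], markers=[MarkerSpec("m", "zzz")])
    with pytest.raises(InvalidSpecError):
        LinkSpec("a", -1.0, 1.0)


def test_state_dimension_and_serialisation_roundtrip(chain3):
    assert chain3.nq == 3 + 3 * chain3.nlinks
    clone = SkeletonModel.from_dict(chain3.to_dict())
    assert clone.nq == chain3.nq
    rng = np.random.default_rng(8)
    q = rng.normal(size=chain3.nq)
    np.testing.assert_allclose(
        mb.forward_kinematics(clone, q).markers, mb.forward_kinematics(chain3, q).markers
    )
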