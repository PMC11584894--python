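"""Ground-contact model: GRF synthesis, friction pyramid, no-slip."""

import numpy as np
import pytest

from conftest import make_chain
from kfte import contact as ct
from kfte import multibody as mb
from kfte.contact import (
    ContactPlan,
    GRFSynthesisParams,
    InvalidForceError,
    InvalidParameterError,
    synth_sinusoidal_grf,
)


@pytest.fixture(scope="module")
def params():
    return GRFSynthesisParams()


def test_half_sine_endpoints_and_midpoint(params):
    prof = synth_sinusoidal_grf(params, speed=0.7, body_mass=28.8, stance=(0, 37), h=0.0125)
    A = params.peak_force(0.7, 28.8)
    assert prof.forces[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert prof.forces[-1, 2] == pytest.approx(0.0, abs=1e-12)
    assert prof.peak_vertical == pytest.approx(A, rel=1e-12)  # odd sample count -> exact midpoint
    assert (prof.forces[:, 2] >= 0).all()
    # symmetric about the stance midpoint
    np.testing.assert_allclose(prof.forces[:, 2], prof.forces[::-1, 2], atol=1e-9)


def test_vertical_impulse_matches_closed_form(params):
    """Trapezoidal integral of the half sine equals 2 A T / pi within 0.5%."""
    prof = synth_sinusoidal_grf(params, speed=0.7, body_mass=28.8, stance=(0, 60), h=0.01)
    A = params.peak_force(0.7, 28.8)
    T = prof.stance_duration
    assert prof.impulse()[2] == pytest.approx(2.0 * A * T / np.pi, rel=5e-3)


def test_fore_aft_spline_zero_at_start_mid_end(params):
    prof = synth_sinusoidal_grf(params, speed=0.7, body_mass=28.8, stance=(0, 41), h=0.01)
    n = len(prof.forces)
    assert prof.forces[0, 0] == pytest.approx(0.0, abs=1e-9)
    assert prof.forces[(n - 1) // 2, 0] == pytest.approx(0.0, abs=1e-9)
    assert prof.forces[-1, 0] == pytest.approx(0.0, abs=1e-9)
    # braking peak half the vertical amplitude, propulsive a quarter
    A = params.peak_force(0.7, 28.8)
    assert prof.forces[:, 0].min() == pytest.approx(-A / 2, rel=0.05)
    assert prof.forces[:, 0].max() == pytest.approx(A / 4, rel=0.05)
    assert np.abs(prof.forces[:, 1]).max() == 0.0  # no lateral component


def test_impulse_invariant_to_resampling(params):
    coarse = synth_sinusoidal_grf(params, 0.7, 28.8, (0, 51), h=0.01)
    fine = synth_sinusoidal_grf(params, 0.7, 28.8, (0, 501), h=0.001)
    np.testing.assert_allclose(coarse.impulse(), fine.impulse(), rtol=5e-3, atol=1e-3)


def test_synthesis_rejects_bad_parameters(params):
    with pytest.raises(InvalidParameterError):
        synth_sinusoidal_grf(params, speed=-1.0, body_mass=30.0, stance=(0, 30), h=0.01)
    with pytest.raises(InvalidParameterError):
        synth_sinusoidal_grf(params, speed=0.7, body_mass=30.0, stance=(5, 6), h=0.01)
    with pytest.raises(InvalidParameterError):
        GRFSynthesisParams(band=1.5)
    bad = GRFSynthesisParams(peak_intercept=-1.0, peak_slope=0.0)
    with pytest.raises(InvalidParameterError):
        synth_sinusoidal_grf(bad, speed=0.5, body_mass=30.0, stance=(0, 30), h=0.01)


# ---------------------------------------------------------------------------
# friction pyramid


def test_pyramid_examples():
    r = ct.friction_pyramid(np.array([0, 0, 0, 0, 100.0]), mu=1.3)
    np.testing.assert_allclose(r, [130.0, 130.0])
    r = ct.friction_pyramid(np.array([131.0, 0, 0, 0, 100.0]), mu=1.3)
    assert r[0] == pytest.approx(-1.0)
    with pytest.raises(InvalidForceError):
        ct.friction_pyramid(np.array([-1.0, 0, 0, 0, 100.0]), mu=1.3)


def test_pyramid_apex_forces_zero_tangential():
    lam = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
    assert (ct.friction_pyramid(lam, 1.3) >= 0).all()
    lam = np.array([0.1, 0.0, 0.0, 0.0, 0.0])
    assert ct.friction_pyramid(lam, 1.3)[0] < 0


def test_randomised_pyramid_agrees_with_direct_inequality():
    """Feasibility of the split form matches |lam_t| <= 1.3 lam_z on 1e4 draws."""
    rng = np.random.default_rng(42)
    F = np.column_stack(
        [rng.normal(0, 80, 10000), rng.normal(0, 80, 10000), rng.uniform(0, 200, 10000)]
    )
    split = ct.split_tangential(F)
    res = ct.friction_pyramid(split, mu=1.3)
    feasible_split = (res >= 0).all(axis=-1)
    feasible_direct = (np.abs(F[:, 0]) <= 1.3 * F[:, 2]) & (np.abs(F[:, 1]) <= 1.3 * F[:, 2])
    assert (feasible_split == feasible_direct).all()


def test_split_reconstruction_identity():
    rng = np.random.default_rng(3)
    F = rng.normal(0, 50, (500, 3))
    split = ct.split_tangential(F)
    np.testing.assert_allclose(ct.recombine_tangential(split), F, atol=1e-12)
    # minimal split: one side of each pair is zero
    assert (np.minimum(split[:, 0], split[:, 1]) == 0).all()
    assert (np.minimum(split[:, 2], split[:, 3]) == 0).all()
    # |lam_x| <= lam+ + lam- always, equality for the minimal split
    np.testing.assert_allclose(np.abs(F[:, 0]), split[:, 0] + split[:, 1], atol=1e-12)


# ---------------------------------------------------------------------------
# no-slip


def test_stationary_foot_satisfies_any_slack():
    model = make_chain(2)
    q = np.zeros(model.nq)
    assert ct.no_slip_residual(model, q, np.zeros(model.nq), "tip", eps=0.0) <= 1e-12
    assert ct.no_slip_residual(model, q, np.zeros(model.nq), "tip", eps=0.5) < 0


def test_base_translation_moves_foot_at_base_speed():
    model = make_chain(2)
    q = np.zeros(model.nq)
    dq = np.zeros(model.nq)
    dq[0] = 1.0
    v = ct.foot_velocity(model, q, dq, "tip")
    assert np.linalg.norm(v) == pytest.approx(1.0, rel=1e-12)
    # finite-difference cross-check of the velocity through FK
    eps = 1e-7
    p0 = mb.forward_kinematics(model, q - eps * dq).marker("tip")
    p1 = mb.forward_kinematics(model, q + eps * dq).marker("tip")
    np.testing.assert_allclose(v, (p1 - p0) / (2 * eps), atol=1e-6)
    assert ct.no_slip_residual(model, q, dq, "tip", eps=0.0) > 0  # moving foot, no slack


def test_contact_plan_bookkeeping():
    plan = ContactPlan(stance={"f": [(0, 5), (10, 12)]})
    assert plan.in_stance("f", 0) and plan.in_stance("f", 4) and not plan.in_stance("f", 5)
    np.testing.assert_array_equal(plan.stance_nodes("f"), [0, 1, 2, 3, 4, 10, 11])
    assert plan.mu == pytest.approx(1.3)  # default friction coefficient
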