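"""NLP assembly, robust cost, seeding (unit level; solves live in test_acceptance)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kfte import estimator as est
from kfte import multibody as mb
from kfte import synthetic as syn
from kfte.estimator import CostWeights, ObservationNoise, redescending_cost


# ---------------------------------------------------------------------------
# redescending robust kernel


def test_redescending_branch_values():
    knots = (3.0, 10.0, 20.0)
    assert redescending_cost(0.0, knots) == 0.0
    # quadratic and linear branches meet at the first knot
    a = knots[0]
    assert redescending_cost(a - 1e-12, knots) == pytest.approx(a * a / 2)
    assert redescending_cost(a + 1e-12, knots) == pytest.approx(a * a / 2)
    # constant beyond the last knot
    assert redescending_cost(25.0, knots) == pytest.approx(redescending_cost(50.0, knots))
    with pytest.raises(ValueError):
        redescending_cost(1.0, (5.0, 4.0, 20.0))


@settings(deadline=None, max_examples=200)
@given(st.floats(-40, 40, allow_nan=False))
def test_redescending_even_and_monotone(e):
    knots = (3.0, 10.0, 20.0)
    assert redescending_cost(e, knots) == pytest.approx(redescending_cost(-e, knots))
    assert redescending_cost(abs(e) + 0.5, knots) >= redescending_cost(e, knots) - 1e-12


def test_redescending_continuity_on_grid():
    knots = (3.0, 10.0, 20.0)
    x = np.linspace(-30, 30, 4001)
    y = redescending_cost(x, knots)
    assert np.abs(np.diff(y)).max() < 3.1 * (x[1] - x[0]) + 1e-9  # slope bounded by a


def test_observation_noise_map():
    noise = ObservationNoise(sigma_base=5.0)
    assert noise.sigma("m", 1.0) == pytest.approx(5.0)
    assert noise.sigma("m", 0.5) == pytest.approx(10.0)
    assert noise.sigma("m", 0.0) == pytest.approx(50.0)  # confidence floored at 0.1
    noise2 = ObservationNoise(per_marker={"nose": 2.0})
    assert noise2.sigma("nose", 1.0) == pytest.approx(2.0)


def test_cost_weights_validation():
    with pytest.raises(ValueError):
        CostWeights(knots=(3.0, 2.0, 20.0))
    with pytest.raises(ValueError):
        CostWeights(alpha_model=-1.0)


# ---------------------------------------------------------------------------
# problem assembly


@pytest.fixture(scope="module")
def small_problem():
    trial = syn.generate_trial(seed=0, noise_px=0.0)
    return trial, trial.problem("sinusoidal")


def test_variable_census_matches_independent_count(small_problem):
    """Variable counts agree with a closed-form census computed from the
    problem structure alone."""
    trial, prob = small_problem
    nlp = est.build_problem(prob, "sinusoidal")
    m, N = trial.model, prob.n_nodes
    n_lam_nodes = sum(
        1
        for foot in trial.contact.feet()
        for k in trial.contact.stance_nodes(foot)
        if 1 <= k <= N
    )
    n_intervals = sum(len(v) for v in trial.contact.stance.values())
    expected = (
        (N + 1) * m.nq  # node states
        + m.nq  # initial velocity
        + N * m.ntau  # joint torques
        + N * m.n_joint_residuals  # joint-constraint torques
        + 5 * n_lam_nodes  # split ground forces
        + n_intervals  # slip slacks
    )
    assert nlp.n_variables == expected
    census = nlp.census()
    assert census["total"] == expected
    assert census["joint_constraint_rows"] == (N + 1) * m.n_joint_residuals


def test_removing_a_camera_never_adds_constraints_or_residuals(small_problem):
    trial, prob = small_problem
    full = est.build_problem(prob, "sinusoidal")
    fewer_obs = [o for o in prob.observations if o.camera != "near1"]
    prob2 = trial.problem("sinusoidal")
    prob2.observations = fewer_obs
    smaller = est.build_problem(prob2, "sinusoidal")
    assert smaller.n_observations < full.n_observations
    c_full, c_small = full.census(), smaller.census()
    for key in ("joint_constraint_rows", "slip_rows", "linear_rows"):
        assert c_small[key] <= c_full[key]
    assert c_small["observation_residuals"] < c_full["observation_residuals"]


def test_sinusoidal_mode_requires_prior(small_problem):
    trial, _ = small_problem
    prob = trial.problem("freeform")
    with pytest.raises(ValueError):
        est.build_problem(prob, "sinusoidal")


def test_problem_rejects_unknown_references(small_problem):
    trial, _ = small_problem
    from kfte.camera import Observation2D

    with pytest.raises(ValueError, match="camera"):
        est.KFTEProblem(
            model=trial.model,
            cameras=trial.cameras,
            observations=[Observation2D(0, "nope", "nose", (1, 1))],
            contact=trial.contact,
            n_nodes=trial.params.n_nodes,
            h=trial.params.h,
        )
    with pytest.raises(ValueError, match="marker"):
        est.KFTEProblem(
            model=trial.model,
            cameras=trial.cameras,
            observations=[Observation2D(0, "near1", "nope", (1, 1))],
            contact=trial.contact,
            n_nodes=trial.params.n_nodes,
            h=trial.params.h,
        )


def test_truth_is_feasible_with_zero_disturbance(small_problem):
    """Packing the generator's truth gives w ~ 0, zero reprojection error,
    machine-zero joint residuals; the objective reduces to smoothness."""
    trial, prob = small_problem
    nlp = est.build_problem(prob, "sinusoidal")
    z = nlp.pack_seed(
        {
            "Q": trial.Q,
            "dq0": trial.dq0,
            "tau": trial.tau,
            "lamc": trial.lambda_c,
            "lam_world": trial.lam_world,
            "eps": 0.05,
        }
    )
    parts = nlp.objective_parts(z)
    assert parts["e_meas"] < 1e-12
    # band clipping at a few escalated nodes leaves a small but bounded
    # model penalty; everywhere else w is machine zero
    assert parts["e_model"] < 0.2
    cf = nlp.constraint_fun(z)
    assert np.abs(cf[: nlp.n_joint_rows]).max() < 1e-12


def test_objective_gradient_matches_finite_differences(small_problem):
    trial, prob = small_problem
    nlp = est.build_problem(prob, "sinusoidal")
    seed = est.seed_initializer(prob)
    z = nlp.pack_seed(seed)
    z = nlp.kinetics_warm_start(z)
    g = nlp.gradient(z)
    rng = np.random.default_rng(0)
    for i in rng.choice(nlp.n_variables, 6, replace=False):
        e = np.zeros(nlp.n_variables)
        e[i] = 1e-6
        nlp._cache = {}
        fp = nlp.objective(z + e)
        nlp._cache = {}
        fm = nlp.objective(z - e)
        assert g[i] == pytest.approx((fp - fm) / 2e-6, rel=1e-4, abs=1e-4)


def test_objective_decomposition_sums_to_total(small_problem):
    trial, prob = small_problem
    nlp = est.build_problem(prob, "sinusoidal")
    z = nlp.pack_seed(est.seed_initializer(prob))
    p = nlp.objective_parts(z)
    W = prob.weights
    total = (
        W.alpha_meas * p["e_meas"]
        + W.alpha_model * p["e_model"]
        + W.alpha_smooth * p["e_smooth"]
        + W.slack_weight * p["e_slack"]
        + W.split_reg * p["e_reg"]
    )
    assert p["objective"] == pytest.approx(total, abs=1e-8)


# ---------------------------------------------------------------------------
# seeding


def test_seed_recovers_markers_from_noise_free_views(small_problem):
    trial, prob = small_problem
    seed = est.seed_initializer(prob, smooth=False)
    err = np.abs(seed["markers"] - trial.markers)
    assert err.max() < 1e-4  # triangulation round trip
    fit = mb.forward_kinematics(trial.model, seed["Q"]).markers
    assert np.mean(np.linalg.norm(fit - trial.markers, axis=-1)) < 2e-3


def test_seed_interpolates_missing_marker(small_problem):
    trial, _ = small_problem
    mk = trial.model.marker_names[0]
    drop_frame = 20
    obs = [
        o
        for o in trial.observations
        if not (o.marker == mk and o.frame == drop_frame)
    ]
    prob = trial.problem("sinusoidal")
    prob.observations = obs
    seed = est.seed_initializer(prob)
    assert seed["interpolated"][drop_frame, trial.model.marker_index(mk)]
    # interpolated position stays close to the truth for a smooth gait
    err = np.linalg.norm(seed["markers"][drop_frame, trial.model.marker_index(mk)] - trial.markers[drop_frame, trial.model.marker_index(mk)])
    assert err < 5e-3


def test_seed_finite_difference_velocity_accuracy(small_problem):
    """Backward-difference velocities of the seed match the generator's
    discrete truth velocities to first order in h."""
    trial, prob = small_problem
    seed = est.seed_initializer(prob, smooth=False)
    qd_seed = np.diff(seed["Q"], axis=0) / prob.h
    assert np.abs(qd_seed - trial.qd[1:]).max() < 0.05
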