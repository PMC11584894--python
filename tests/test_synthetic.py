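"""The synthetic-trial generator: exact dynamic consistency and rendering."""

import numpy as np
import pytest

from kfte import multibody as mb
from kfte import synthetic as syn
from kfte.multibody import GeneralizedState
from kfte.presets import cheetah17, quadruped9


def test_truth_satisfies_discrete_dynamics(trial_clean):
    """dynamics_residual on the generated trajectory is < 1e-6 everywhere."""
    t = trial_clean
    m = t.model
    fs = m.total_mass * m.gravity
    worst = 0.0
    for k in range(1, t.params.n_nodes + 1):
        feet = {f: t.lam_world[(f, k)] for f in t.contact.feet() if (f, k) in t.lam_world}
        w = mb.dynamics_residual(
            m,
            GeneralizedState(t.Q[k], t.qd[k], t.qdd[k - 1]),
            tau=t.tau[k - 1],
            contact_forces=feet,
            joint_forces=t.lambda_c[k - 1],
        )
        worst = max(worst, float(np.abs(w).max()) / fs)
    assert worst < 1e-6


def test_truth_vertical_force_nonnegative(trial_clean):
    assert min(lam[2] for lam in trial_clean.lam_world.values()) >= 0.0


def test_stride_average_vertical_force_equals_body_weight(trial_clean):
    """Impulse-momentum balance: stride-mean total Fz is body weight within 2%."""
    t = trial_clean
    bw = t.model.total_mass * t.model.gravity
    mean_fz = sum(lam[2] for lam in t.lam_world.values()) / t.params.n_nodes
    assert abs(mean_fz / bw - 1.0) < 0.02


def test_truth_joint_geometry_exact(trial_clean):
    r = mb.joint_constraint_residuals(trial_clean.model, trial_clean.Q)
    assert np.abs(r).max() < 1e-12


def test_stance_feet_pinned(trial_clean):
    """A stance foot's marker does not move between consecutive stance nodes."""
    t = trial_clean
    X = t.markers
    for foot in t.contact.feet():
        mi = t.model.marker_index(foot)
        for a, b in t.contact.stance[foot]:
            for k in range(max(a, 0) + 1, min(b, t.params.n_nodes + 1)):
                d = np.linalg.norm(X[k, mi] - X[k - 1, mi])
                assert d < 1e-9
                assert abs(X[k, mi, 2]) < 1e-9  # on the ground


def test_schedule_keeps_three_feet_grounded(trial_clean):
    t = trial_clean
    counts = np.zeros(t.params.n_nodes + 1, int)
    for foot in t.contact.feet():
        counts[t.contact.stance_nodes(foot)] += 1
    assert counts.min() >= 3


def test_same_seed_reproduces_trial_bitwise():
    a = syn.generate_trial(seed=7, noise_px=1.0)
    b = syn.generate_trial(seed=7, noise_px=1.0)
    assert len(a.observations) == len(b.observations)
    assert all(x == y for x, y in zip(a.observations, b.observations))
    np.testing.assert_array_equal(a.Q, b.Q)


def test_different_seed_same_truth_different_noise(trial_clean):
    c = syn.generate_trial(seed=123, noise_px=1.0)
    np.testing.assert_array_equal(c.Q, trial_clean.Q)
    d = syn.generate_trial(seed=124, noise_px=1.0)
    pa = np.array([o.pixel for o in c.observations])
    pb = np.array([o.pixel for o in d.observations])
    assert pa.shape == pb.shape and not np.allclose(pa, pb)


def test_zero_noise_observations_reproject_exactly(trial_clean):
    from kfte.camera import project

    X = trial_clean.markers
    idx = {n: i for i, n in enumerate(trial_clean.model.marker_names)}
    errs = []
    for o in trial_clean.observations[::37]:
        cam = trial_clean.cameras[o.camera]
        errs.append(np.linalg.norm(project(cam, X[o.frame, idx[o.marker]]) - o.pixel))
    assert max(errs) < 1e-9


def test_rendered_noise_matches_requested_sigma():
    """Empirical residual std within 10% of the requested 2 px."""
    from kfte.camera import project

    t = syn.generate_trial(seed=5, noise_px=2.0)
    X = t.markers
    idx = {n: i for i, n in enumerate(t.model.marker_names)}
    res = []
    for o in t.observations:
        cam = t.cameras[o.camera]
        res.extend(project(cam, X[o.frame, idx[o.marker]]) - np.asarray(o.pixel))
    assert len(res) > 2000
    assert np.std(res) == pytest.approx(2.0, rel=0.1)
    assert all(0 < o.confidence <= 1 for o in t.observations)


def test_dropout_removes_observations():
    full = syn.generate_trial(seed=5, noise_px=0.0)
    dropped = syn.generate_trial(seed=5, noise_px=0.0, dropout=0.3)
    ratio = len(dropped.observations) / len(full.observations)
    assert 0.6 < ratio < 0.8


def test_generation_error_for_unreachable_gait():
    with pytest.raises(syn.GenerationError):
        syn.generate_gait(params=syn.GaitParams(speed=4.0))  # step far beyond leg reach


def test_generation_error_for_underfilled_support():
    with pytest.raises(syn.GenerationError):
        # duty 0.5 with staggered offsets leaves 2-foot windows
        syn.generate_gait(params=syn.GaitParams(duty=0.5))


def test_reconstruction_error_grows_monotonically_with_noise():
    """Marker recovery (triangulation + IK) degrades monotonically, averaged
    over seeds, as pixel noise grows through 0, 1, 2, 5 px."""
    from kfte import estimator as est
    from kfte import metrics

    means = []
    for sigma in (0.0, 1.0, 2.0, 5.0):
        errs = []
        for sd in (11, 12, 13):
            t = syn.generate_trial(seed=sd, noise_px=sigma)
            seed = est.seed_initializer(t.problem("freeform"))
            fit = mb.forward_kinematics(t.model, seed["Q"]).markers
            errs.append(metrics.mpe(t.markers, fit))
        means.append(np.mean(errs))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_presets_load_and_are_consistent():
    q9 = quadruped9()
    assert q9.nq == 30 and len(q9.markers) == 17
    c17 = cheetah17()
    assert c17.nlinks == 17 and c17.nq == 54 and len(c17.markers) == 23
    # the big preset is dynamically evaluable too
    rng = np.random.default_rng(0)
    q = rng.normal(0, 0.2, c17.nq)
    t = mb.dynamics_terms(c17, q, rng.normal(0, 0.5, c17.nq))
    assert np.abs(t.M - t.M.T).max() < 1e-10
    assert np.linalg.eigvalsh(t.M).min() > 0
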