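"""Evaluation metrics: RMSE, PCK, MPE, GRF error, impulse."""

import numpy as np
import pytest

from kfte import metrics
from kfte.contact import GRFProfile
from kfte.metrics import UndefinedMetricError


def test_rmse_examples():
    assert metrics.rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert metrics.rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(25 / 2))
    x = np.array([1.0, -2.0, 0.5])
    xh = np.array([0.3, 1.0, -0.2])
    assert metrics.rmse(3 * x, 3 * xh) == pytest.approx(3 * metrics.rmse(x, xh))
    with pytest.raises(ValueError):
        metrics.rmse([], [])
    with pytest.raises(ValueError):
        metrics.rmse([1, 2], [1])


def test_l2_norm():
    assert metrics.l2([3, 4]) == pytest.approx(5.0)


def test_pck_examples():
    gt = np.zeros((1, 2, 2))
    thr = np.array([10.0])
    est = gt.copy()
    assert metrics.pck(gt, est, thr) == 100.0
    est = np.array([[[5.0, 0.0], [20.0, 0.0]]])  # errors 0.5 thr and 2 thr
    assert metrics.pck(gt, est, thr) == 50.0


def test_pck_excludes_ineligible_frames():
    gt = np.zeros((2, 2, 2))
    est = np.zeros((2, 2, 2))
    est[1] += 100.0  # gross errors confined to the ineligible frame
    thr = np.array([10.0, np.nan])  # second frame: no visible eye
    assert metrics.pck(gt, est, thr) == 100.0
    with pytest.raises(UndefinedMetricError):
        metrics.pck(gt, est, np.array([np.nan, np.nan]))


def test_nose_to_eye_threshold_uses_first_visible_eye():
    gt = np.zeros((2, 3, 2))
    gt[:, 1] = [3.0, 4.0]  # eye 1 at distance 5 from the nose
    gt[:, 2] = [6.0, 8.0]  # eye 2 at distance 10
    vis = np.ones((2, 3), bool)
    vis[1, 1] = False  # frame 1 falls back to the second eye
    thr = metrics.nose_to_eye_thresholds(gt, nose_idx=0, eye_idx=[1, 2], visible=vis)
    np.testing.assert_allclose(thr, [5.0, 10.0])


def test_mpe_examples():
    x = np.zeros((1, 2, 3))
    xh = np.zeros((1, 2, 3))
    assert metrics.mpe(x, xh) == 0.0
    xh2 = x + np.array([0.003, 0.004, 0.0])
    assert metrics.mpe(x, xh2) == pytest.approx(5.0)  # constant 5 mm offset
    xh3 = x.copy()
    xh3[0, 0, 0] = 0.010
    xh3[0, 1, 0] = 0.030
    assert metrics.mpe(x, xh3) == pytest.approx(20.0)  # mean of 10 mm and 30 mm
    with pytest.raises(ValueError):
        metrics.mpe(np.zeros((1, 2, 3)), np.zeros((1, 3, 3)))


def test_mpe_invariant_to_consistent_reordering():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(5, 4, 3))
    xh = x + rng.normal(0, 0.01, x.shape)
    perm = rng.permutation(4)
    assert metrics.mpe(x, xh) == pytest.approx(metrics.mpe(x[:, perm], xh[:, perm]))


def test_grf_error_examples():
    h = 0.01
    t = np.arange(51) * h
    truth = np.zeros((51, 3))
    truth[:, 2] = 100.0 * np.sin(np.pi * t / t[-1])
    tp = GRFProfile(truth, h)
    r, pct, (ie, it_) = metrics.grf_error(tp, tp)
    assert r == 0.0 and pct == 0.0 and ie == pytest.approx(it_)
    # constant 10 N offset -> RMSE 10 N
    est = GRFProfile(truth + [0.0, 0.0, 10.0], h)
    r, _, _ = metrics.grf_error(est, tp)
    assert r == pytest.approx(10.0, rel=1e-3)
    # zero estimate vs half-sine amplitude A: RMSE A/sqrt(2), 70.7% of peak
    zero = GRFProfile(np.zeros((51, 3)), h)
    r, pct, _ = metrics.grf_error(zero, tp)
    assert r == pytest.approx(100.0 / np.sqrt(2), rel=2e-2)
    assert pct == pytest.approx(70.7, rel=2e-2)


def test_grf_error_resamples_to_common_grid():
    h = 0.01
    t = np.arange(51) * h
    f = 100.0 * np.sin(np.pi * t / t[-1])
    tp = GRFProfile(np.column_stack([0 * f, 0 * f, f]), h)
    t2 = np.arange(501) * 0.001
    f2 = 100.0 * np.sin(np.pi * t2 / t2[-1])
    est = GRFProfile(np.column_stack([0 * f2, 0 * f2, f2]), 0.001)
    r, pct, _ = metrics.grf_error(est, tp)
    assert pct < 0.5  # same curve at a different rate


def test_reprojection_summary_aggregations():
    e = np.array([1.0, 3.0, 2.0, 6.0])
    frames = np.array([0, 0, 1, 1])
    out = metrics.reprojection_summary(e, frames)
    assert out["per_keypoint"] == pytest.approx(3.0)
    assert out["per_frame"] == pytest.approx((2.0 + 4.0) / 2)
    with pytest.raises(UndefinedMetricError):
        metrics.reprojection_summary([])
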