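"""Evaluation metrics for kinematic and kinetic estimates.

Implements the standard pose/force error measures used to validate
markerless motion-and-force estimation: RMSE, reprojection l2 error,
percentage of correct keypoints (PCK) with a per-frame nose-to-eye
threshold, global mean position error (MPE) in millimetres, and ground
reaction force error reported both in newtons and as a percentage of the
truth peak, alongside impulses from trapezoidal quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvaluationReport",
    "UndefinedMetricError",
    "rmse",
    "l2",
    "pck",
    "mpe",
    "grf_error",
    "reprojection_summary",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined on the given inputs (e.g. no eligible frames)."""


@dataclass
class EvaluationReport:
    """Bundle of evaluation results; all errors nonnegative, pck in [0, 100]."""

    rmse: dict = field(default_factory=dict)
    mean_reprojection_px: float | None = None
    pck_percent: float | None = None
    mpe_mm: float | None = None
    grf_mean_error_n: float | None = None
    grf_error_percent_of_peak: float | None = None
    impulse: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rmse": dict(self.rmse),
            "mean_reprojection_px": self.mean_reprojection_px,
            "pck_percent": self.pck_percent,
            "mpe_mm": self.mpe_mm,
            "grf_mean_error_n": self.grf_mean_error_n,
            "grf_error_percent_of_peak": self.grf_error_percent_of_peak,
            "impulse": dict(self.impulse),
        }


def rmse(x, x_hat) -> float:
    """Root-mean-square error sqrt(mean((x - x_hat)^2)) over all elements."""
    x = np.asarray(x, float)
    x_hat = np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    if x.size == 0:
        raise ValueError("rmse of empty input is undefined")
    return float(np.sqrt(np.mean((x - x_hat) ** 2)))


def l2(x) -> float:
    """Euclidean norm of a vector."""
    return float(np.linalg.norm(np.asarray(x, float).ravel()))


def pck(
    gt_pixels,
    est_pixels,
    thresholds,
    visible=None,
    frame_eligible=None,
) -> float:
    """Percentage of correct keypoints under a per-frame threshold.

    ``gt_pixels``/``est_pixels`` are (N frames, K keypoints, 2);
    ``thresholds`` is per-frame (N,) — typically the nose-to-eye segment
    length in pixels; ``visible`` is an optional (N, K) boolean mask;
    ``frame_eligible`` an optional (N,) mask for frames on which the
    threshold is defined (the nose and at least one eye clearly visible).
    Ineligible frames contribute to neither numerator nor denominator.
    """
    gt = np.asarray(gt_pixels, float)
    est = np.asarray(est_pixels, float)
    thr = np.asarray(thresholds, float).reshape(-1)
    if gt.shape != est.shape or gt.ndim != 3 or gt.shape[0] != thr.shape[0]:
        raise ValueError("gt/est must be (N, K, 2) with one threshold per frame")
    n, k = gt.shape[:2]
    vis = np.ones((n, k), bool) if visible is None else np.asarray(visible, bool)
    elig = np.isfinite(thr) if frame_eligible is None else (
        np.asarray(frame_eligible, bool) & np.isfinite(thr)
    )
    mask = vis & elig[:, None]
    total = int(mask.sum())
    if total == 0:
        raise UndefinedMetricError("no eligible keypoints for PCK")
    err = np.linalg.norm(gt - est, axis=-1)
    correct = int(((err <= thr[:, None]) & mask).sum())
    return 100.0 * correct / total


def nose_to_eye_thresholds(gt_pixels, nose_idx: int, eye_idx, visible=None) -> np.ndarray:
    """Per-frame PCK threshold: nose-to-eye segment length in pixels.

    ``eye_idx`` may list several eye keypoints; the first visible one is
    used.  Frames where the nose or every eye is invisible get NaN (treated
    as ineligible by :func:`pck`).
    """
    gt = np.asarray(gt_pixels, float)
    n, k = gt.shape[:2]
    vis = np.ones((n, k), bool) if visible is None else np.asarray(visible, bool)
    eye_idx = np.atleast_1d(eye_idx)
    thr = np.full(n, np.nan)
    for f in range(n):
        if not vis[f, nose_idx]:
            continue
        for e in eye_idx:
            if vis[f, e]:
                thr[f] = np.linalg.norm(gt[f, nose_idx] - gt[f, e])
                break
    return thr


def mpe(truth_markers, est_markers) -> float:
    """Global mean position error in millimetres.

    mean over frames k and markers j of ||x_{k,j} - x_hat_{k,j}|| with
    positions in metres; returned in mm.
    """
    x = np.asarray(truth_markers, float)
    xh = np.asarray(est_markers, float)
    if x.shape != xh.shape or x.shape[-1] != 3:
        raise ValueError("marker arrays must have identical (N, M, 3) shapes")
    return float(np.mean(np.linalg.norm(x - xh, axis=-1)) * 1000.0)


def grf_error(est_profile, truth_profile, h: float | None = None):
    """Force-magnitude RMSE over stance, as newtons and % of the truth peak.

    Accepts :class:`kfte.contact.GRFProfile` objects or plain (n, 3)/(n,)
    arrays on a common time base (pass ``h`` for arrays).  Returns
    (rmse_n, percent_of_truth_peak, (est_impulse, truth_impulse)) where the
    impulses are trapezoidal integrals of the force magnitude (kg m/s).
    """

    def as_mag_and_h(p):
        if hasattr(p, "forces"):
            return np.linalg.norm(p.forces, axis=-1), p.h
        a = np.asarray(p, float)
        if a.ndim == 2:
            a = np.linalg.norm(a, axis=-1)
        if h is None:
            raise ValueError("h is required for plain-array profiles")
        return a, h

    est, h_e = as_mag_and_h(est_profile)
    tru, h_t = as_mag_and_h(truth_profile)
    if len(tru) < 2 or len(est) < 2:
        raise ValueError("zero-length stance")
    if len(est) != len(tru):
        # resample the estimate onto the truth grid by linear interpolation
        t_e = np.arange(len(est)) * h_e
        t_t = np.arange(len(tru)) * h_t
        est = np.interp(t_t, t_e, est)
    err = rmse(tru, est)
    peak = float(tru.max())
    if peak <= 0:
        raise ValueError("truth profile has non-positive peak")
    imp_est = float(np.trapezoid(est, dx=h_t))
    imp_tru = float(np.trapezoid(tru, dx=h_t))
    return err, 100.0 * err / peak, (imp_est, imp_tru)


def reprojection_summary(errors_px, frames=None) -> dict:
    """Mean l2 reprojection error aggregated per keypoint, per frame, per trial.

    ``errors_px`` is a flat array of per-observation l2 errors; ``frames``
    optionally groups them by frame for the per-frame mean.
    """
    e = np.asarray(errors_px, float).ravel()
    if e.size == 0:
        raise UndefinedMetricError("no reprojection errors")
    out = {"per_keypoint": float(e.mean())}
    if frames is not None:
        frames = np.asarray(frames).ravel()
        means = [e[frames == f].mean() for f in np.unique(frames)]
        out["per_frame"] = float(np.mean(means))
    out["per_trial"] = float(e.mean())
    return out
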