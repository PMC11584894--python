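"""Camera projection and multi-view triangulation.

A :class:`CameraModel` is a calibrated pinhole camera with equidistant
(fisheye) radial distortion — the model used for GoPro-style footage — and a
rigid world-to-camera transform.  Projection maps a world point to continuous
pixel coordinates (origin at the top-left corner, x right, y down).

Triangulation is plumbing used only to seed the trajectory optimiser: a
linear DLT solve on undistorted normalised rays, followed by a Gauss-Newton
refinement of the reprojection error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CameraModel",
    "Observation2D",
    "BehindCameraError",
    "DegenerateGeometryError",
    "project",
    "undistort_points",
    "triangulate",
]


class BehindCameraError(ValueError):
    """The point lies on or behind the camera's principal plane."""


class DegenerateGeometryError(ValueError):
    """Triangulation geometry is ill-posed (too few views or parallel rays)."""


@dataclass
class CameraModel:
    """Intrinsics, fisheye distortion, extrinsics and an error-weight scale.

    ``K`` is (fx, fy, cx, cy) in pixels; ``dist`` holds up to four
    equidistant radial coefficients (k1..k4, may be empty or zero);
    ``R``/``t`` map world points into the camera frame, X_cam = R X + t;
    ``confidence_scale`` multiplies normalised observation errors (1.0 for
    well-calibrated views, e.g. 0.6 for far-side cameras whose calibration
    was recovered indirectly).
    """

    K: Sequence[float]
    R: np.ndarray
    t: np.ndarray
    dist: Sequence[float] = ()
    image_size: Sequence[int] = (1920, 1080)
    confidence_scale: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.K = tuple(float(v) for v in self.K)
        if len(self.K) != 4 or self.K[0] <= 0 or self.K[1] <= 0:
            raise ValueError("K must be (fx, fy, cx, cy) with positive focal lengths")
        self.R = np.asarray(self.R, float).reshape(3, 3)
        if np.abs(self.R.T @ self.R - np.eye(3)).max() > 1e-8:
            raise ValueError("extrinsic rotation must be orthonormal")
        self.t = np.asarray(self.t, float).reshape(3)
        self.dist = tuple(float(v) for v in self.dist)
        if not 0.0 < self.confidence_scale <= 1.0:
            raise ValueError("confidence_scale must be in (0, 1]")

    @property
    def centre(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return -self.R.T @ self.t

    def to_dict(self) -> dict:
        return {
            "K": list(self.K),
            "dist": list(self.dist),
            "R": self.R.tolist(),
            "t": self.t.tolist(),
            "image_size": list(self.image_size),
            "confidence_scale": self.confidence_scale,
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CameraModel":
        return cls(
            K=d["K"],
            R=np.asarray(d["R"]),
            t=np.asarray(d["t"]),
            dist=d.get("dist", ()),
            image_size=tuple(d.get("image_size", (1920, 1080))),
            confidence_scale=d.get("confidence_scale", 1.0),
            name=d.get("name", ""),
        )


@dataclass(frozen=True)
class Observation2D:
    """One 2D keypoint detection: (frame, camera, marker) -> pixel + confidence."""

    frame: int
    camera: str
    marker: str
    pixel: tuple = (0.0, 0.0)
    confidence: float = 1.0
    visible: bool = True


def _distort_normalised(x, y, dist):
    """Apply equidistant distortion to normalised image coordinates."""
    r = np.sqrt(x * x + y * y)
    # guard the r -> 0 limit (theta_d / r -> 1); complex-safe
    r_safe = np.where(np.abs(r) < 1e-12, 1e-12, r)
    theta = np.arctan(r_safe)
    t2 = theta * theta
    theta_d = theta
    acc = t2
    for k in dist:
        theta_d = theta_d + k * theta * acc
        acc = acc * t2
    scale = np.where(np.abs(r) < 1e-12, 1.0 + 0.0 * r_safe, theta_d / r_safe)
    return x * scale, y * scale


def project(camera: CameraModel, X) -> np.ndarray:
    """Project world point(s) X (..., 3) to pixel coordinates (..., 2).

    Pinhole division, then equidistant distortion, then the intrinsic
    mapping.  Raises :class:`BehindCameraError` if any point is on or behind
    the principal plane.  Complex-safe for complex-step differentiation.
    """
    X = np.asarray(X)
    Xc = np.einsum("ij,...j->...i", camera.R, X) + camera.t
    z = Xc[..., 2]
    if np.any(np.real(z) <= 1e-9):
        raise BehindCameraError("point at or behind the camera plane")
    x, y = Xc[..., 0] / z, Xc[..., 1] / z
    if any(camera.dist):
        x, y = _distort_normalised(x, y, camera.dist)
    fx, fy, cx, cy = camera.K
    return np.stack([fx * x + cx, fy * y + cy], axis=-1)


def undistort_points(camera: CameraModel, pixels) -> np.ndarray:
    """Invert intrinsics + distortion, returning normalised coordinates (..., 2)."""
    pixels = np.asarray(pixels, float)
    fx, fy, cx, cy = camera.K
    xd = (pixels[..., 0] - cx) / fx
    yd = (pixels[..., 1] - cy) / fy
    if not any(camera.dist):
        return np.stack([xd, yd], axis=-1)
    rd = np.sqrt(xd * xd + yd * yd)
    rd_safe = np.where(rd < 1e-12, 1e-12, rd)
    # Newton solve theta_d(theta) = rd for theta, then r = tan(theta)
    theta = np.array(rd, copy=True)
    for _ in range(25):
        t2 = theta * theta
        td = theta
        dtd = np.ones_like(theta)
        acc = t2
        for i, k in enumerate(camera.dist):
            td = td + k * theta * acc
            dtd = dtd + (2 * i + 3) * k * acc
            acc = acc * t2
        theta = theta - (td - rd) / dtd
    scale = np.where(rd < 1e-12, 1.0, np.tan(theta) / rd_safe)
    return np.stack([xd * scale, yd * scale], axis=-1)


def triangulate(
    cameras: Sequence[CameraModel],
    pixels: Sequence,
    refine: bool = True,
) -> tuple[np.ndarray, float]:
    """Least-squares world point from >= 2 views; returns (point, mean px residual).

    Linear DLT on undistorted rays, then (optionally) Gauss-Newton on the
    distorted reprojection error.  Raises :class:`DegenerateGeometryError`
    for fewer than two views or near-parallel ray geometry.
    """
    if len(cameras) < 2 or len(cameras) != len(pixels):
        raise DegenerateGeometryError("need matching pixels for at least two cameras")
    rows = []
    for cam, px in zip(cameras, pixels):
        nrm = undistort_points(cam, np.asarray(px, float))
        P = np.hstack([cam.R, cam.t[:, None]])  # normalised projection
        rows.append(nrm[..., 0] * P[2] - P[0])
        rows.append(nrm[..., 1] * P[2] - P[1])
    A = np.asarray(rows)
    _, s, Vt = np.linalg.svd(A)
    if s[-2] < 1e-9 * s[0]:
        raise DegenerateGeometryError("near-parallel rays: triangulation ill-posed")
    Xh = Vt[-1]
    if abs(Xh[3]) < 1e-12 * np.linalg.norm(Xh):
        raise DegenerateGeometryError("point at infinity")
    X = Xh[:3] / Xh[3]

    if refine:
        eye = np.eye(3)
        for _ in range(10):
            r = []
            J = []
            for cam, px in zip(cameras, pixels):
                r.append(project(cam, X) - np.asarray(px, float))
                h = 1e-200
                Jc = np.stack([np.imag(project(cam, X + 1j * h * e)) / h for e in eye], axis=-1)
                J.append(Jc)
            rv = np.concatenate(r)
            Jv = np.concatenate(J, axis=0)
            step = np.linalg.lstsq(Jv, -rv, rcond=None)[0]
            X = X + step
            if np.linalg.norm(step) < 1e-12:
                break

    resid = float(
        np.mean([np.linalg.norm(project(cam, X) - np.asarray(px, float)) for cam, px in zip(cameras, pixels)])
    )
    return X, resid
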