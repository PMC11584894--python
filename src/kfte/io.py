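"""File formats and trial bundles.

A trial directory holds plain-text artefacts:

* ``skeleton.json``   — the cylinder-link model,
* ``cameras.json``    — calibrated camera list,
* ``keypoints.csv``   — frame, camera, marker, x_px, y_px, confidence, visible,
* ``contacts.json``   — per-foot half-open stance frame intervals,
* ``truth_forces.csv``/``forces.csv`` — time_s, foot, Fx_N, Fy_N, Fz_N,
* ``manifest.json``   — config hash, seed, versions (reproducibility).

Frame indices are 0-based and contiguous per trial; stance intervals are
half-open [start, end); the world frame has x along the direction of travel
and z up, origin on the ground.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from kfte.camera import CameraModel, Observation2D
from kfte.contact import ContactPlan, GRFProfile
from kfte.multibody import SkeletonModel

__all__ = [
    "FormatError",
    "TrialBundle",
    "read_keypoints",
    "write_keypoints",
    "read_skeleton",
    "write_skeleton",
    "read_cameras",
    "write_cameras",
    "read_contacts",
    "write_contacts",
    "read_forces",
    "write_forces",
    "resample_forces",
    "write_manifest",
    "write_trajectory_csv",
    "write_forces_csv",
]

KEYPOINT_COLUMNS = ["frame", "camera", "marker", "x_px", "y_px", "confidence", "visible"]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# keypoints


def read_keypoints(path, confidence_floor: float = 0.0) -> list[Observation2D]:
    """Load a keypoint CSV into Observation2D records.

    Rows with confidence below ``confidence_floor`` are loaded but flagged
    invisible; malformed rows raise :class:`FormatError` naming the line.
    """
    df = pd.read_csv(path)
    missing = [c for c in KEYPOINT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    obs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            frame = int(row.frame)
            x, y = float(row.x_px), float(row.y_px)
            conf = float(row.confidence)
            visible = bool(int(row.visible))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed row at line {i}: {exc}") from exc
        if not (np.isfinite(x) and np.isfinite(y)):
            raise FormatError(f"{path}: non-finite pixel value at line {i}")
        if conf < confidence_floor:
            visible = False
        obs.append(
            Observation2D(
                frame=frame,
                camera=str(row.camera),
                marker=str(row.marker),
                pixel=(x, y),
                confidence=conf,
                visible=visible,
            )
        )
    return obs


def write_keypoints(path, observations: Sequence[Observation2D]) -> None:
    df = pd.DataFrame(
        {
            "frame": [o.frame for o in observations],
            "camera": [o.camera for o in observations],
            "marker": [o.marker for o in observations],
            "x_px": [o.pixel[0] for o in observations],
            "y_px": [o.pixel[1] for o in observations],
            "confidence": [o.confidence for o in observations],
            "visible": [int(o.visible) for o in observations],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# json blobs


def read_skeleton(path) -> SkeletonModel:
    with open(path) as f:
        return SkeletonModel.from_dict(json.load(f))


def write_skeleton(path, model: SkeletonModel) -> None:
    with open(path, "w") as f:
        json.dump(model.to_dict(), f, indent=1)


def read_cameras(path) -> dict[str, CameraModel]:
    with open(path) as f:
        data = json.load(f)
    cams = {}
    for i, d in enumerate(data):
        cam = CameraModel.from_dict(d)
        cams[cam.name or f"cam{i}"] = cam
    return cams


def write_cameras(path, cameras: Mapping[str, CameraModel]) -> None:
    out = []
    for name, cam in cameras.items():
        d = cam.to_dict()
        d["name"] = name
        out.append(d)
    with open(path, "w") as f:
        json.dump(out, f, indent=1)


def read_contacts(path, mu: float = 1.3) -> ContactPlan:
    with open(path) as f:
        data = json.load(f)
    mu = data.pop("mu", mu) if isinstance(data, dict) and "mu" in data else mu
    stance = {foot: [tuple(iv) for iv in ivs] for foot, ivs in data.items()}
    return ContactPlan(stance=stance, mu=mu)


def write_contacts(path, plan: ContactPlan) -> None:
    with open(path, "w") as f:
        json.dump(plan.to_dict(), f, indent=1)


# ---------------------------------------------------------------------------
# forces


def read_forces(path) -> dict[str, GRFProfile]:
    """Force CSV (time_s, foot, Fx_N, Fy_N, Fz_N) -> per-foot profiles."""
    df = pd.read_csv(path)
    need = ["time_s", "foot", "Fx_N", "Fy_N", "Fz_N"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = {}
    for foot, g in df.groupby("foot"):
        g = g.sort_values("time_s")
        t = g["time_s"].to_numpy()
        if len(t) < 2:
            raise FormatError(f"{path}: foot {foot!r} has fewer than two samples")
        h = float(np.median(np.diff(t)))
        forces = g[["Fx_N", "Fy_N", "Fz_N"]].to_numpy()
        out[str(foot)] = GRFProfile(forces, h, foot=str(foot), start_node=int(round(t[0] / h)))
    return out


def write_forces(path, profiles: Mapping[str, GRFProfile]) -> None:
    rows = []
    for foot, p in profiles.items():
        for i, f in enumerate(p.forces):
            rows.append(
                {
                    "time_s": (p.start_node + i) * p.h,
                    "foot": foot,
                    "Fx_N": f[0],
                    "Fy_N": f[1],
                    "Fz_N": f[2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def resample_forces(series: np.ndarray, f_in: float, f_out: float) -> np.ndarray:
    """Linear-interpolation resampling of a force series between sample rates.

    ``series`` is (n,) or (n, c) sampled at ``f_in`` Hz; the result covers
    the same time span at ``f_out`` Hz.  Impulse is preserved within ~1% for
    smooth inputs.
    """
    a = np.asarray(series, float)
    if a.size == 0:
        raise ValueError("empty series")
    if f_in <= 0 or f_out <= 0:
        raise ValueError("sample rates must be > 0")
    if f_in == f_out:
        return a.copy()
    n = a.shape[0]
    t_in = np.arange(n) / f_in
    t_out = np.arange(0.0, t_in[-1] + 0.5 / f_out, 1.0 / f_out)
    t_out = t_out[t_out <= t_in[-1] + 1e-12]
    if a.ndim == 1:
        return np.interp(t_out, t_in, a)
    return np.column_stack([np.interp(t_out, t_in, a[:, c]) for c in range(a.shape[1])])


# ---------------------------------------------------------------------------
# solution output


def write_trajectory_csv(path, solution) -> None:
    """Per-node CSV: frame, q..., tau..., |w|."""
    n, nq = solution.q.shape
    cols = {"frame": np.arange(n)}
    for i in range(nq):
        cols[f"q{i}"] = solution.q[:, i]
    for i in range(solution.tau.shape[1]):
        cols[f"tau{i}"] = solution.tau[:, i]
    cols["w_norm"] = np.linalg.norm(solution.w, axis=1)
    pd.DataFrame(cols).to_csv(path, index=False)


def write_forces_csv(path, solution) -> None:
    write_forces(path, solution.forces)


def write_manifest(path, config: Mapping, seed: int | None = None, extra: Mapping | None = None) -> None:
    """Run manifest: config hash + seed + versions, for bit-for-bit reruns."""
    import scipy

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__, "pandas": pd.__version__},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as f:
        json.dump(manifest, f, indent=1, default=str)


# ---------------------------------------------------------------------------
# trial bundle


@dataclass
class TrialBundle:
    """Paths + parsed contents of one trial directory."""

    root: Path
    model: SkeletonModel
    cameras: dict
    observations: list
    contact: ContactPlan
    truth_forces: dict | None = None
    frame_rate: float = 100.0

    @classmethod
    def load(cls, root, frame_rate: float | None = None) -> "TrialBundle":
        root = Path(root)
        for name in ("skeleton.json", "cameras.json", "keypoints.csv", "contacts.json"):
            if not (root / name).exists():
                raise FormatError(f"trial bundle missing {name} in {root}")
        manifest = {}
        if (root / "manifest.json").exists():
            with open(root / "manifest.json") as f:
                manifest = json.load(f)
        fr = frame_rate or float(
            manifest.get("frame_rate", manifest.get("config", {}).get("frame_rate", 100.0))
        )
        if fr <= 0:
            raise FormatError("frame rate must be > 0")
        model = read_skeleton(root / "skeleton.json")
        cameras = read_cameras(root / "cameras.json")
        observations = read_keypoints(root / "keypoints.csv")
        contact = read_contacts(root / "contacts.json")
        truth = read_forces(root / "truth_forces.csv") if (root / "truth_forces.csv").exists() else None
        frames = {o.frame for o in observations}
        n_nodes = max(frames)
        for foot, ivs in contact.stance.items():
            for a, b in ivs:
                if not (0 <= a < b <= n_nodes + 1):
                    raise FormatError(f"stance interval {(a, b)} of {foot!r} outside trial frames")
        return cls(
            root=root,
            model=model,
            cameras=cameras,
            observations=observations,
            contact=contact,
            truth_forces=truth,
            frame_rate=fr,
        )

    @property
    def n_nodes(self) -> int:
        return max(o.frame for o in self.observations)

    @property
    def h(self) -> float:
        return 1.0 / self.frame_rate
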