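"""Bundled skeleton presets.

``quadruped9`` is the reduced dog-sized model the synthetic trials and the
test-suite use (torso + four 2-segment legs, 9 links, 30 coordinates);
``cheetah17`` is the full 17-link, 54-coordinate cheetah layout (split
spine with a universal joint, neck+head, two tail segments, 3-segment
legs, 23 markers).  Both ship as editable JSON files under
``kfte/data`` — link lengths/masses/radii are morphometric estimates meant
to be replaced with subject-specific values.
"""

from __future__ import annotations

import json
from importlib import resources

from kfte.multibody import SkeletonModel

__all__ = ["load_preset", "quadruped9", "cheetah17", "PRESETS"]

PRESETS = ("quadruped9", "cheetah17")


def load_preset(name: str) -> SkeletonModel:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    with resources.files("kfte.data").joinpath(f"{name}.json").open() as f:
        return SkeletonModel.from_dict(json.load(f))


def quadruped9() -> SkeletonModel:
    """Reduced 9-link quadruped (30 generalized coordinates)."""
    return load_preset("quadruped9")


def cheetah17() -> SkeletonModel:
    """17-link cheetah (54 generalized coordinates, 23 markers)."""
    return load_preset("cheetah17")
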