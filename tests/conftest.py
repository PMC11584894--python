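"""Shared fixtures: small chain models and one synthetic walking trial.

The expensive end-to-end solves are session-scoped so the recovery and
mode-consistency checks share them.
"""

import numpy as np
import pytest

from kfte import estimator as est
from kfte import synthetic as syn
from kfte.multibody import JointSpec, LinkSpec, MarkerSpec, SkeletonModel


def make_chain(n_links: int, joints=True) -> SkeletonModel:
    """Serial chain of n cylinder links along +x with revolute joints."""
    lengths = [0.5, 0.4, 0.3][:n_links]
    masses = [2.0, 1.0, 0.5][:n_links]
    radii = [0.05, 0.04, 0.03][:n_links]
    links = [LinkSpec("l0", lengths[0], masses[0], radii[0])]
    for i in range(1, n_links):
        links.append(
            LinkSpec(f"l{i}", lengths[i], masses[i], radii[i], parent=f"l{i-1}", offset=lengths[i - 1])
        )
    jts = (
        [JointSpec("revolute", f"l{i-1}", f"l{i}") for i in range(1, n_links)] if joints else []
    )
    markers = [MarkerSpec("tip", f"l{n_links-1}", (lengths[n_links - 1], 0, 0))]
    return SkeletonModel(links, jts, markers)


@pytest.fixture(scope="session")
def chain1():
    return make_chain(1)


@pytest.fixture(scope="session")
def chain2():
    return make_chain(2)


@pytest.fixture(scope="session")
def chain3():
    return make_chain(3)


@pytest.fixture(scope="session")
def trial_clean():
    """Zero-noise synthetic walking trial (the package's reference fixture)."""
    return syn.generate_trial(seed=0, noise_px=0.0)


@pytest.fixture(scope="session")
def trial_noisy():
    """Same walk rendered with 2 px keypoint noise."""
    return syn.generate_trial(seed=1, noise_px=2.0)


@pytest.fixture(scope="session")
def solved_sinusoidal(trial_clean):
    return est.solve(trial_clean.problem("sinusoidal"), "sinusoidal", options={"maxiter": 60})


@pytest.fixture(scope="session")
def solved_freeform(trial_clean):
    return est.solve(trial_clean.problem("freeform"), "freeform", options={"maxiter": 60})


@pytest.fixture(scope="session")
def solved_noisy(trial_noisy):
    return est.solve(trial_noisy.problem("sinusoidal"), "sinusoidal", options={"maxiter": 250})
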