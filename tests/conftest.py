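"""Shared fixtures: small synthetic scenes and straight-axon stacks.

Everything is generated programmatically at test time; scenes use the
reduced desk-scale imaging field so a full render-extract-detect-track
cycle stays fast.
"""

import numpy as np
import pytest

import boutondyn as bd


@pytest.fixture(scope="session")
def desk_imaging():
    return bd.ImagingParams.desk()


@pytest.fixture(scope="session")
def small_scene():
    """A short (80 um) noise-free scene with default dynamics."""
    return bd.generate_scene(42, length_um=80.0)


@pytest.fixture(scope="session")
def small_analysis(small_scene):
    return bd.analyze_scene(small_scene)


@pytest.fixture(scope="session")
def straight_path():
    """A straight axon through the middle of the desk field."""
    img = bd.ImagingParams.desk()
    xs = np.linspace(5.0, 35.0, 301)
    pts = np.column_stack([
        xs, np.full_like(xs, 20.0), np.full_like(xs, img.depth_um / 2),
    ])
    return bd.AxonPath(points=pts, trace_id="straight")


def make_obs(day, positions_sizes, axon_id="ax"):
    """Observation list helper for tracking tests."""
    return [
        bd.BoutonObservation(obs_id=i, axon_id=axon_id, session_day=day,
                             position_s=float(p), size=float(s))
        for i, (p, s) in enumerate(positions_sizes)
    ]


@pytest.fixture
def obs_factory():
    return make_obs
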