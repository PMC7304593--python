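"""End-to-end convenience pipeline: scene -> stacks -> profiles -> tracks.

Ties the stages together for simulation studies and for analysing a
scene directory written by :func:`boutondyn.synthetic.write_scene`:
render (or read) each session's stack, extract the arc-length intensity
profile along the trace, compute the bouton-weight profile, detect
peaks, and chain detections into identity tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import (
    BoutonObservation,
    DetectionThresholds,
    detect_putative,
    shaft_baseline,
    weight_profile,
)
from .profiles import (
    DEFAULT_EXTRACTION_RADIUS,
    DEFAULT_STEP_UM,
    SessionStack,
    extract_profile,
    resample_path,
)
from .synthetic import AxonScene, render_stack, render_tube
from .tracking import BoutonTrack, build_tracks, tracks_to_events


@dataclass
class SceneAnalysis:
    """Everything the pipeline computed for one field."""

    scene_id: str
    traced_length_um: float
    session_days: list[int]
    observations_by_day: dict[int, list[BoutonObservation]]
    tracks: list[BoutonTrack]

    @property
    def events(self):
        return tracks_to_events(self.tracks, self.session_days)


def detect_stack(
    stack: SessionStack,
    rpath,
    thresholds: DetectionThresholds | None = None,
    radius: float = DEFAULT_EXTRACTION_RADIUS,
    baseline_sigma_um: float = 5.0,
    axon_id: str = "axon",
) -> list[BoutonObservation]:
    """Profile -> baseline -> weight -> peaks for one session's stack."""
    profile = extract_profile(stack, rpath, radius=radius)
    baseline = shaft_baseline(profile, sigma_um=baseline_sigma_um)
    wp = weight_profile(profile, baseline)
    return detect_putative(wp, thresholds, axon_id=axon_id,
                           session_day=stack.session_day)


def analyze_scene(
    scene: AxonScene,
    thresholds: DetectionThresholds | None = None,
    step: float = DEFAULT_STEP_UM,
    radius: float = DEFAULT_EXTRACTION_RADIUS,
    noise_seed=None,
) -> SceneAnalysis:
    """Run the full detection + tracking pipeline on a synthetic scene."""
    thresholds = thresholds or DetectionThresholds()
    rpath = resample_path(scene.path, step)
    tube = render_tube(scene.path, scene.imaging)
    days = list(scene.dynamics.session_days)
    entropy = np.random.SeedSequence(
        [scene.seed if noise_seed is None else noise_seed]
    ).spawn(len(days))

    obs_by_day: dict[int, list[BoutonObservation]] = {}
    for child, day in zip(entropy, days):
        stack = render_stack(
            scene.path, scene.boutons, day, scene.imaging,
            arc_offset=scene.arc_offset_by_session.get(day, 0.0),
            tube=tube, seed=child,
        )
        obs_by_day[day] = detect_stack(
            stack, rpath, thresholds, radius=radius, axon_id=scene.scene_id,
        )
    tracks = build_tracks(
        obs_by_day, thresholds, axon_id=scene.scene_id,
        axon_length=scene.path.total_length,
    )
    return SceneAnalysis(
        scene_id=scene.scene_id,
        traced_length_um=scene.path.total_length,
        session_days=days,
        observations_by_day=obs_by_day,
        tracks=tracks,
    )


def analyze_scene_dir(
    scene_dir,
    thresholds: DetectionThresholds | None = None,
    step: float = DEFAULT_STEP_UM,
    radius: float = DEFAULT_EXTRACTION_RADIUS,
) -> SceneAnalysis:
    """Analyse a scene directory (TIFF stacks + SWC trace) from disk."""
    import glob
    import os

    from .profiles import read_stack, read_swc

    paths = read_swc(os.path.join(scene_dir, "trace.swc"))
    path = paths[0]
    rpath = resample_path(path, step)
    obs_by_day = {}
    for tif in sorted(glob.glob(os.path.join(scene_dir, "session_day*.tif"))):
        stack = read_stack(tif)
        obs_by_day[stack.session_day] = detect_stack(
            stack, rpath, thresholds, radius=radius, axon_id=path.trace_id,
        )
    days = sorted(obs_by_day)
    tracks = build_tracks(
        obs_by_day, thresholds, axon_id=path.trace_id,
        axon_length=path.total_length,
    )
    return SceneAnalysis(
        scene_id=path.trace_id,
        traced_length_um=path.total_length,
        session_days=days,
        observations_by_day=obs_by_day,
        tracks=tracks,
    )
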