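"""Shared fixtures: synthetic validation scenes and detection factories."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isletflow import SceneConfig, analyze_frames, make_scene, validate_config
from isletflow.segmentation import Detection

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: micrometers per pixel of the reference chip (1 mm marker spanning 460 px)
DELTA_UM_PER_PX = 1000.0 / 460.0

VALIDATION_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def pipeline_config():
    return validate_config({"scale": {"delta_um_per_px": DELTA_UM_PER_PX}})


@pytest.fixture(scope="session")
def validation_runs(pipeline_config):
    """Five seed-fixed 50-islet validation scenes, fully analyzed."""
    runs = []
    for seed in VALIDATION_SEEDS:
        frames, background, gt = make_scene(SceneConfig(n_islets=50, seed=seed))
        tracks, records, report = analyze_frames(frames, background, pipeline_config)
        runs.append(
            SimpleNamespace(
                seed=seed, gt=gt, tracks=tracks, records=records, report=report
            )
        )
    return runs


@pytest.fixture(scope="session")
def small_scene():
    """A light 6-islet scene for pipeline and tracking tests."""
    config = SceneConfig(
        n_islets=6, frame_size=(360, 240), radius_range=(12.0, 18.0), seed=7
    )
    frames, background, gt = make_scene(config)
    return SimpleNamespace(
        config=config, frames=frames, background=background, gt=gt
    )


@pytest.fixture(scope="session")
def small_run(small_scene, pipeline_config):
    tracks, records, report = analyze_frames(
        small_scene.frames, small_scene.background, pipeline_config
    )
    return SimpleNamespace(
        scene=small_scene, tracks=tracks, records=records, report=report
    )


def match_track_to_islet(track, gt) -> int:
    """Ground-truth islet id nearest a track's middle detection."""
    det = track.detections[len(track.detections) // 2]
    rows = gt.frame_rows(det.frame_index)
    idx = (
        (rows.cx - det.centroid_x) ** 2 + (rows.cy - det.centroid_y) ** 2
    ).idxmin()
    return int(rows.loc[idx, "islet_id"])


@pytest.fixture(scope="session")
def track_matcher():
    return match_track_to_islet


def make_detection(
    x: float = 0.0,
    y: float = 0.0,
    area: float = 400.0,
    frame_index: int = 0,
    major: float | None = None,
    minor: float | None = None,
    perimeter: float | None = None,
    hull: float | None = None,
    dtz: float = 0.0,
    touches_edge: bool = False,
) -> Detection:
    """Hand-built detection with geometrically consistent defaults."""
    r = np.sqrt(area / np.pi)
    return Detection(
        frame_index=frame_index,
        centroid_x=x,
        centroid_y=y,
        area_px=area,
        perimeter_px=perimeter if perimeter is not None else 2 * np.pi * r,
        contour=np.empty((0, 2)),
        hull_area_px=hull if hull is not None else area,
        ellipse_major_semiaxis_px=major if major is not None else r,
        ellipse_minor_semiaxis_px=minor if minor is not None else r,
        dtz_positive_px=dtz,
        touches_edge=touches_edge,
    )


@pytest.fixture(scope="session")
def detection_factory():
    return make_detection
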