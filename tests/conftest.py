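"""Shared fixtures: small rendered scenes and a compact trained tracker."""

from __future__ import annotations

import numpy as np
import pytest

from reachtrack.stereo import default_rig
from reachtrack.synth import (ReachKinematicsParams, SceneParams,
                              render_stereo_video, simulate_trial)
from reachtrack.tracker import CascadeTracker


@pytest.fixture(scope="session")
def kin() -> ReachKinematicsParams:
    return ReachKinematicsParams()


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def small_scene() -> SceneParams:
    # compact frames keep unit tests fast; the acceptance suite uses defaults
    size = (120, 100)
    return SceneParams(image_size=size, blob_sigma=5.0,
                       cameras=default_rig(focal_px=300.0, image_size=size))


@pytest.fixture(scope="session")
def rendered_small(kin, small_scene):
    trial = simulate_trial(kin, None, seed=7, cue_frame=60, n_frames=300)
    return render_stereo_video(trial, small_scene, seed=5)


@pytest.fixture(scope="session")
def small_tracker(rendered_small) -> CascadeTracker:
    idx = np.linspace(0, 299, 80).astype(int)
    model = CascadeTracker(n_stages=40, n_ferns=25, n_candidate_features=150,
                           n_selected_features=25, feature_radius=40.0,
                           random_state=0)
    model.fit(list(rendered_small.frames["front"][idx]),
              rendered_small.tracks["front"][idx])
    return model


@pytest.fixture(scope="session")
def held_out_frames(rendered_small):
    idx = np.linspace(0, 299, 80).astype(int)
    hold = np.setdiff1d(np.arange(300), idx)[::4][:40]
    return (rendered_small.frames["front"][hold],
            rendered_small.tracks["front"][hold])
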