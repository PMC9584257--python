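import numpy as np
import pytest

from fidtrack import generate_dictionary
from fidtrack.roi import RegionOfInterest
from fidtrack.scenes import Pose, SceneSpec, TrackSegment, generate_scene


@pytest.fixture(scope="session")
def dictionary():
    """The study configuration: 16 markers, 4x4 grid (16-bit code words)."""
    return generate_dictionary(16, 4, 1, seed=7)


@pytest.fixture(scope="session")
def spaced_rois():
    return [RegionOfInterest(1, "food", 30, 40, 100, 110),
            RegionOfInterest(2, "water", 190, 40, 100, 110)]


def render_scene_single(dictionary, marker_id, pose, frame_shape=(200, 200),
                        n_frames=1, **spec_kw):
    """One marker at a fixed pose; returns (frames, truth)."""
    spec = SceneSpec(frame_shape=frame_shape, n_frames=n_frames, rois=[],
                     tracks={marker_id: [TrackSegment(0, n_frames, pose)]},
                     **spec_kw)
    return generate_scene(spec, dictionary)


@pytest.fixture(scope="session")
def single_marker_frame(dictionary):
    frames, truth = render_scene_single(dictionary, 10, Pose((100, 100), 48))
    return frames[0], truth
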