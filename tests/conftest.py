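"""Shared fixtures: the packaged stimulus, tiny stimuli and simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

import gazediag as g
from gazediag.stimulus_model import Aoi, MovieClip, StimulusSet


@pytest.fixture(scope="session")
def stimulus():
    return g.default_stimulus()


@pytest.fixture(scope="session")
def tiny_stimulus():
    """One 1-second clip with two overlapping AOIs (circle inside rect)."""
    aois = (
        Aoi(aoi_id="clip1.inner", clip_id="clip1", shape="circle",
            label="face", cx=200.0, cy=200.0, r=50.0),
        Aoi(aoi_id="clip1.outer", clip_id="clip1", shape="rect",
            label="human", x=100.0, y=100.0, w=300.0, h=300.0),
    )
    clip = MovieClip(clip_id="clip1", paradigm="social", duration_s=1.0,
                     order_index=1, aois=aois)
    return StimulusSet(clips=(clip,))


def make_recording(pid, clip_id, xs, ys, valid=None, t0=0):
    """Build a GazeRecordingSet for one clip from coordinate lists."""
    n = len(xs)
    valid = [True] * n if valid is None else list(valid)
    rec = g.GazeRecordingSet(participant_id=pid)
    rec.clips[clip_id] = pd.DataFrame(
        {
            "t_ms": np.arange(t0, t0 + n, dtype=np.int64) * 20,
            "x_px": np.asarray(xs, dtype=float),
            "y_px": np.asarray(ys, dtype=float),
            "valid": np.asarray(valid, dtype=bool),
        }
    )
    return rec


@pytest.fixture(scope="session")
def small_cohort(stimulus):
    """Study-flavoured but small simulated cohort (16 ASD / 24 TD)."""
    cfg = g.SimConfig(n_asd=16, n_td=24, seed=11, low_fixation_fraction=0.0)
    cohort = g.simulate_cohort(stimulus, cfg)
    matrix = g.build_attribute_matrix(cohort.recordings, stimulus)
    return cohort, matrix
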