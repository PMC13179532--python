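import numpy as np
import pandas as pd
import pytest

from soundturn import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_blobs(rng):
    """Well-separated 2-D blobs at (-0.5, 0), (0, 0), (0.5, 0), sd 0.05."""
    centres = np.array([[-0.5, 0.0], [0.0, 0.0], [0.5, 0.0]])
    X = np.concatenate([c + 0.05 * rng.standard_normal((300, 2)) for c in centres])
    labels = np.repeat([0, 1, 2], 300)
    return X, centres, labels


def make_frames(timestamps, yaw=None, **overrides):
    """Minimal hand-built frame table with all dialect columns."""
    n = len(timestamps)
    df = pd.DataFrame(0.0, index=range(n), columns=list(synth.FRAME_COLUMNS))
    df["frame"] = np.arange(1, n + 1)
    df["timestamp"] = np.asarray(timestamps, float)
    df["success"] = 1.0
    df["gaze_0_z"] = -1.0
    df["gaze_1_z"] = -1.0
    if yaw is not None:
        df["pose_Ry"] = np.asarray(yaw, float)
    for col, vals in overrides.items():
        df[col] = vals
    return df


def make_trial(pid="T01", group="toddler", idx=0, stimulus="ba", side="left",
               onset=10.0):
    return synth.TrialRecord(pid, group, idx, stimulus, side, onset)


@pytest.fixture(scope="session")
def small_cohort():
    """4 infants + 6 toddlers, default response model (shared, read-only)."""
    return synth.simulate_cohort(4, 6, seed=777)
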