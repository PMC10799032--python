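import numpy as np
import pandas as pd
import pytest

from surgskill.channels import Montage
from surgskill.recordings import EegRecording, GazeRecording, gaze_columns


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid_montage():
    """A 4x4 grid of channels projected onto the unit sphere."""
    labels = [f"ch{i}" for i in range(16)]
    xs, ys = np.meshgrid(np.linspace(-0.5, 0.5, 4), np.linspace(-0.5, 0.5, 4))
    pos = np.column_stack([xs.ravel(), ys.ravel(),
                           np.sqrt(1 - xs.ravel() ** 2 - ys.ravel() ** 2)])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(labels, pos)


@pytest.fixture
def random_recording(rng, grid_montage):
    samples = rng.standard_normal((16, 1000)) * 20
    return EegRecording(grid_montage.labels, 500.0, samples)


def make_gaze(n=100, fs=50.0, dominant_eye="right", invalid=(),
              gaze_fn=None, diam_fn=None, pos_fn=None):
    """Hand-built gaze recording for unit tests."""
    t = np.arange(n) / fs
    data = {"time_s": t}
    invalid = set(invalid)
    valid = np.array([i not in invalid for i in range(n)])
    for e in ("L", "R"):
        g = gaze_fn(n) if gaze_fn else np.tile([0.0, 0.0, 1.0], (n, 1))
        p = pos_fn(n) if pos_fn else np.tile([30.0, 0.0, 40.0], (n, 1))
        d = diam_fn(n) if diam_fn else np.full(n, 3.5)
        g = g.astype(float).copy()
        p = p.astype(float).copy()
        d = d.astype(float).copy()
        g[~valid] = np.nan
        p[~valid] = np.nan
        d[~valid] = np.nan
        data[f"gaze_{e}_x"], data[f"gaze_{e}_y"], data[f"gaze_{e}_z"] = g.T
        (data[f"pupil_pos_{e}_x"], data[f"pupil_pos_{e}_y"],
         data[f"pupil_pos_{e}_z"]) = p.T
        data[f"pupil_diam_{e}"] = d
        data[f"valid_{e}"] = valid.astype(int)
    df = pd.DataFrame(data)[gaze_columns()]
    return GazeRecording(df, fs, dominant_eye)
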