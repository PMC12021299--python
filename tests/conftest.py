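import numpy as np
import pandas as pd
import pytest

from crowdcontact.proximity import score_dataset
from crowdcontact.scene import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_detections(frames):
    """Detection table from {(camera_id, frame_id): [(x, y), ...]}."""
    rows = []
    for (cam, fid), pts in frames.items():
        for pid, (x, y) in enumerate(pts):
            rows.append((cam, fid, pid, float(x), float(y)))
    return pd.DataFrame(rows, columns=["camera_id", "frame_id", "person_id", "x_m", "y_m"])


@pytest.fixture(scope="session")
def default_dataset():
    """Full calibrated 49-camera dataset plus its scored tables (shared)."""
    cfg = GeneratorConfig(seed=20_240_117)
    det = generate_dataset(cfg)
    persons, frames = score_dataset(det, cfg.threshold_m)
    return cfg, det, persons, frames


@pytest.fixture
def random_frames_table(rng):
    """50 random frames (3-40 persons each) on a 36 x 18 m rectangle."""
    frames = {}
    for f in range(50):
        n = int(rng.integers(3, 41))
        pts = rng.random((n, 2)) * np.array([36.0, 18.0])
        frames[("camA", f"f{f:03d}")] = [tuple(p) for p in pts]
    return make_detections(frames)
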