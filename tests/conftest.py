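import numpy as np
import pandas as pd
import pytest

from heartbend.track_io import TrackSet


def make_trackset(rows, **kwargs) -> TrackSet:
    """Build a TrackSet from (track_id, t_index, t_hours, x, y, z, region) rows."""
    df = pd.DataFrame(
        rows,
        columns=["track_id", "t_index", "t_hours", "x_um", "y_um", "z_um", "region"],
    )
    return TrackSet(records=df, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_region_frame():
    """One frame with AV cells symmetric about the origin, ventricle centroid
    at (5,0,0) and atrium centroid at (0,-5,0)."""
    rows = [
        ("c1", 0, 0.0, 1.0, 0.0, 0.0, "avcanal"),
        ("c2", 0, 0.0, -1.0, 0.0, 0.0, "avcanal"),
        ("v1", 0, 0.0, 5.0, 1.0, 0.0, "ventricle"),
        ("v2", 0, 0.0, 5.0, -1.0, 0.0, "ventricle"),
        ("a1", 0, 0.0, 1.0, -5.0, 0.0, "atrium"),
        ("a2", 0, 0.0, -1.0, -5.0, 0.0, "atrium"),
    ]
    return make_trackset(rows)


def rodrigues_matrix(axis, angle_deg):
    """Independent rotation-matrix oracle: R = I + sinθ·K + (1−cosθ)·K²."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
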