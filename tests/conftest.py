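import numpy as np
import pandas as pd
import pytest

import facekin as fk


@pytest.fixture(scope="session")
def template():
    return fk.make_template_face(seed=0)


@pytest.fixture(scope="session")
def small_study():
    """A small but full synthetic study shared across model tests."""
    cfg = fk.StudyConfig(n_clips=30, nt_raters=120, include_hat=False)
    return fk.make_study(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_track(rng, n_frames=10, n_landmarks=5, clip_id="c0", actor="a0"):
    frames = rng.normal(size=(n_frames, n_landmarks, 2))
    return fk.ClipTrack(
        clip_id=clip_id, frames=frames, actor_id=actor, emotion="joy"
    )


@pytest.fixture()
def tiny_track(rng):
    return random_track(rng)


def standardized_design(n, r, b1, b2, seed=0):
    """Design with *exact* sample moments: two mean-0, sd-1 predictors with
    sample correlation exactly ``r`` and a response with unit sample variance
    whose true standardized coefficients are (b1, b2).

    Built from an orthonormalized random basis, so fitted standardized
    coefficients and R^2 = b1^2 + b2^2 + 2*b1*b2*r are exact.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n, 3))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    scale = np.sqrt(n - 1)
    x1 = q[:, 0] * scale
    x2 = (r * q[:, 0] + np.sqrt(1 - r**2) * q[:, 1]) * scale
    r2 = b1**2 + b2**2 + 2 * b1 * b2 * r
    assert 0 <= r2 < 1
    y = b1 * x1 + b2 * x2 + np.sqrt(1 - r2) * q[:, 2] * scale
    X = pd.DataFrame(
        {"dist_neutral_mean": x1, "speed_mean": x2},
        index=[f"c{i}" for i in range(n)],
    )
    return X, pd.Series(y, index=X.index), r2


def write_openface_fixture(path, n_frames=2, n_landmarks=68, seed=0,
                           header_space=False, drop_column=None):
    """Write a minimal OpenFace-style CSV fixture."""
    rng = np.random.default_rng(seed)
    cols = {"frame": np.arange(n_frames)}
    prefix = " " if header_space else ""
    for i in range(n_landmarks):
        cols[f"{prefix}x_{i}"] = rng.uniform(0, 640, n_frames)
    for i in range(n_landmarks):
        cols[f"{prefix}y_{i}"] = rng.uniform(0, 480, n_frames)
    df = pd.DataFrame(cols)
    if drop_column:
        df = df.drop(columns=[c for c in df.columns if c.strip() == drop_column])
    df.to_csv(path, index=False)
    return df
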