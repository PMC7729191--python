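"""Frame-wise kinematic measures of facial expressions and their aggregates.

The displacement of an expression frame from a baseline face is summarized by
the root mean square deviation (RMSD) over landmarks of the per-landmark
Euclidean distances.  Applied between consecutive frames the same statistic
gives the root mean squared speed; applied to finite-difference velocity
vectors it gives the root mean squared acceleration magnitude.  Squaring
means opposing landmark motions accumulate instead of canceling.

Two baseline faces are supported: the *clip neutral face* (the clip's first,
neutral frame) and the *actor mean face* (per-coordinate mean over all frames
of all clips of an actor).  Each frame-wise series is aggregated with both
the mean and the maximum, yielding eight candidate measures per clip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FEATURE_COLUMNS
from .types import ClipTrack, as_shape

MEASURES = ("dist_neutral", "dist_mean_face", "speed", "accel")


@dataclass
class BaselineFace:
    """A reference landmark configuration displacement is measured from."""

    shape: np.ndarray
    kind: str            # "clip_neutral" or "actor_mean"
    provenance: str      # clip_id or actor_id

    def __post_init__(self) -> None:
        self.shape = as_shape(self.shape)


@dataclass
class MeasureSeries:
    """One frame-wise measure for one clip.

    For a T-frame clip the support is T values for the distance measures,
    T-1 for speed and T-2 for acceleration; each series is aggregated over
    its own support.
    """

    clip_id: str
    measure: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def aggregate(self, how: str) -> float:
        return aggregate_series(self.values, how)


def point_distance(p_a, p_b) -> float:
    """Euclidean distance between two landmark positions."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    return float(np.hypot(*(p_b - p_a)))


def rmsd(shape_a, shape_b) -> float:
    """Root mean square deviation between two landmark configurations.

    sqrt( sum_p d(p_a, p_b)^2 / N ) — the total structural distance between
    two tracked expressions.
    """
    a = as_shape(shape_a)
    b = as_shape(shape_b, n_landmarks=a.shape[0])
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _rmsd_to(frames: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(np.sum((frames - baseline) ** 2, axis=2), axis=1))


def clip_neutral_face(track: ClipTrack) -> BaselineFace:
    """Baseline from the clip's first frame (the actor at rest)."""
    return BaselineFace(track.frames[0].copy(), "clip_neutral", track.clip_id)


def actor_mean_face(tracks: list[ClipTrack]) -> BaselineFace:
    """Per-coordinate mean over the pooled frames of all clips of one actor.

    Clips contribute one row per frame, so longer clips carry proportionally
    more weight.
    """
    if not tracks:
        raise ValueError("need at least one track")
    actors = {t.actor_id for t in tracks}
    if len(actors) > 1:
        raise ValueError(f"tracks mix actors: {sorted(actors)}")
    pooled = np.concatenate([t.frames for t in tracks], axis=0)
    return BaselineFace(pooled.mean(axis=0), "actor_mean", tracks[0].actor_id)


def distance_series(track: ClipTrack, baseline: BaselineFace) -> MeasureSeries:
    """RMSD of every frame to the baseline face (length T)."""
    if baseline.shape.shape[0] != track.n_landmarks:
        raise ValueError("baseline landmark count does not match track")
    name = (
        "dist_neutral" if baseline.kind == "clip_neutral" else "dist_mean_face"
    )
    return MeasureSeries(
        track.clip_id, name, _rmsd_to(track.frames, baseline.shape)
    )


def speed_series(track: ClipTrack) -> MeasureSeries:
    """Root mean squared speed between consecutive frames (length T-1).

    With a frame offset of one, per-landmark speed equals the Euclidean
    distance moved per frame, so the series is the RMSD between neighbours.
    """
    if track.n_frames < 2:
        raise ValueError("speed needs at least 2 frames")
    vals = _rmsd_to(track.frames[1:], track.frames[:-1])
    return MeasureSeries(track.clip_id, "speed", vals)


def acceleration_series(
    track: ClipTrack, denominator: int = 2
) -> MeasureSeries:
    """Root mean squared acceleration magnitude (length T-2).

    Per-landmark acceleration between frame f and f+2 is the difference of the
    two consecutive velocity vectors divided by the spanned interval.  The
    default ``denominator=2`` divides by the two-frame span; ``denominator=1``
    treats the raw velocity difference as the acceleration.
    """
    if track.n_frames < 3:
        raise ValueError("acceleration needs at least 3 frames")
    if denominator not in (1, 2):
        raise ValueError("accel denominator must be 1 or 2")
    vel = track.frames[1:] - track.frames[:-1]          # (T-1, N, 2)
    acc = (vel[1:] - vel[:-1]) / denominator            # (T-2, N, 2)
    vals = np.sqrt(np.mean(np.sum(acc**2, axis=2), axis=1))
    return MeasureSeries(track.clip_id, "accel", vals)


def aggregate_series(values, how: str) -> float:
    """Aggregate a frame-wise series by its mean or maximum."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty series")
    if how == "mean":
        return float(values.mean())
    if how == "max":
        return float(values.max())
    raise ValueError(f"unknown aggregation {how!r}")


def compute_clip_features(
    track: ClipTrack,
    clip_neutral: BaselineFace,
    actor_mean: BaselineFace,
    accel_denominator: int = 2,
) -> dict:
    """The eight aggregated measures {mean, max} x {dist, dist-mean, speed, accel}."""
    series = {
        "dist_neutral": distance_series(track, clip_neutral),
        "dist_mean_face": distance_series(track, actor_mean),
        "speed": speed_series(track),
        "accel": acceleration_series(track, accel_denominator),
    }
    out: dict = {"clip_id": track.clip_id}
    for name, s in series.items():
        out[f"{name}_mean"] = s.aggregate("mean")
        out[f"{name}_max"] = s.aggregate("max")
    return out


def feature_table(
    tracks: list[ClipTrack], accel_denominator: int = 2
) -> pd.DataFrame:
    """Per-clip feature table for a set of normalized tracks.

    Actor mean faces are built by pooling every clip of each actor in the
    input.  Returns a DataFrame indexed by clip_id with the eight measures in
    canonical order.
    """
    if not tracks:
        raise ValueError("no tracks given")
    by_actor: dict[str, list[ClipTrack]] = {}
    for t in tracks:
        by_actor.setdefault(t.actor_id, []).append(t)
    mean_faces = {a: actor_mean_face(ts) for a, ts in by_actor.items()}
    rows = [
        compute_clip_features(
            t, clip_neutral_face(t), mean_faces[t.actor_id], accel_denominator
        )
        for t in tracks
    ]
    df = pd.DataFrame(rows).set_index("clip_id")
    return df[FEATURE_COLUMNS]


class KinematicFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer from normalized clip tracks to the 8-measure feature table.

    Stateless apart from parameters; ``fit`` exists for pipeline
    compatibility.  ``transform`` accepts a list of :class:`ClipTrack` and
    returns the clip-indexed feature DataFrame.
    """

    def __init__(self, accel_denominator: int = 2):
        self.accel_denominator = accel_denominator

    def fit(self, X, y=None):
        self.n_features_out_ = len(FEATURE_COLUMNS)
        return self

    def transform(self, X) -> pd.DataFrame:
        return feature_table(list(X), self.accel_denominator)
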