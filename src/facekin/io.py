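"""Reading and writing landmark tracks, rating tables and feature tables.

The landmark format is the OpenFace 2-D CSV layout: one row per video frame
with a ``frame`` column, optional ``timestamp`` / ``confidence`` / ``success``
columns, and coordinate columns ``x_0 .. x_{N-1}``, ``y_0 .. y_{N-1}``.
Different OpenFace releases disagree on whether header names carry a leading
space; headers are whitespace-stripped on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ClipTrack

#: canonical order of the eight per-clip kinematic measures
FEATURE_COLUMNS = [
    "dist_neutral_mean",
    "dist_neutral_max",
    "dist_mean_face_mean",
    "dist_mean_face_max",
    "speed_mean",
    "speed_max",
    "accel_mean",
    "accel_max",
]

VALID_GROUPS = {"NT", "ASD", "HAT"}
RATING_SCALE = (1, 101)


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_openface_csv(
    path,
    clip_id: str | None = None,
    actor_id: str = "",
    emotion: str = "",
    confidence_threshold: float = 0.0,
) -> ClipTrack:
    """Read one clip's landmark time series from an OpenFace-style CSV.

    The landmark count N is inferred from the ``x_*`` columns.  Frames are
    returned ordered by the file's frame index; original indices are kept in
    ``source_frame_index``.  Frames whose tracking confidence falls below
    ``confidence_threshold`` are flagged in ``low_confidence_mask`` but never
    dropped here (dropping is a pipeline decision).
    """
    df = _read_table(path)
    if "frame" not in df.columns:
        raise FormatError(f"{path}: missing required column 'frame'")
    xcols = sorted(
        (c for c in df.columns if re.fullmatch(r"x_\d+", c)),
        key=lambda c: int(c.split("_")[1]),
    )
    if not xcols:
        raise FormatError(f"{path}: no landmark columns x_0..x_N found")
    n = int(xcols[-1].split("_")[1]) + 1
    needed = [f"x_{i}" for i in range(n)] + [f"y_{i}" for i in range(n)]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing coordinate column(s) {missing}")

    coords = df[needed]
    numeric = coords.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~coords.isna()
    if bad.to_numpy().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy()))
        col = bad.columns[int(np.argmax(bad.iloc[row].to_numpy()))]
        raise FormatError(
            f"{path}: non-numeric value in column {col!r} at data row {row}"
        )
    if numeric.isna().to_numpy().any():
        raise FormatError(f"{path}: missing coordinate values")

    order = np.argsort(df["frame"].to_numpy(), kind="stable")
    frames = np.empty((len(df), n, 2))
    frames[:, :, 0] = numeric[[f"x_{i}" for i in range(n)]].to_numpy()[order]
    frames[:, :, 1] = numeric[[f"y_{i}" for i in range(n)]].to_numpy()[order]

    confidence = None
    low_mask = None
    if "confidence" in df.columns:
        confidence = df["confidence"].to_numpy(dtype=float)[order]
        low_mask = confidence < confidence_threshold
    return ClipTrack(
        clip_id=clip_id if clip_id is not None else Path(path).stem,
        frames=frames,
        actor_id=actor_id,
        emotion=emotion,
        confidence=confidence,
        source_frame_index=df["frame"].to_numpy()[order],
        low_confidence_mask=low_mask,
    )


def write_openface_csv(track: ClipTrack, path) -> None:
    """Write a track back to the OpenFace CSV layout (frame, x_*, y_*)."""
    n = track.n_landmarks
    data = {"frame": np.arange(track.n_frames)}
    if track.source_frame_index is not None:
        data["frame"] = track.source_frame_index
    if track.confidence is not None:
        data["confidence"] = track.confidence
    for i in range(n):
        data[f"x_{i}"] = track.frames[:, i, 0]
    for i in range(n):
        data[f"y_{i}"] = track.frames[:, i, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_ratings(path) -> pd.DataFrame:
    """Read and validate a ratings table.

    Expects columns ``rater_id, group, clip_id, arousal, valence``; group
    labels are upper-cased, and both ratings must lie on the 1..101 visual
    analog scale.  Returns one row per (rater, clip).
    """
    df = _read_table(path)
    required = ["rater_id", "group", "clip_id", "arousal", "valence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[required].copy()
    df["group"] = df["group"].astype(str).str.strip().str.upper()
    unknown = set(df["group"]) - VALID_GROUPS
    if unknown:
        raise FormatError(f"{path}: unknown group label(s) {sorted(unknown)}")
    lo, hi = RATING_SCALE
    for col in ("arousal", "valence"):
        vals = pd.to_numeric(df[col], errors="coerce")
        out = ~vals.between(lo, hi) | vals.isna()
        if out.any():
            rows = list(df.index[out][:10])
            raise FormatError(
                f"{path}: {col} outside [{lo}, {hi}] at row(s) {rows}"
            )
        df[col] = vals.astype(int)
    dup = df.duplicated(subset=["rater_id", "clip_id"])
    if dup.any():
        raise FormatError(
            f"{path}: duplicate (rater_id, clip_id) at row(s) "
            f"{list(df.index[dup][:10])}"
        )
    df["rater_id"] = df["rater_id"].astype(str)
    df["clip_id"] = df["clip_id"].astype(str)
    return df


def read_clip_metadata(path) -> pd.DataFrame:
    """Read the clip metadata table (clip_id, actor_id, emotion_category)."""
    df = _read_table(path)
    required = ["clip_id", "actor_id", "emotion_category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = df[required].astype(str)
    if out["clip_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate clip_id in metadata")
    return out


def write_feature_table(features: pd.DataFrame, path) -> None:
    """Write the per-clip feature table as CSV (clip_id + the 8 measures)."""
    if len(features) == 0:
        raise ValueError("refusing to write an empty feature table")
    df = features.copy()
    if df.index.name == "clip_id":
        df = df.reset_index()
    missing = [c for c in ["clip_id", *FEATURE_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing column(s) {missing}")
    if df["clip_id"].duplicated().any():
        raise ValueError("duplicate clip_id in feature table")
    df[["clip_id", *FEATURE_COLUMNS]].to_csv(
        path, index=False, float_format="%.17g"
    )


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = _read_table(path)
    missing = [c for c in ["clip_id", *FEATURE_COLUMNS] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df["clip_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate clip_id")
    return df.set_index("clip_id")[FEATURE_COLUMNS].astype(float)
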