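"""Core containers: landmark shapes, clip tracks and validation helpers.

A *face shape* is one frame's landmark configuration, stored as a float
array of shape ``(n_landmarks, 2)`` (x, y).  A :class:`ClipTrack` is the
ordered sequence of face shapes tracked over one video clip, together with
clip-level metadata (clip id, actor id, emotion category) and optional
per-frame tracking confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_N_LANDMARKS = 68


def as_shape(points, n_landmarks: int | None = None) -> np.ndarray:
    """Validate and return a landmark configuration as an ``(N, 2)`` float array.

    Raises ``ValueError`` on wrong dimensionality, non-finite coordinates or a
    landmark-count mismatch.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"a face shape must be (N, 2), got {arr.shape}")
    if n_landmarks is not None and arr.shape[0] != n_landmarks:
        raise ValueError(
            f"expected {n_landmarks} landmarks, got {arr.shape[0]}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("face shape contains non-finite coordinates")
    return arr


@dataclass
class ClipTrack:
    """Ordered landmark frames of one video clip.

    Attributes
    ----------
    clip_id, actor_id, emotion : str
        Clip metadata; ``actor_id``/``emotion`` may be empty when unknown.
    frames : ndarray of shape (T, N, 2)
        Landmark coordinates per frame; frame indexing is 0-based internally.
    confidence : ndarray of shape (T,), optional
        Per-frame tracker confidence in [0, 1] when the source provides it.
    source_frame_index : ndarray of shape (T,), optional
        Frame indices as they appeared in the source file.
    """

    clip_id: str
    frames: np.ndarray
    actor_id: str = ""
    emotion: str = ""
    confidence: np.ndarray | None = None
    source_frame_index: np.ndarray | None = None
    low_confidence_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 2:
            raise ValueError(
                f"frames must be (T, N, 2), got {self.frames.shape}"
            )
        if self.n_frames < 1:
            raise ValueError("a clip track needs at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError(f"clip {self.clip_id!r}: non-finite coordinates")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (self.n_frames,):
                raise ValueError("confidence must have one value per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.frames.shape[1]

    def with_frames(self, frames: np.ndarray) -> "ClipTrack":
        """Copy of this track with the coordinate array replaced."""
        return replace(self, frames=np.asarray(frames, dtype=float))
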