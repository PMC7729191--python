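"""Generalized Procrustes Analysis for 2-D landmark configurations.

All frames of all clips of a study are pooled into one superimposition so
that baselines taken from different clips live in the same coordinate frame.
Each configuration is translated to a zero centroid and scaled to unit
centroid size; with rotation enabled, each is then rotated to best match an
iteratively refined consensus.  Reflections are forbidden by default because
faces have handedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .types import ClipTrack


@dataclass
class NormalizationConfig:
    """Settings for the superimposition.

    ``tolerance`` is the relative consensus change (Procrustes RMSD of the new
    consensus against the previous one) below which iteration stops.
    """

    include_rotation: bool = True
    allow_reflection: bool = False
    tolerance: float = 1e-8
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class AlignedStudy:
    """Result of a pooled GPA run."""

    aligned: np.ndarray          # (M, N, 2), dimensionless
    consensus: np.ndarray        # (N, 2)
    n_iterations: int
    residual: float              # mean squared Procrustes distance to consensus
    converged: bool


def centroid_size(shape: np.ndarray) -> float:
    """Root sum of squared centered coordinates (the centroid size)."""
    shape = np.asarray(shape, dtype=float)
    centered = shape - shape.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def center_scale(shape: np.ndarray) -> np.ndarray:
    """Translate the centroid to the origin and scale centroid size to 1."""
    shape = np.asarray(shape, dtype=float)
    if shape.shape[0] < 2:
        raise ValueError("need at least 2 landmarks")
    centered = shape - shape.mean(axis=0)
    size = np.sqrt(np.sum(centered**2))
    if size == 0:
        raise ValueError("degenerate shape: all landmarks coincide")
    return centered / size


def _center_scale_batch(shapes: np.ndarray) -> np.ndarray:
    centered = shapes - shapes.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(centered**2, axis=(1, 2)))
    if np.any(sizes == 0):
        raise ValueError("degenerate shape: all landmarks coincide")
    return centered / sizes[:, None, None]


def _rotation_angles(shapes: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation angle of each shape onto the reference (batch).

    For centered 2-D configurations the least-squares rotation has the closed
    form  theta = atan2(sum(x y' - y x'), sum(x x' + y y')).
    """
    num = np.einsum("km,m->k", shapes[:, :, 0], reference[:, 1]) - np.einsum(
        "km,m->k", shapes[:, :, 1], reference[:, 0]
    )
    den = np.einsum("kmi,mi->k", shapes, reference)
    return np.arctan2(num, den)


def _rotate_batch(shapes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles), np.sin(angles)
    x, y = shapes[:, :, 0], shapes[:, :, 1]
    out = np.empty_like(shapes)
    out[:, :, 0] = c[:, None] * x - s[:, None] * y
    out[:, :, 1] = s[:, None] * x + c[:, None] * y
    return out


def optimal_rotation(
    shape: np.ndarray,
    reference: np.ndarray,
    allow_reflection: bool = False,
) -> np.ndarray:
    """Rotate ``shape`` to minimize squared distance to ``reference``.

    Both inputs must be centered and scaled configurations with the same
    landmark count.  With ``allow_reflection`` the mirrored shape is also
    considered and the better of the two fits returned; by default the
    transform is a proper rotation (determinant +1).
    """
    shape = np.asarray(shape, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if shape.shape != reference.shape:
        raise ValueError(
            f"landmark count mismatch: {shape.shape} vs {reference.shape}"
        )
    candidates = [shape]
    if allow_reflection:
        candidates.append(shape * np.array([1.0, -1.0]))
    best, best_res = None, np.inf
    for cand in candidates:
        ang = _rotation_angles(cand[None], reference)[0]
        rot = _rotate_batch(cand[None], np.array([ang]))[0]
        res = float(np.sum((rot - reference) ** 2))
        if res < best_res:
            best, best_res = rot, res
    return best


def _canonicalize(consensus: np.ndarray) -> np.ndarray:
    """Rotate the consensus so its principal axis lies along +x.

    The sign ambiguity of the principal axis is broken by requiring the first
    landmark to have a non-positive x coordinate (arbitrary but deterministic).
    """
    cov = consensus.T @ consensus
    _, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    angle = -np.arctan2(axis[1], axis[0])
    c, s = np.cos(angle), np.sin(angle)
    rot = consensus @ np.array([[c, s], [-s, c]])
    if rot[0, 0] > 0:
        rot = -rot
    return rot


def procrustes_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Rotation-invariant RMSD between two centered/scaled configurations."""
    aligned = optimal_rotation(a, b)
    return float(np.sqrt(np.mean(np.sum((aligned - b) ** 2, axis=1))))


def gpa(
    shapes, config: NormalizationConfig | None = None
) -> AlignedStudy:
    """Generalized Procrustes superimposition of a set of configurations.

    Iteratively: center/scale all shapes, rotate each onto the current
    consensus, recompute the consensus as the mean shape (re-standardized),
    until the consensus changes by less than ``config.tolerance`` in
    Procrustes RMSD or ``config.max_iterations`` is reached.  The final
    consensus is canonicalized (principal axis along +x) so the result does
    not depend on the orientation of the inputs.
    """
    config = config or NormalizationConfig()
    arr = np.asarray(shapes, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("gpa needs at least two (N, 2) shapes")
    aligned = _center_scale_batch(arr)

    if not config.include_rotation:
        consensus = _canonicalize(center_scale(aligned.mean(axis=0)))
        resid = float(np.mean(np.sum((aligned - consensus) ** 2, axis=(1, 2))))
        return AlignedStudy(aligned, consensus, 0, resid, True)

    consensus = aligned[0].copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):
        angles = _rotation_angles(aligned, consensus)
        aligned = _rotate_batch(aligned, angles)
        new_consensus = center_scale(aligned.mean(axis=0))
        change = procrustes_rmsd(new_consensus, consensus)
        consensus = new_consensus
        if change < config.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {config.max_iterations} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    consensus = _canonicalize(consensus)
    angles = _rotation_angles(aligned, consensus)
    aligned = _rotate_batch(aligned, angles)
    resid = float(np.mean(np.sum((aligned - consensus) ** 2, axis=(1, 2))))
    return AlignedStudy(aligned, consensus, n_iter, resid, converged)


class ProcrustesAligner(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping the pooled GPA.

    ``fit`` learns the consensus from a stack of shapes ``(M, N, 2)``;
    ``transform`` center/scales and rotates shapes onto that consensus, so new
    frames can be brought into the fitted coordinate frame.

    Attributes
    ----------
    consensus_ : ndarray (N, 2)
    n_iterations_ : int
    residual_ : float
    converged_ : bool
    """

    def __init__(
        self,
        include_rotation: bool = True,
        allow_reflection: bool = False,
        tolerance: float = 1e-8,
        max_iterations: int = 100,
    ):
        self.include_rotation = include_rotation
        self.allow_reflection = allow_reflection
        self.tolerance = tolerance
        self.max_iterations = max_iterations

    def _config(self) -> NormalizationConfig:
        return NormalizationConfig(
            include_rotation=self.include_rotation,
            allow_reflection=self.allow_reflection,
            tolerance=self.tolerance,
            max_iterations=self.max_iterations,
        )

    def fit(self, X, y=None):
        result = gpa(X, self._config())
        self.consensus_ = result.consensus
        self.n_iterations_ = result.n_iterations
        self.residual_ = result.residual
        self.converged_ = result.converged
        return self

    def transform(self, X):
        if not hasattr(self, "consensus_"):
            raise ValueError("ProcrustesAligner is not fitted")
        arr = _center_scale_batch(np.asarray(X, dtype=float))
        if not self.include_rotation:
            return arr
        angles = _rotation_angles(arr, self.consensus_)
        return _rotate_batch(arr, angles)


def align_study(
    tracks: list[ClipTrack], config: NormalizationConfig | None = None
) -> tuple[list[ClipTrack], AlignedStudy]:
    """Pool all frames of all clips, run GPA, and return re-assembled tracks.

    Every frame of every clip enters one superimposition, so distances between
    frames of different clips (and baselines built from them) are commensurable.
    """
    if not tracks:
        raise ValueError("no tracks to align")
    n = tracks[0].n_landmarks
    for t in tracks:
        if t.n_landmarks != n:
            raise ValueError(
                f"clip {t.clip_id!r} has {t.n_landmarks} landmarks, expected {n}"
            )
    pooled = np.concatenate([t.frames for t in tracks], axis=0)
    result = gpa(pooled, config)
    out: list[ClipTrack] = []
    start = 0
    for t in tracks:
        stop = start + t.n_frames
        out.append(t.with_frames(result.aligned[start:stop]))
        start = stop
    return out, result
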