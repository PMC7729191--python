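"""Synthetic landmark clips and rater panels with the assumed data structure.

The generator emulates short acted-expression videos: a 68-landmark face
starts neutral, moves along a fixed displacement field with a raised-cosine
amplitude envelope (neutral -> peak -> neutral) and returns to rest.  The
displacement field has unit root-mean-square magnitude and is orthogonal to
the similarity transforms of the template, so the clip's peak amplitude ``A``
*is* the peak RMSD from the first frame: with no noise and no nuisance
transforms the distance-to-neutral series equals ``A * g(f)`` exactly.

Rater panels mimic the study design: a large neurotypical (NT) panel whose
members each rate only a handful of clips, a small ASD panel rating 14 clips
each, and an optional high-autistic-traits (HAT) replication panel.  Arousal
is generated from the linear rating model on the z-scored kinematic features
with a group intercept offset, rounded to the 1..101 visual-analog scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import FEATURE_COLUMNS
from .kinematics import feature_table
from .procrustes import NormalizationConfig, align_study, center_scale
from .types import ClipTrack

RATING_LO, RATING_HI = 1, 101


# --------------------------------------------------------------------------
# template face and displacement field

def _ellipse(cx, cy, rx, ry, n, start=0.0):
    t = start + np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def make_template_face(seed: int = 0, jitter: float = 0.01) -> np.ndarray:
    """A deterministic face-like 68-landmark template (centroid 0, size 1).

    Landmarks follow the usual 2-D layout: jaw 0-16, brows 17-26, nose 27-35,
    eyes 36-47, outer lip 48-59, inner lip 60-67.  A small seeded jitter makes
    different seeds produce distinct but equally valid faces.
    """
    pts = np.empty((68, 2))
    t = np.linspace(-1.0, 1.0, 17)
    # jaw: parabola-shaped arc, chin at the bottom
    pts[0:17, 0] = 0.95 * t
    pts[0:17, 1] = -0.15 - 0.8 * (1 - t**2)
    xb = np.linspace(0.15, 0.7, 5)
    arch = 0.06 * np.sin(np.linspace(0, np.pi, 5))
    pts[17:22] = np.column_stack([-xb[::-1], 0.45 + arch[::-1]])
    pts[22:27] = np.column_stack([xb, 0.45 + arch])
    pts[27:31] = np.column_stack([np.zeros(4), np.linspace(0.35, 0.0, 4)])
    xn = np.linspace(-0.15, 0.15, 5)
    pts[31:36] = np.column_stack([xn, -0.1 + 0.03 * (1 - (xn / 0.15) ** 2)])
    pts[36:42] = _ellipse(-0.4, 0.3, 0.13, 0.055, 6)
    pts[42:48] = _ellipse(0.4, 0.3, 0.13, 0.055, 6)
    pts[48:60] = _ellipse(0.0, -0.5, 0.3, 0.13, 12, start=np.pi)
    pts[60:68] = _ellipse(0.0, -0.5, 0.19, 0.06, 8, start=np.pi)
    rng = np.random.default_rng(seed)
    pts = pts + rng.normal(0.0, jitter, pts.shape)
    return center_scale(pts)


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity-transform tangent space."""
    n = template.shape[0]
    tx = np.zeros((n, 2)); tx[:, 0] = 1.0
    ty = np.zeros((n, 2)); ty[:, 1] = 1.0
    scale = template.copy()
    rot = np.column_stack([-template[:, 1], template[:, 0]])
    basis = []
    for v in (tx, ty, scale, rot):
        w = v.ravel().astype(float)
        for b in basis:
            w = w - (w @ b) * b
        norm = np.linalg.norm(w)
        if norm > 1e-12:
            basis.append(w / norm)
    return np.array(basis)


def make_displacement_field(
    template: np.ndarray, seed: int, smoothness: float = 0.3
) -> np.ndarray:
    """Smooth random per-landmark displacement directions with unit RMS.

    Nearby landmarks move coherently (Gaussian spatial kernel).  The field is
    projected orthogonal to translations, scaling and rotation of the
    template so expression displacement is not absorbed by the Procrustes
    normalization, then scaled so sqrt(mean |field_p|^2) = 1, making the
    amplitude parameter directly interpretable as peak RMSD.
    """
    rng = np.random.default_rng(seed)
    n = template.shape[0]
    d2 = np.sum(
        (template[:, None, :] - template[None, :, :]) ** 2, axis=2
    )
    kernel = np.exp(-d2 / (2 * smoothness**2))
    raw = kernel @ rng.normal(size=(n, 2))
    flat = raw.ravel()
    for b in _similarity_basis(template):
        flat = flat - (flat @ b) * b
    field = flat.reshape(n, 2)
    rms = np.sqrt(np.mean(np.sum(field**2, axis=1)))
    if rms == 0:
        raise ValueError("degenerate displacement field")
    return field / rms


def raised_cosine_envelope(n_frames: int) -> np.ndarray:
    """g(f) = (1 - cos(2 pi f / (T-1))) / 2: zero at both ends, peak mid-clip."""
    if n_frames < 2:
        raise ValueError("envelope needs at least 2 frames")
    f = np.arange(n_frames)
    return (1 - np.cos(2 * np.pi * f / (n_frames - 1))) / 2


# --------------------------------------------------------------------------
# single-clip generation

@dataclass
class ExpressionParams:
    """Parameters of one synthetic expression clip.

    ``amplitude`` is the peak RMSD from the neutral first frame in normalized
    (consensus) units; ``n_frames`` the clip length in frames.  Nuisance
    standard deviations describe per-frame camera/tracking jitter: translation
    in coordinate units, scale on the log scale, rotation in radians.
    ``noise_sd`` is i.i.d. per-coordinate tracking noise.
    """

    amplitude: float
    n_frames: int = 100
    noise_sd: float = 0.0
    translation_sd: float = 0.0
    scale_sd: float = 0.0
    rotation_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames")


def make_expression_clip(
    template: np.ndarray,
    params: ExpressionParams,
    seed: int,
    clip_id: str = "clip",
    actor_id: str = "",
    emotion: str = "",
    field: np.ndarray | None = None,
) -> ClipTrack:
    """One neutral -> peak -> neutral clip along a displacement field."""
    rng = np.random.default_rng(seed)
    if field is None:
        field = make_displacement_field(template, rng.integers(2**31))
    g = raised_cosine_envelope(params.n_frames)
    frames = template[None] + params.amplitude * g[:, None, None] * field[None]
    if params.noise_sd > 0:
        frames = frames + rng.normal(0, params.noise_sd, frames.shape)
    if params.rotation_sd or params.scale_sd or params.translation_sd:
        ang = rng.normal(0, params.rotation_sd, params.n_frames)
        scl = np.exp(rng.normal(0, params.scale_sd, params.n_frames))
        trn = rng.normal(0, params.translation_sd, (params.n_frames, 1, 2))
        c, s = np.cos(ang), np.sin(ang)
        x, y = frames[:, :, 0], frames[:, :, 1]
        rot = np.empty_like(frames)
        rot[:, :, 0] = c[:, None] * x - s[:, None] * y
        rot[:, :, 1] = s[:, None] * x + c[:, None] * y
        frames = scl[:, None, None] * rot + trn
    return ClipTrack(
        clip_id=clip_id, frames=frames, actor_id=actor_id, emotion=emotion
    )


# --------------------------------------------------------------------------
# clip sets with a target distance-speed correlation

def _lognormal_log_corr(target: float, s_a: float, s_d: float) -> float:
    """Log-scale correlation of (amplitude, duration) giving a level-scale
    distance-speed correlation close to ``target``.

    With mean distance proportional to A and mean speed to A / (T-1), both
    lognormal, the level-scale Pearson correlation has a closed form in the
    log-scale correlation rho, inverted numerically.
    """
    if not -1 < target < 1:
        raise ValueError("target correlation must be in (-1, 1)")

    def level_corr(rho: float) -> float:
        cov = s_a**2 - rho * s_a * s_d
        var_w = s_a**2 + s_d**2 - 2 * rho * s_a * s_d
        if var_w <= 0:
            return 1.0
        return (np.exp(cov) - 1) / np.sqrt(
            (np.exp(s_a**2) - 1) * (np.exp(var_w) - 1)
        )

    lo, hi = -0.999, 0.999
    f_lo, f_hi = level_corr(lo) - target, level_corr(hi) - target
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target correlation {target} not attainable with "
            f"amplitude/duration spreads ({s_a}, {s_d})"
        )
    return float(brentq(lambda r: level_corr(r) - target, lo, hi, xtol=1e-10))


def envelope_features(amplitude: float, n_frames: int) -> dict:
    """Closed-form (noise-free, nuisance-free) kinematic measures of a clip.

    The distance-to-neutral series is A*g(f); speed is A*|dg|; acceleration is
    A*|d2g|/2.  The distance to the actor mean face is not envelope-determined
    (it depends on the actor's other clips) and is reported as the distance
    to the clip's own time-mean configuration.
    """
    g = raised_cosine_envelope(n_frames)
    dist = amplitude * g
    speed = amplitude * np.abs(np.diff(g))
    accel = amplitude * np.abs(np.diff(g, 2)) / 2
    dist_mean = amplitude * np.abs(g - g.mean())
    return {
        "dist_neutral_mean": float(dist.mean()),
        "dist_neutral_max": float(dist.max()),
        "dist_mean_face_mean": float(dist_mean.mean()),
        "dist_mean_face_max": float(dist_mean.max()),
        "speed_mean": float(speed.mean()),
        "speed_max": float(speed.max()),
        "accel_mean": float(accel.mean()),
        "accel_max": float(accel.max()),
    }


@dataclass
class StudyConfig:
    """Full configuration of a synthetic two-group rating study.

    Amplitudes and clip durations are bivariate lognormal; their log-scale
    correlation is solved so the distance and speed measures correlate at
    ``target_feature_correlation`` (the strength the rating models have to
    cope with).  Rating noise decomposes into a per-clip effect shared by all
    raters (unmodelled clip-level appeal) and independent per-rating noise;
    with the defaults the within-group models see residual scatter of roughly
    20 rating points and the between-group difference roughly 12.
    """

    n_clips: int = 80
    n_actors: int = 12
    n_emotions: int = 21
    amplitude_median: float = 0.02
    amplitude_sigma: float = 0.4
    duration_median: float = 100.0
    duration_sigma: float = 0.6
    target_feature_correlation: float = 0.51
    tracking_noise_sd: float = 2e-5
    translation_sd: float = 0.02
    scale_sd: float = 0.02
    rotation_sd: float = 0.02
    normalize: bool = True
    accel_denominator: int = 2
    # rating model (within-group, on z-scored features)
    nt_beta0: float = 47.60
    beta_distance: float = 5.93
    beta_speed: float = 2.53
    asd_offset: float = 4.29
    hat_offset: float = 4.64
    clip_effect_sd: float = 19.0
    rater_noise_sd: float = 20.0
    valence_mean: float = 51.0
    # panels
    nt_raters: int = 401
    nt_clips_per_rater: tuple[int, int] = (1, 6)
    asd_raters: int = 19
    asd_clips_per_rater: int = 14
    hat_raters: int = 41
    hat_clips_per_rater: int = 14
    include_hat: bool = True


@dataclass
class PanelConfig:
    """One rater panel: who rates how many clips, and the rating model."""

    group: str
    n_raters: int
    clips_per_rater: int | tuple[int, int]
    beta0: float
    beta_distance: float
    beta_speed: float
    rater_noise_sd: float = 20.0
    valence_mean: float = 51.0


@dataclass
class SyntheticStudy:
    """A generated study: tracks, ground truth, features and ratings."""

    tracks: list[ClipTrack]
    true_params: pd.DataFrame          # amplitude, n_frames per clip
    true_features: pd.DataFrame        # closed-form envelope measures
    realized_correlation: float        # distance-speed r among true features
    features: pd.DataFrame | None = None    # measured (pipeline) features
    ratings: pd.DataFrame | None = None
    clip_effects: pd.Series | None = None
    seed: int | None = None
    config: StudyConfig | None = None


def generate_clip_set(
    n_clips: int = 80,
    config: StudyConfig | None = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate landmark tracks for a set of clips.

    Per-clip amplitude and duration are drawn jointly so the correlation of
    the mean-distance and mean-speed measures approximates the configured
    target; the realized correlation (on the closed-form measures) is
    reported on the returned study.
    """
    config = config or StudyConfig()
    if n_clips < 3:
        raise ValueError("need at least 3 clips")
    rng = np.random.default_rng(seed)
    rho = _lognormal_log_corr(
        config.target_feature_correlation,
        config.amplitude_sigma,
        config.duration_sigma,
    )
    cov = np.array(
        [
            [config.amplitude_sigma**2,
             rho * config.amplitude_sigma * config.duration_sigma],
            [rho * config.amplitude_sigma * config.duration_sigma,
             config.duration_sigma**2],
        ]
    )
    mean = np.log([config.amplitude_median, config.duration_median - 1])
    draws = rng.multivariate_normal(mean, cov, size=n_clips)
    amplitudes = np.exp(draws[:, 0])
    durations = np.clip(np.round(np.exp(draws[:, 1])).astype(int) + 1, 10, 500)

    actor_ids = [f"a{(i % config.n_actors):02d}" for i in range(n_clips)]
    emotions = [f"emotion{(i % config.n_emotions):02d}" for i in range(n_clips)]
    templates = {
        a: make_template_face(seed=int(rng.integers(2**31)))
        for a in sorted(set(actor_ids))
    }
    tracks, truth_rows, feat_rows = [], [], []
    for i in range(n_clips):
        clip_id = f"c{i:03d}"
        template = templates[actor_ids[i]]
        params = ExpressionParams(
            amplitude=float(amplitudes[i]),
            n_frames=int(durations[i]),
            noise_sd=config.tracking_noise_sd,
            translation_sd=config.translation_sd,
            scale_sd=config.scale_sd,
            rotation_sd=config.rotation_sd,
        )
        tracks.append(
            make_expression_clip(
                template,
                params,
                seed=int(rng.integers(2**31)),
                clip_id=clip_id,
                actor_id=actor_ids[i],
                emotion=emotions[i],
            )
        )
        truth_rows.append(
            {
                "clip_id": clip_id,
                "amplitude": params.amplitude,
                "n_frames": params.n_frames,
                "actor_id": actor_ids[i],
                "emotion": emotions[i],
            }
        )
        feat_rows.append(
            {"clip_id": clip_id, **envelope_features(params.amplitude, params.n_frames)}
        )
    true_params = pd.DataFrame(truth_rows).set_index("clip_id")
    true_features = pd.DataFrame(feat_rows).set_index("clip_id")[FEATURE_COLUMNS]
    realized = float(
        np.corrcoef(
            true_features["dist_neutral_mean"], true_features["speed_mean"]
        )[0, 1]
    )
    return SyntheticStudy(
        tracks=tracks,
        true_params=true_params,
        true_features=true_features,
        realized_correlation=realized,
        seed=seed,
        config=config,
    )


def generate_ratings(
    features: pd.DataFrame,
    panel: PanelConfig,
    seed: int = 0,
    clip_effects: pd.Series | None = None,
    valence_effects: pd.Series | None = None,
) -> pd.DataFrame:
    """Rating records for one panel under random clip assignment.

    Each rater receives ``clips_per_rater`` clips drawn uniformly without
    replacement (missing completely at random).  Arousal follows the linear
    model on the z-scored distance/speed features plus the shared clip effect
    and rater noise; valence is independent of the kinematic features.
    Ratings are rounded and truncated to the 1..101 scale.
    """
    rng = np.random.default_rng(seed)
    clips = list(features.index)
    n_clips = len(clips)
    if isinstance(panel.clips_per_rater, tuple):
        lo, hi = panel.clips_per_rater
        counts = rng.integers(lo, hi + 1, size=panel.n_raters)
    else:
        counts = np.full(panel.n_raters, int(panel.clips_per_rater))
    if counts.max() > n_clips:
        raise ValueError("clips_per_rater exceeds the number of clips")

    x = features[["dist_neutral_mean", "speed_mean"]].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        z = np.zeros_like(x)
    else:
        z = (x - x.mean(axis=0)) / sd
    signal = (
        panel.beta0
        + panel.beta_distance * z[:, 0]
        + panel.beta_speed * z[:, 1]
    )
    if clip_effects is not None:
        signal = signal + clip_effects.reindex(clips).to_numpy()
    vsignal = np.full(n_clips, panel.valence_mean)
    if valence_effects is not None:
        vsignal = vsignal + valence_effects.reindex(clips).to_numpy()

    rows = []
    for r in range(panel.n_raters):
        chosen = rng.choice(n_clips, size=counts[r], replace=False)
        noise = rng.normal(0, panel.rater_noise_sd, size=counts[r])
        vnoise = rng.normal(0, panel.rater_noise_sd, size=counts[r])
        arousal = np.clip(
            np.round(signal[chosen] + noise), RATING_LO, RATING_HI
        ).astype(int)
        valence = np.clip(
            np.round(vsignal[chosen] + vnoise), RATING_LO, RATING_HI
        ).astype(int)
        for j, c in enumerate(chosen):
            rows.append(
                {
                    "rater_id": f"{panel.group.lower()}_r{r:04d}",
                    "group": panel.group,
                    "clip_id": clips[c],
                    "arousal": int(arousal[j]),
                    "valence": int(valence[j]),
                }
            )
    return pd.DataFrame(rows)


def make_study(
    config: StudyConfig | None = None, seed: int = 0
) -> SyntheticStudy:
    """Clips, measured features and NT/ASD(/HAT) rating panels, end to end.

    The ASD (and HAT) panels share the NT slopes but have their intercept
    lowered by the configured offsets.  Ratings are generated from the
    *measured* features (post-normalization when ``config.normalize``), so the
    generating coefficients are the exact truth for the fitted models.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    study = generate_clip_set(
        config.n_clips, config, seed=int(rng.integers(2**31))
    )
    tracks = study.tracks
    if config.normalize:
        aligned, _ = align_study(tracks, NormalizationConfig())
    else:
        aligned = tracks
    features = feature_table(aligned, config.accel_denominator)
    clip_effects = pd.Series(
        rng.normal(0, config.clip_effect_sd, config.n_clips),
        index=features.index,
    )
    valence_effects = pd.Series(
        rng.normal(0, config.clip_effect_sd, config.n_clips),
        index=features.index,
    )
    panels = [
        PanelConfig(
            "NT", config.nt_raters, config.nt_clips_per_rater,
            config.nt_beta0, config.beta_distance, config.beta_speed,
            config.rater_noise_sd, config.valence_mean,
        ),
        PanelConfig(
            "ASD", config.asd_raters, config.asd_clips_per_rater,
            config.nt_beta0 - config.asd_offset, config.beta_distance,
            config.beta_speed, config.rater_noise_sd, config.valence_mean,
        ),
    ]
    if config.include_hat:
        panels.append(
            PanelConfig(
                "HAT", config.hat_raters, config.hat_clips_per_rater,
                config.nt_beta0 - config.hat_offset, config.beta_distance,
                config.beta_speed, config.rater_noise_sd, config.valence_mean,
            )
        )
    ratings = pd.concat(
        [
            generate_ratings(
                features, p, seed=int(rng.integers(2**31)),
                clip_effects=clip_effects, valence_effects=valence_effects,
            )
            for p in panels
        ],
        ignore_index=True,
    )
    return SyntheticStudy(
        tracks=tracks,
        true_params=study.true_params,
        true_features=study.true_features,
        realized_correlation=study.realized_correlation,
        features=features,
        ratings=ratings,
        clip_effects=clip_effects,
        seed=seed,
        config=config,
    )
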