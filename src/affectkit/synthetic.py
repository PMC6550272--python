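"""Seeded synthetic-data generators.

No deposited study data exist, so everything downstream is exercised on
synthetic inputs with controllable structure:

* labeled "face" data, either as direct feature vectors with per-emotion
  class means and additive per-user offsets, or as rendered cartoon faces
  whose mouth curvature / eye aperture / brow angle carry the class signal
  through the real image → HOG pipeline;
* session frame streams at a fixed frame rate against a wall-clock schedule;
* paired intake/conclusion cohort tables (65 ordinal questionnaire items,
  total and subscale T-scores, emotion-guessing-game scores, usage
  covariates) with configurable mean change and pre/post correlation.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import fsolve
from scipy.stats import norm

from .classifier import LabeledDataset
from .features import FaceBox, FaceFrame
from .labels import EMOTIONS

__all__ = [
    "FaceGenParams",
    "GeneratedFaces",
    "generate_face_dataset",
    "generate_session_stream",
    "CohortGenParams",
    "generate_cohort",
    "save_cohort",
    "SRS2_SUBSCALES",
]

# ---------------------------------------------------------------------------
# (a) face / feature generator


@dataclass(frozen=True)
class FaceGenParams:
    """Per-emotion, per-user face/feature distribution parameters.

    In feature mode each frame's feature vector is drawn as
    ``class_separation · mu_e + offset_u + noise`` with fixed seeded unit
    prototypes mu_e, user offsets ~ N(0, user_offset_sd² I) and i.i.d.
    N(0, noise_sd²) noise. In render mode the emotion instead controls the
    geometry of a drawn cartoon face (mouth curvature, mouth opening, eye
    aperture, brow angle) so the image → HOG pipeline carries the signal;
    user offsets and noise perturb the geometry and pixels.
    """

    n_users: int = 5
    frames_per_user_per_emotion: int = 25
    class_separation: float = 1.0
    user_offset_sd: float = 0.3
    noise_sd: float = 0.3
    render: bool = False
    image_size: int = 64
    n_features: int = 32
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        if min(self.class_separation, self.user_offset_sd, self.noise_sd) < 0:
            raise ValueError("scales must be >= 0")


@dataclass
class GeneratedFaces:
    """Output of :func:`generate_face_dataset`."""

    labels: list[str]
    user_ids: list[str]
    features: np.ndarray | None = None  # feature mode
    frames: list[FaceFrame] | None = None  # render mode
    class_means: dict | None = None  # feature mode: emotion -> mean vector
    user_offsets: dict | None = None

    def as_dataset(self) -> LabeledDataset:
        if self.features is None:
            raise ValueError("render-mode output has frames, not features")
        return LabeledDataset(self.features, self.labels, user_ids=list(self.user_ids))


# geometry lookup: (mouth_curve, mouth_open, mouth_tilt, eye_aperture, brow_angle)
_EMOTION_GEOMETRY: dict[str, tuple[float, float, float, float, float]] = {
    "happy": (0.9, 0.0, 0.0, 0.5, 0.0),
    "sad": (-0.8, 0.0, 0.0, 0.45, 0.35),
    "angry": (-0.5, 0.0, 0.0, 0.3, -0.45),
    "scared": (-0.1, 0.5, 0.0, 0.85, 0.25),
    "surprised": (0.0, 0.9, 0.0, 1.0, 0.45),
    "neutral": (0.0, 0.0, 0.0, 0.5, 0.0),
    "disgust": (-0.6, 0.15, 0.0, 0.25, -0.2),
    "contempt": (0.1, 0.0, 0.5, 0.4, -0.1),
}


def _render_face(size: int, geom: np.ndarray) -> np.ndarray:
    """Draw a cartoon face (dark strokes on light ground) from a geometry
    vector (mouth_curve, mouth_open, mouth_tilt, eye_aperture, brow_angle).
    Distance-field strokes keep the image smooth so gradients are informative.
    """
    curve, mouth_open, tilt, aperture, brow = geom
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size
    img = np.ones((size, size))

    def stroke(px: np.ndarray, py: np.ndarray, width: float, strength: float = 0.9) -> None:
        d2 = np.min(
            (xx[..., None] - px[None, None, :]) ** 2 + (yy[..., None] - py[None, None, :]) ** 2,
            axis=-1,
        )
        np.minimum(img, 1.0 - strength * np.exp(-d2 / (2 * width**2)), out=img)

    t = np.linspace(0, 2 * np.pi, 80)
    stroke(0.5 + 0.38 * np.cos(t), 0.5 + 0.45 * np.sin(t), 0.012)  # head outline

    for side in (-1.0, 1.0):  # eyes: filled ellipses, height = aperture
        cx = 0.5 + side * 0.16
        ry = 0.015 + 0.05 * aperture
        u = np.linspace(0, 2 * np.pi, 60)
        for r in np.linspace(0.25, 1.0, 4):
            stroke(cx + 0.07 * r * np.cos(u), 0.42 + ry * r * np.sin(u), 0.012)
        # brow: line rotated by brow_angle (inner end moves with the sign)
        bx = np.linspace(cx - 0.08, cx + 0.08, 25)
        slope = -side * brow * 0.5
        stroke(bx, 0.30 + slope * (bx - cx), 0.012)

    mx = np.linspace(0.32, 0.68, 60)
    u = 2 * (mx - 0.5) / 0.36
    my = 0.72 - 0.10 * curve * (1 - u**2) + 0.08 * tilt * u
    stroke(mx, my, 0.014)
    if mouth_open > 0:
        v = np.linspace(0, 2 * np.pi, 60)
        for r in np.linspace(0.3, 1.0, 3):
            stroke(0.5 + 0.09 * r * np.cos(v), 0.74 + (0.02 + 0.07 * mouth_open) * r * np.sin(v), 0.012)
    return np.clip(img, 0.0, 1.0)


def generate_face_dataset(params: FaceGenParams) -> GeneratedFaces:
    """Balanced labeled faces/features for ``n_users`` users x 8 emotions."""
    rng = np.random.default_rng(params.rng_seed)
    labels: list[str] = []
    user_ids: list[str] = []

    if not params.render:
        d = params.n_features
        protos = rng.standard_normal((len(EMOTIONS), d))
        protos /= np.linalg.norm(protos, axis=1, keepdims=True)
        class_means = {e: params.class_separation * protos[i] for i, e in enumerate(EMOTIONS)}
        offsets = {
            f"user_{u}": rng.normal(0.0, params.user_offset_sd, size=d)
            for u in range(params.n_users)
        }
        rows = []
        for u in range(params.n_users):
            uid = f"user_{u}"
            for e in EMOTIONS:
                mean = class_means[e] + offsets[uid]
                X = mean + rng.normal(0.0, params.noise_sd, size=(params.frames_per_user_per_emotion, d))
                rows.append(X)
                labels += [e] * params.frames_per_user_per_emotion
                user_ids += [uid] * params.frames_per_user_per_emotion
        return GeneratedFaces(
            labels=labels,
            user_ids=user_ids,
            features=np.vstack(rows),
            class_means=class_means,
            user_offsets=offsets,
        )

    # render mode: geometry signal scaled by class_separation (1 = nominal)
    frames: list[FaceFrame] = []
    size = params.image_size
    geom_scale = params.class_separation
    user_geom = {
        f"user_{u}": rng.normal(0.0, 0.08 * params.user_offset_sd, size=5)
        for u in range(params.n_users)
    }
    t = 0.0
    for u in range(params.n_users):
        uid = f"user_{u}"
        for e in EMOTIONS:
            base = np.asarray(_EMOTION_GEOMETRY[e]) * geom_scale + user_geom[uid]
            for _ in range(params.frames_per_user_per_emotion):
                geom = base + rng.normal(0.0, 0.03 * params.noise_sd, size=5)
                img = _render_face(size, geom)
                img = np.clip(img + rng.normal(0.0, 0.05 * params.noise_sd, size=img.shape), 0, 1)
                margin = 0.04 * size
                box = FaceBox(margin, margin, size - 2 * margin, size - 2 * margin)
                frames.append(FaceFrame(img, t, box, e))
                labels.append(e)
                user_ids.append(uid)
                t += 1.0 / 30.0
    return GeneratedFaces(labels=labels, user_ids=user_ids, frames=frames)


# ---------------------------------------------------------------------------
# (b) session stream generator


def generate_session_stream(
    schedule,
    rng_seed: int = 0,
    fps: float = 30.0,
    include_frames: bool = True,
    mean_run_s: float = 2.0,
    p_none: float = 0.4,
    participant_id: str | None = None,
) -> list[dict]:
    """Frame streams + wall-clock session records against a schedule.

    ``schedule`` is a list of ``(date, duration_min, mode)``. Each session's
    frame count is exactly ``duration_min * 60 * fps`` (total minutes equal
    the schedule sum). Labels come in runs: alternating gaps ('none') and
    seeded emotion runs with mean length ``mean_run_s``. With
    ``include_frames=False`` only the summary records are produced (for
    usage accounting at scale).
    """
    rng = np.random.default_rng(rng_seed)
    sessions = []
    for i, (day, duration_min, mode) in enumerate(schedule):
        rec = {
            "session_id": f"{participant_id or 's'}_{i:04d}",
            "participant_id": participant_id,
            "date": str(day),
            "duration_min": float(duration_min),
            "mode": mode,
        }
        if include_frames:
            n = int(round(duration_min * 60 * fps))
            frames = []
            t = 0.0
            while len(frames) < n:
                if rng.random() < p_none:
                    label = "none"
                else:
                    label = EMOTIONS[rng.integers(len(EMOTIONS))]
                run = max(1, int(rng.exponential(mean_run_s) * fps))
                for _ in range(min(run, n - len(frames))):
                    frames.append((round(t, 6), label, 1.0 if label != "none" else 0.0))
                    t += 1.0 / fps
            rec["frames"] = frames
        sessions.append(rec)
    return sessions


# ---------------------------------------------------------------------------
# (c) paired cohort generator

SRS2_SUBSCALES = ("awareness", "cognition", "communication", "motivation", "mannerisms")

# intake mean, intake SD, conclusion SD, change at nominal total change (-7.14)
_SUBSCALE_DEFAULTS = {
    "awareness": (78.07, 11.19, 11.54, -6.86),
    "cognition": (74.86, 8.16, 10.59, -4.93),
    "communication": (78.93, 10.48, 10.31, -6.36),
    "motivation": (68.71, 9.52, 9.78, -3.92),
    "mannerisms": (83.07, 18.04, 11.74, -11.00),
}

_NOMINAL_TOTAL_CHANGE = -7.14


@dataclass(frozen=True)
class CohortGenParams:
    """Calibration of the paired intake/conclusion cohort table.

    Defaults reproduce the study conditions: n = 14, total T-score 80.07
    (SD 9.53) at intake dropping by 7.14 points, emotion-guessing scores
    28.45 (SD 11.0) rising by 9.55 with the first ``egg_missing_intake``
    participants unassessed at intake. Pre/post correlations are fixed by
    back-solving the difference-score SD implied by the reported paired F
    statistics. Subscale changes scale proportionally with
    ``srs2_mean_change`` so a null total change is a null generator
    throughout.
    """

    n_participants: int = 14
    srs2_intake_mean: float = 80.07
    srs2_intake_sd: float = 9.53
    srs2_conclusion_sd: float = 10.29
    srs2_mean_change: float = -7.14
    pre_post_correlation: float = 0.89
    egg_intake_mean: float = 28.45
    egg_intake_sd: float = 11.0
    egg_conclusion_sd: float = 2.68
    egg_mean_change: float = 9.55
    egg_correlation: float = 0.74
    egg_missing_intake: int = 3
    item_noise_sd: float = 0.8
    subscale_idio_sd: float = 0.25  # T-score points of per-timepoint subscale noise
    dropout_rate: float = 0.0
    noncompliance_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.pre_post_correlation, self.egg_correlation):
            if not (-1 < r < 1):
                raise ValueError("correlations must lie in (-1, 1)")


def _bivariate(rng, n, m1, s1, m2, s2, rho):
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return m1 + s1 * z1, m2 + s2 * z2, z1, z2


def _probit_binomial_params(mean: float, sd: float, n_items: int = 40):
    """Latent-normal (m, s) so that Binomial(n, Phi(theta)), theta~N(m, s²),
    has the requested score-scale mean and SD (Gauss–Hermite moment match)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def moments(v):
        m, log_s = v
        s = np.exp(log_s)
        p = norm.cdf(m + s * nodes)
        mu = n_items * np.sum(weights * p)
        var = n_items * np.sum(weights * p * (1 - p)) + n_items**2 * (
            np.sum(weights * p**2) - np.sum(weights * p) ** 2
        )
        return [mu - mean, np.sqrt(max(var, 1e-12)) - sd]

    m0 = norm.ppf(np.clip(mean / n_items, 1e-4, 1 - 1e-4))
    sol = fsolve(moments, [m0, 0.0], full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def generate_cohort(params: CohortGenParams | None = None) -> pd.DataFrame:
    """One row per participant: paired T-scores, subscales, 65 ordinal items
    per timepoint, emotion-guessing scores, usage covariates."""
    params = params or CohortGenParams()
    rng = np.random.default_rng(params.rng_seed)
    n = params.n_participants

    conc_mean = params.srs2_intake_mean + params.srs2_mean_change
    total_in, total_out, z_in, z_out = _bivariate(
        rng,
        n,
        params.srs2_intake_mean,
        params.srs2_intake_sd,
        conc_mean,
        params.srs2_conclusion_sd,
        params.pre_post_correlation,
    )

    df = pd.DataFrame({"participant_id": [f"p{i:02d}" for i in range(n)]})
    status = np.array(["completed"] * n, dtype=object)
    u = rng.random(n)
    status[u < params.dropout_rate] = "withdrew"
    status[(u >= params.dropout_rate) & (u < params.dropout_rate + params.noncompliance_rate)] = (
        "noncompliant"
    )
    df["status"] = status
    df["srs2_total_intake"] = total_in
    df["srs2_total_conclusion"] = total_out

    change_scale = params.srs2_mean_change / _NOMINAL_TOTAL_CHANGE
    # Subscales: intake scores load on the shared severity latent plus a
    # persistent subscale trait; *change* is driven by one participant-level
    # improvement factor (the centred total change) with scale-proportional
    # loadings — a single parent reporter moves all subscales together.
    centred_change = (total_out - total_in) - params.srs2_mean_change
    eta = rng.standard_normal((len(SRS2_SUBSCALES), n))
    for k, name in enumerate(SRS2_SUBSCALES):
        mu_in, sd_in, _sd_out, chg = _SUBSCALE_DEFAULTS[name]
        lat_in = (0.9 * z_in + 0.436 * eta[k]) / np.sqrt(0.81 + 0.19)
        intake_k = mu_in + sd_in * lat_in
        loading = sd_in / params.srs2_intake_sd
        df[f"srs2_{name}_intake"] = intake_k
        df[f"srs2_{name}_conclusion"] = (
            intake_k
            + chg * change_scale
            + loading * centred_change
            + params.subscale_idio_sd * rng.standard_normal(n)
        )

    # ordinal items via graded thresholds on a shared latent (realistic ties)
    centers = rng.uniform(-1.2, 1.2, size=65)
    spreads = rng.uniform(0.8, 1.2, size=65)
    item_cols = {}
    for t, z in (("intake", z_in), ("conclusion", z_out)):
        noise = rng.normal(0.0, params.item_noise_sd, size=(n, 65))
        latent = z[:, None] + noise
        thresholds = centers[None, :, None] + spreads[None, :, None] * np.array([-1.0, 0.0, 1.0])
        resp = 1 + (latent[:, :, None] > thresholds).sum(axis=2)
        for j in range(65):
            item_cols[f"item_{j + 1:02d}_{t}"] = resp[:, j].astype(int)
    df = pd.concat([df, pd.DataFrame(item_cols)], axis=1)

    # emotion-guessing scores: probit-latent binomial, paired on the latent
    m1, s1 = _probit_binomial_params(params.egg_intake_mean, params.egg_intake_sd)
    m2, s2 = _probit_binomial_params(
        params.egg_intake_mean + params.egg_mean_change, params.egg_conclusion_sd
    )
    th_in, th_out, _, _ = _bivariate(rng, n, m1, s1, m2, s2, params.egg_correlation)
    egg_in = rng.binomial(40, norm.cdf(th_in)).astype(float)
    egg_out = rng.binomial(40, norm.cdf(th_out)).astype(float)
    if params.egg_missing_intake > 0:
        egg_in[: params.egg_missing_intake] = np.nan
    df["egg_intake"] = egg_in
    df["egg_conclusion"] = egg_out

    df["abiq"] = np.clip(rng.normal(95.14, 22.36, size=n), 40, 160).round(0)
    df["n_therapies"] = rng.poisson(2.0, size=n)
    df["days_at_home"] = np.clip(rng.normal(72, 35, size=n), 27, 136).round(0)
    df["usage_min"] = np.clip(rng.normal(409, 266.8, size=n), 60, 1010).round(0)
    return df


def save_cohort(df: pd.DataFrame, path, params: CohortGenParams | None = None) -> None:
    """Write cohort.csv; parameters echoed to a YAML sidecar if given."""
    path = Path(path)
    df.to_csv(path, index=False)
    if params is not None:
        import yaml

        sidecar = path.with_suffix(".params.yaml")
        sidecar.write_text(yaml.safe_dump(asdict(params)))


def default_study_schedule(
    n_weeks: int = 4,
    sessions_per_week: int = 3,
    session_min: float = 20.0,
    start: date = date(2016, 7, 4),
    mode: str = "free_play",
) -> list[tuple[date, float, str]]:
    """Protocol-shaped schedule: k sessions of m minutes in each 7-day block."""
    sched = []
    for w in range(n_weeks):
        for s in range(sessions_per_week):
            day = start + timedelta(days=7 * w + 2 * s)
            sched.append((day, session_min, mode))
    return sched
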