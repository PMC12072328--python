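"""Synthetic pediatric cohorts and noisy pose-frame rendering.

Emulates the data a photographic capture pipeline would produce: a cohort of
children with realistic age/sex/habitus structure and, per child, a
17-keypoint stick-figure "photograph" with camera-style corruption.

Cohort model
------------
Ages are drawn per stratum (1–12 months, 13–71 months, 72–155 months) with a
configurable mix, uniform within a stratum; sex is Bernoulli(0.5).  Each
child has a latent habitus percentile ~ Uniform(0.02, 0.98); height is the
chart height quantile at that percentile and weight is the chart weight
quantile at a correlated percentile (Gaussian-copula correlation ρ, default
0.7 — tall children tend to be heavy, imperfectly).  The visually assessed
habitus band is the chart classification of the sampled weight, flipped to
an adjacent band with a configurable assessor error rate.

Capture model
-------------
Keypoints are placed from body-segment proportions of stature.  The vertical
chain head→trunk→thigh→shank sums to exactly 1 so the head-to-heel pixel
span before noise equals stature × effective scale (the crown is collapsed
onto the nose landmark).  The head fraction shrinks from ~1/4 of stature at
1 month to ~1/7 at 12 years, linearly in log-age, giving the pose an
age-correlated shape signal.  Per-subject anatomical variation is modeled
as multiplicative jitter on every segment proportion (chain renormalized),
so two children of equal age and stature do not photograph identically.
Monocular scale ambiguity is modeled as log-normal jitter on pixels-per-cm;
a small rotation, a random translation and iid Gaussian landmark noise
complete the corruption.  Keypoints pushed
off the image by noise are clamped back and flagged low-confidence.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .growth_reference import (
    AGE_MAX_MONTHS,
    BodyType,
    GrowthChart,
    classify_body_type,
    percentile_height,
    percentile_weight,
)
from .pose_features import KEYPOINT_NAMES, Keypoint, PoseFrame

__all__ = [
    "AGE_STRATA",
    "DEFAULT_AGE_MIX",
    "SyntheticSubject",
    "PoseTemplate",
    "CaptureConfig",
    "sample_cohort",
    "render_pose",
    "make_dataset",
    "subjects_to_frame",
]

#: Age strata in months: infants, preschool, school-age.
AGE_STRATA = ((1, 12), (13, 71), (72, 155))

#: Stratum mix of the cohort this generator emulates (150 / 825 / 360 of 1335).
DEFAULT_AGE_MIX = (150 / 1335, 825 / 1335, 360 / 1335)

DEFAULT_RHO = 0.7
DEFAULT_ASSESSOR_ERROR_RATE = 0.2
LOW_CONFIDENCE = 0.1


@dataclass
class SyntheticSubject:
    id: str
    age_months: int
    sex: str
    latent_percentile: float
    body_type: str
    height_cm: float
    weight_kg: float


@dataclass
class PoseTemplate:
    """Body-segment lengths as proportions of stature.

    ``trunk_frac``, ``thigh_frac`` and ``shank_frac`` are proportions of the
    sub-cranial stature (1 − head fraction) and sum to 1, so the vertical
    chain always spans exactly the full stature regardless of age.
    """

    trunk_frac: float = 0.45
    thigh_frac: float = 0.28
    shank_frac: float = 0.27
    upper_arm_frac: float = 0.17   # of stature
    forearm_frac: float = 0.15
    shoulder_width_frac: float = 0.22
    hip_width_frac: float = 0.16
    head_frac_infant: float = 0.25     # at 1 month
    head_frac_child: float = 1.0 / 7.0  # at 155 months

    def __post_init__(self) -> None:
        vals = [
            self.trunk_frac, self.thigh_frac, self.shank_frac,
            self.upper_arm_frac, self.forearm_frac,
            self.shoulder_width_frac, self.hip_width_frac,
            self.head_frac_infant, self.head_frac_child,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all segment proportions must be positive")
        chain = self.trunk_frac + self.thigh_frac + self.shank_frac
        if abs(chain - 1.0) > 1e-9:
            raise ValueError("trunk + thigh + shank proportions must sum to 1")

    def head_fraction(self, age_months: float) -> float:
        """Head proportion of stature, linear in log-age from infant to child."""
        t = math.log(age_months) / math.log(AGE_MAX_MONTHS)
        t = min(max(t, 0.0), 1.0)
        return self.head_frac_infant + t * (self.head_frac_child - self.head_frac_infant)


@dataclass
class CaptureConfig:
    """Camera/noise parameters of the synthetic capture.

    Defaults emulate a tablet photographed at roughly standardized distance:
    5 px/cm nominal scale with 15% log-normal distance jitter, ±5° tilt,
    ~10 px framing translation, ~4% per-subject proportion spread and 10 px
    landmark localization error on a 768×1024 image — the error level of
    real pose detection on clothed, imperfectly positioned children.
    """

    pixels_per_cm: float = 5.0
    scale_jitter_sd: float = 0.15
    rotation_sd: float = 5.0        # degrees
    translation_sd: float = 10.0    # pixels
    landmark_noise_sd: float = 10.0  # pixels
    proportion_sd: float = 0.04     # per-subject segment-proportion spread
    image_width: int = 768
    image_height: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")
        for name in (
            "scale_jitter_sd", "rotation_sd", "translation_sd",
            "landmark_noise_sd", "proportion_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def noiseless(cls, **kw) -> "CaptureConfig":
        """All noise scales zero — capture becomes a deterministic projection."""
        kw.setdefault("scale_jitter_sd", 0.0)
        kw.setdefault("rotation_sd", 0.0)
        kw.setdefault("translation_sd", 0.0)
        kw.setdefault("landmark_noise_sd", 0.0)
        kw.setdefault("proportion_sd", 0.0)
        return cls(**kw)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

_ADJACENT = {"thin": ["normal"], "overweight": ["normal"], "normal": ["thin", "overweight"]}


def sample_cohort(
    n: int,
    chart: GrowthChart,
    age_mix: tuple[float, float, float] = DEFAULT_AGE_MIX,
    assessor_error_rate: float = DEFAULT_ASSESSOR_ERROR_RATE,
    rho: float = DEFAULT_RHO,
    seed: int = 0,
) -> list[SyntheticSubject]:
    """Draw ``n`` synthetic subjects with ages stratified per ``age_mix``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(age_mix, dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("age_mix must be three non-negative fractions summing to 1")
    if not 0.0 <= assessor_error_rate <= 1.0:
        raise ValueError("assessor_error_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, mix)
    ages = np.concatenate(
        [rng.integers(lo, hi + 1, size=c) for (lo, hi), c in zip(AGE_STRATA, counts)]
    )
    rng.shuffle(ages)

    subjects = []
    for i, age in enumerate(ages):
        sex = "male" if rng.random() < 0.5 else "female"
        p_h = rng.uniform(0.02, 0.98)
        z_h = ndtri(p_h)
        z_w = rho * z_h + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
        p_w = float(np.clip(ndtr(z_w), 0.02, 0.98))
        height = percentile_height(chart, sex, int(age), p_h)
        weight = percentile_weight(chart, sex, int(age), p_w)
        bt = classify_body_type(chart, sex, int(age), weight).value
        if rng.random() < assessor_error_rate:
            options = _ADJACENT[bt]
            bt = options[rng.integers(len(options))]
        subjects.append(
            SyntheticSubject(
                id=f"S{i:05d}",
                age_months=int(age),
                sex=sex,
                latent_percentile=p_h,
                body_type=bt,
                height_cm=height,
                weight_kg=weight,
            )
        )
    return subjects


def subjects_to_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "age_months": [s.age_months for s in subjects],
            "sex": [s.sex for s in subjects],
            "body_type": [s.body_type for s in subjects],
            "height_cm": [s.height_cm for s in subjects],
            "weight_kg": [s.weight_kg for s in subjects],
        }
    )


# ---------------------------------------------------------------------------
# Pose rendering
# ---------------------------------------------------------------------------

def _skeleton_layout(height_cm: float, age_months: float, tpl: PoseTemplate) -> np.ndarray:
    """(17, 2) keypoint positions in cm, y down, nose (crown) at origin."""
    head = tpl.head_fraction(age_months) * height_cm
    rest = height_cm - head
    trunk = tpl.trunk_frac * rest
    thigh = tpl.thigh_frac * rest
    shank = tpl.shank_frac * rest
    upper_arm = tpl.upper_arm_frac * height_cm
    forearm = tpl.forearm_frac * height_cm
    half_shoulder = tpl.shoulder_width_frac * height_cm / 2.0
    half_hip = tpl.hip_width_frac * height_cm / 2.0

    y_shoulder = head
    y_hip = head + trunk
    y_knee = y_hip + thigh
    y_ankle = y_knee + shank  # == height_cm by construction

    pos = {
        "nose": (0.0, 0.0),
        "left_eye": (-0.05 * head, 0.20 * head),
        "right_eye": (0.05 * head, 0.20 * head),
        "left_ear": (-0.12 * head, 0.30 * head),
        "right_ear": (0.12 * head, 0.30 * head),
        "left_shoulder": (-half_shoulder, y_shoulder),
        "right_shoulder": (half_shoulder, y_shoulder),
        # arms slightly abducted from the trunk
        "left_elbow": (-half_shoulder - 0.25 * upper_arm, y_shoulder + 0.97 * upper_arm),
        "right_elbow": (half_shoulder + 0.25 * upper_arm, y_shoulder + 0.97 * upper_arm),
        "left_wrist": (-half_shoulder - 0.40 * forearm, y_shoulder + 0.97 * upper_arm + 0.92 * forearm),
        "right_wrist": (half_shoulder + 0.40 * forearm, y_shoulder + 0.97 * upper_arm + 0.92 * forearm),
        "left_hip": (-half_hip, y_hip),
        "right_hip": (half_hip, y_hip),
        "left_knee": (-half_hip, y_knee),
        "right_knee": (half_hip, y_knee),
        "left_ankle": (-half_hip, y_ankle),
        "right_ankle": (half_hip, y_ankle),
    }
    return np.array([pos[name] for name in KEYPOINT_NAMES])


def _perturb_template(
    tpl: PoseTemplate, sd: float, rng: np.random.Generator
) -> PoseTemplate:
    """Individual anatomy: multiplicative log-normal jitter on each segment
    proportion, with the vertical chain renormalized to keep the head-to-heel
    span exactly equal to stature."""
    if sd == 0.0:
        return tpl
    j = lambda v: v * math.exp(rng.normal(0.0, sd))
    trunk, thigh, shank = j(tpl.trunk_frac), j(tpl.thigh_frac), j(tpl.shank_frac)
    chain = trunk + thigh + shank
    return PoseTemplate(
        trunk_frac=trunk / chain,
        thigh_frac=thigh / chain,
        shank_frac=shank / chain,
        upper_arm_frac=j(tpl.upper_arm_frac),
        forearm_frac=j(tpl.forearm_frac),
        shoulder_width_frac=j(tpl.shoulder_width_frac),
        hip_width_frac=j(tpl.hip_width_frac),
        head_frac_infant=j(tpl.head_frac_infant),
        head_frac_child=j(tpl.head_frac_child),
    )


def render_pose(
    subject: SyntheticSubject,
    template: PoseTemplate | None = None,
    cfg: CaptureConfig | None = None,
    rng: np.random.Generator | None = None,
) -> PoseFrame:
    """Project a subject's skeleton onto a synthetic image, with capture noise.

    Returns a frame in *pixel* coordinates; feed it through
    :func:`pedweight.pose_features.normalize_keypoints` downstream.
    """
    template = template or PoseTemplate()
    cfg = cfg or CaptureConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    template = _perturb_template(template, cfg.proportion_sd, rng)
    scale = cfg.pixels_per_cm * math.exp(rng.normal(0.0, cfg.scale_jitter_sd))
    pts = _skeleton_layout(subject.height_cm, subject.age_months, template) * scale

    theta = math.radians(rng.normal(0.0, cfg.rotation_sd))
    centroid = pts.mean(axis=0)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    pts = (pts - centroid) @ rot.T + centroid

    # center the figure in the image, then jitter the framing
    target = np.array([cfg.image_width / 2.0, cfg.image_height / 2.0])
    pts = pts - pts.mean(axis=0) + target + rng.normal(0.0, cfg.translation_sd, size=2)

    noisy = pts + rng.normal(0.0, cfg.landmark_noise_sd, size=pts.shape)
    clamped = np.clip(noisy, [0.0, 0.0], [cfg.image_width, cfg.image_height])
    off_image = np.any(noisy != clamped, axis=1)
    base_conf = rng.uniform(0.6, 1.0, size=len(KEYPOINT_NAMES))

    kps = {}
    for i, name in enumerate(KEYPOINT_NAMES):
        conf = LOW_CONFIDENCE if off_image[i] else float(base_conf[i])
        kps[name] = Keypoint(name, float(clamped[i, 0]), float(clamped[i, 1]), conf)
    return PoseFrame(subject.id, kps, cfg.image_width, cfg.image_height)


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------

def make_dataset(
    n: int,
    chart: GrowthChart,
    out_dir,
    template: PoseTemplate | None = None,
    cfg: CaptureConfig | None = None,
    age_mix: tuple[float, float, float] = DEFAULT_AGE_MIX,
    assessor_error_rate: float = DEFAULT_ASSESSOR_ERROR_RATE,
    rho: float = DEFAULT_RHO,
    seed: int = 0,
) -> dict:
    """Write a pose CSV + subject CSV + manifest; return the manifest dict."""
    from .pose_features import frames_to_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cfg or CaptureConfig(seed=seed)
    template = template or PoseTemplate()

    subjects = sample_cohort(
        n, chart, age_mix=age_mix, assessor_error_rate=assessor_error_rate,
        rho=rho, seed=seed,
    )
    render_rng = np.random.default_rng(seed + 1)
    frames = [render_pose(s, template, cfg, render_rng) for s in subjects]

    pose_path = out / "pose.csv"
    subj_path = out / "subjects.csv"
    frames_to_csv(frames, pose_path)
    subjects_to_frame(subjects).to_csv(subj_path, index=False)

    strata_counts = [
        sum(lo <= s.age_months <= hi for s in subjects) for lo, hi in AGE_STRATA
    ]
    digest = hashlib.sha256(pose_path.read_bytes() + subj_path.read_bytes()).hexdigest()
    manifest = {
        "n": n,
        "seed": seed,
        "age_strata": [list(s) for s in AGE_STRATA],
        "stratum_counts": strata_counts,
        "content_sha256": digest,
        "files": {"pose": pose_path.name, "subjects": subj_path.name},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
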