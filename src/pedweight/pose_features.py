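"""Pose keypoints → fixed-length feature vectors.

A pose frame is the set of 17 named 2-D body landmarks (the canonical
pose-estimation keypoint set: nose, eyes, ears, shoulders, elbows, wrists,
hips, knees, ankles) with a confidence each.  Features are the Euclidean
distances along the 16 anatomically connected skeleton edges, computed on
image-normalized coordinates, concatenated with five encoded metadata
values (sex code, scaled age, habitus one-hot) for a length-21 vector.

Distances on normalized coordinates are translation invariant; rotation
invariance holds only for square images (normalization is anisotropic when
width ≠ height).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth_reference import AGE_MAX_MONTHS, AGE_MIN_MONTHS, BodyType, Sex

__all__ = [
    "KEYPOINT_NAMES",
    "DEFAULT_EDGES",
    "FEATURE_NAMES",
    "N_FEATURES",
    "Keypoint",
    "PoseFrame",
    "SchemaError",
    "normalize_keypoints",
    "edge_distances",
    "encode_metadata",
    "build_features",
    "frames_to_csv",
    "frames_from_csv",
    "feature_table",
]

KEYPOINT_NAMES = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: Canonical skeleton connectivity for the 17 landmarks, order fixed.
DEFAULT_EDGES = (
    ("nose", "left_eye"),
    ("nose", "right_eye"),
    ("left_eye", "left_ear"),
    ("right_eye", "right_ear"),
    ("left_shoulder", "right_shoulder"),
    ("left_shoulder", "left_elbow"),
    ("left_elbow", "left_wrist"),
    ("right_shoulder", "right_elbow"),
    ("right_elbow", "right_wrist"),
    ("left_shoulder", "left_hip"),
    ("right_shoulder", "right_hip"),
    ("left_hip", "right_hip"),
    ("left_hip", "left_knee"),
    ("left_knee", "left_ankle"),
    ("right_hip", "right_knee"),
    ("right_knee", "right_ankle"),
)

META_NAMES = ("sex_code", "age_scaled", "bt_thin", "bt_normal", "bt_overweight")
FEATURE_NAMES = tuple(f"d_{a}__{b}" for a, b in DEFAULT_EDGES) + META_NAMES
N_FEATURES = len(FEATURE_NAMES)  # 16 + 5 = 21


class SchemaError(ValueError):
    """A frame or feature vector violates the fixed keypoint/feature schema."""


@dataclass(frozen=True)
class Keypoint:
    name: str
    x: float
    y: float
    confidence: float = 1.0


@dataclass
class PoseFrame:
    """One subject photo's worth of keypoints plus the image dimensions.

    Coordinates may be in pixels (as emitted by a pose detector) or already
    normalized to [0, 1]; :func:`normalize_keypoints` converts and is a
    no-op on normalized input.
    """

    subject_id: str
    keypoints: dict[str, Keypoint]
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        names = set(self.keypoints)
        if names != set(KEYPOINT_NAMES):
            missing = sorted(set(KEYPOINT_NAMES) - names)
            extra = sorted(names - set(KEYPOINT_NAMES))
            raise SchemaError(f"keypoint schema mismatch: missing={missing} extra={extra}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise SchemaError("image dimensions must be positive")

    def coords(self) -> np.ndarray:
        """(17, 2) array in canonical keypoint order."""
        return np.array(
            [[self.keypoints[n].x, self.keypoints[n].y] for n in KEYPOINT_NAMES]
        )


def _is_normalized(frame: PoseFrame) -> bool:
    c = frame.coords()
    return bool(np.all(c >= 0.0) and np.all(c <= 1.0))


def normalize_keypoints(frame: PoseFrame) -> PoseFrame:
    """Divide pixel coordinates by the image dimensions, clamping to [0, 1].

    Idempotent: a frame whose coordinates already all lie in [0, 1] is
    returned unchanged.
    """
    if _is_normalized(frame):
        return frame
    kps = {}
    for name, kp in frame.keypoints.items():
        x = min(max(kp.x / frame.image_width, 0.0), 1.0)
        y = min(max(kp.y / frame.image_height, 0.0), 1.0)
        kps[name] = replace(kp, x=x, y=y)
    return PoseFrame(frame.subject_id, kps, frame.image_width, frame.image_height)


def edge_distances(
    frame: PoseFrame, edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES
) -> np.ndarray:
    """Euclidean distance per skeleton edge, in edge-set order."""
    out = np.empty(len(edges))
    for i, (a, b) in enumerate(edges):
        try:
            ka, kb = frame.keypoints[a], frame.keypoints[b]
        except KeyError as exc:
            raise SchemaError(f"edge references absent keypoint {exc.args[0]!r}") from exc
        out[i] = np.hypot(ka.x - kb.x, ka.y - kb.y)
    return out


def encode_metadata(
    sex: Sex | str, age_months: float, body_type: BodyType | str
) -> np.ndarray:
    """[sex∈{0,1}, age/155, onehot(thin, normal, overweight)]."""
    if not AGE_MIN_MONTHS <= age_months <= AGE_MAX_MONTHS:
        raise ValueError(
            f"age {age_months} outside [{AGE_MIN_MONTHS}, {AGE_MAX_MONTHS}] months"
        )
    sex_code = {"male": 0.0, "female": 1.0}[Sex(sex).value]
    onehot = {"thin": 0, "normal": 1, "overweight": 2}[BodyType(body_type).value]
    vec = np.zeros(5)
    vec[0] = sex_code
    vec[1] = age_months / AGE_MAX_MONTHS
    vec[2 + onehot] = 1.0
    return vec


def build_features(
    frame: PoseFrame,
    sex: Sex | str,
    age_months: float,
    body_type: BodyType | str,
    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES,
) -> np.ndarray:
    """Length-21 regressor input: [16 edge distances ‖ 5 metadata values]."""
    frame = normalize_keypoints(frame)
    return np.concatenate(
        [edge_distances(frame, edges), encode_metadata(sex, age_months, body_type)]
    )


# ---------------------------------------------------------------------------
# File I/O (pose CSV schema: id, image_w, image_h, kp_{name}_{x,y,conf} × 17)
# ---------------------------------------------------------------------------

def frames_to_csv(frames: list[PoseFrame], path) -> None:
    rows = []
    for f in frames:
        row: dict[str, object] = {
            "id": f.subject_id,
            "image_w": f.image_width,
            "image_h": f.image_height,
        }
        for name in KEYPOINT_NAMES:
            kp = f.keypoints[name]
            row[f"kp_{name}_x"] = kp.x
            row[f"kp_{name}_y"] = kp.y
            row[f"kp_{name}_conf"] = kp.confidence
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def frames_from_csv(path) -> list[PoseFrame]:
    df = pd.read_csv(path)
    frames = []
    for _, row in df.iterrows():
        kps = {}
        for name in KEYPOINT_NAMES:
            try:
                kps[name] = Keypoint(
                    name,
                    float(row[f"kp_{name}_x"]),
                    float(row[f"kp_{name}_y"]),
                    float(row[f"kp_{name}_conf"]),
                )
            except KeyError as exc:
                raise SchemaError(f"pose CSV missing column {exc.args[0]!r}") from exc
        frames.append(
            PoseFrame(str(row["id"]), kps, int(row["image_w"]), int(row["image_h"]))
        )
    return frames


def feature_table(frames: list[PoseFrame], subjects: pd.DataFrame) -> pd.DataFrame:
    """Feature matrix for frames joined to subject metadata by id.

    ``subjects`` needs columns id, sex, age_months, body_type; extra columns
    (height_cm, weight_kg) pass through untouched for downstream targets.
    """
    meta = subjects.set_index(subjects["id"].astype(str))
    rows = []
    for frame in frames:
        try:
            m = meta.loc[frame.subject_id]
        except KeyError as exc:
            raise SchemaError(f"no metadata for subject {frame.subject_id!r}") from exc
        feats = build_features(frame, m["sex"], float(m["age_months"]), m["body_type"])
        row = dict(zip(FEATURE_NAMES, feats))
        row["id"] = frame.subject_id
        for col in ("height_cm", "weight_kg"):
            if col in meta.columns:
                row[col] = float(m[col])
        rows.append(row)
    cols = ["id", *FEATURE_NAMES] + [
        c for c in ("height_cm", "weight_kg") if c in meta.columns
    ]
    return pd.DataFrame(rows)[cols]
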