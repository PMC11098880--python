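"""Per-point instance labeling from detected human poses and object boxes.

Turns a fused colored point cloud plus upstream detections into a labeled
cloud (one entity id per point, -1 = background) and extracts fixed-size
per-entity / per-pair point sets for the scene-graph network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "JOINT_NAMES",
    "BONES",
    "PointCloudFrame",
    "HumanPose",
    "ObjectBox",
    "LabelParams",
    "LabeledCloud",
    "compute_instance_labels",
    "sample_entity_cloud",
    "sample_pair_cloud",
    "instrument_node_id",
]

#: 14-joint skeleton: head, neck and left/right shoulder, elbow, wrist, hip,
#: knee, ankle.
JOINT_NAMES: tuple[str, ...] = (
    "head",
    "neck",
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

#: Bone segments connecting the 14 joints (indices into JOINT_NAMES).
BONES: tuple[tuple[int, int], ...] = (
    (0, 1),  # head-neck
    (1, 2),
    (1, 3),  # neck-shoulders
    (2, 4),
    (3, 5),  # shoulder-elbow
    (4, 6),
    (5, 7),  # elbow-wrist
    (1, 8),
    (1, 9),  # neck-hips (torso)
    (8, 9),  # pelvis
    (8, 10),
    (9, 11),  # hip-knee
    (10, 12),
    (11, 13),  # knee-ankle
)

WRIST_INDICES = (6, 7)


@dataclass
class PointCloudFrame:
    """Colored 3D points with optional per-point instance labels.

    ``labels[i]`` indexes :attr:`entity_ids` or is -1 for background.
    """

    points: np.ndarray  # (N, 3) float, meters
    colors: np.ndarray  # (N, 3) float in [0, 1]
    labels: Optional[np.ndarray] = None  # (N,) int
    entity_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
        if len(self.points) != len(self.colors):
            raise ValueError("points and colors must have equal length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
            if len(self.labels) != len(self.points):
                raise ValueError("labels must align with points")
            if len(self.entity_ids) and self.labels.size and self.labels.max(initial=-1) >= len(self.entity_ids):
                raise ValueError("labels reference entities beyond entity_ids")

    def __len__(self) -> int:
        return len(self.points)

    def points_of(self, entity_id: str) -> np.ndarray:
        """Boolean mask of points labeled with ``entity_id``."""
        if self.labels is None:
            raise ValueError("cloud has no instance labels")
        try:
            idx = self.entity_ids.index(entity_id)
        except ValueError:
            return np.zeros(len(self.points), dtype=bool)
        return self.labels == idx


@dataclass
class HumanPose:
    """A detected 3D skeleton with exactly 14 named joints."""

    person_id: str
    joints: np.ndarray  # (14, 3)
    confidence: np.ndarray | None = None  # (14,)

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=np.float64)
        if self.joints.shape != (14, 3):
            raise ValueError("joints must be a (14, 3) array")
        if not np.all(np.isfinite(self.joints)):
            raise ValueError("joint coordinates must be finite")
        if self.confidence is None:
            self.confidence = np.ones(14)
        else:
            self.confidence = np.asarray(self.confidence, dtype=np.float64).reshape(14)

    def joint(self, name: str) -> np.ndarray:
        return self.joints[JOINT_NAMES.index(name)]

    @property
    def wrists(self) -> np.ndarray:
        return self.joints[list(WRIST_INDICES)]

    @property
    def centroid(self) -> np.ndarray:
        return self.joints.mean(axis=0)


@dataclass
class ObjectBox:
    """An upright 3D bounding box (yaw about z) for a detected object."""

    class_name: str
    center: np.ndarray  # (3,)
    size: np.ndarray  # (3,) full extents
    yaw: float = 0.0
    node_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        self.size = np.asarray(self.size, dtype=np.float64).reshape(3)
        if np.any(self.size <= 0):
            raise ValueError("box extents must be positive")
        if self.node_id is None:
            self.node_id = self.class_name

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized inside-test for an (N, 3) array."""
        local = points - self.center
        c, s = np.cos(-self.yaw), np.sin(-self.yaw)
        x = c * local[:, 0] - s * local[:, 1]
        y = s * local[:, 0] + c * local[:, 1]
        z = local[:, 2]
        half = self.size / 2.0
        return (
            (np.abs(x) <= half[0]) & (np.abs(y) <= half[1]) & (np.abs(z) <= half[2])
        )


@dataclass
class LabelParams:
    """Geometric thresholds for instance-label computation.

    The upstream detections carry no per-point assignment, so points are
    claimed by, in precedence order: object boxes, then skeleton bones
    within ``r_body``, then wrist spheres of ``r_hand`` (virtual instrument).
    """

    r_body: float = 0.15
    r_hand: float = 0.25
    min_instrument_points: int = 20


class LabeledCloud(PointCloudFrame):
    """A PointCloudFrame whose labels were computed by this module."""


def instrument_node_id(person_id: str) -> str:
    """Node id of the virtual instrument attached to one person."""
    return f"instrument:{person_id}"


def _point_segment_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Distance from each of N points to segment ab (vectorized)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a[None, :] + t[:, None] * ab[None, :]
    return np.linalg.norm(points - closest, axis=1)


def compute_instance_labels(
    cloud: PointCloudFrame,
    poses: Sequence[HumanPose],
    boxes: Sequence[ObjectBox],
    params: LabelParams | None = None,
) -> LabeledCloud:
    """Assign every point to exactly one entity (or -1 background).

    Precedence: boxes > humans > virtual instrument.  A point inside several
    boxes goes to the box with the nearest center.  A virtual instrument node
    for a person is only materialized if at least ``min_instrument_points``
    otherwise-unassigned points fall inside one of their hand spheres.
    """
    params = params or LabelParams()
    pts = cloud.points
    n = len(pts)

    entity_ids: list[str] = []
    labels = np.full(n, -1, dtype=np.int64)
    claimed = np.zeros(n, dtype=bool)

    # --- boxes first ------------------------------------------------------
    if boxes:
        inside = np.stack([b.contains(pts) for b in boxes], axis=1)  # (N, B)
        center_d = np.stack(
            [np.linalg.norm(pts - b.center, axis=1) for b in boxes], axis=1
        )
        center_d[~inside] = np.inf
        best_box = np.argmin(center_d, axis=1)
        any_box = inside.any(axis=1)
        for bi, box in enumerate(boxes):
            mask = any_box & (best_box == bi)
            if not mask.any():
                continue
            entity_ids.append(box.node_id)
            labels[mask] = len(entity_ids) - 1
        claimed |= any_box

    # --- skeleton bones ---------------------------------------------------
    if poses:
        body_d = np.full((n, len(poses)), np.inf)
        for pi, pose in enumerate(poses):
            d = np.full(n, np.inf)
            for ja, jb in BONES:
                d = np.minimum(
                    d, _point_segment_distance(pts, pose.joints[ja], pose.joints[jb])
                )
            body_d[:, pi] = d
        nearest_person = np.argmin(body_d, axis=1)
        near_body = body_d.min(axis=1) <= params.r_body
        for pi, pose in enumerate(poses):
            mask = ~claimed & near_body & (nearest_person == pi)
            if not mask.any():
                continue
            entity_ids.append(pose.person_id)
            labels[mask] = len(entity_ids) - 1
        claimed |= near_body

    # --- hand spheres -> virtual instrument -------------------------------
    for pose in poses:
        hand_d = np.min(
            np.stack(
                [np.linalg.norm(pts - w, axis=1) for w in pose.wrists], axis=1
            ),
            axis=1,
        )
        mask = ~claimed & (hand_d <= params.r_hand)
        if mask.sum() >= params.min_instrument_points:
            entity_ids.append(instrument_node_id(pose.person_id))
            labels[mask] = len(entity_ids) - 1
            claimed |= mask

    return LabeledCloud(
        points=pts.copy(),
        colors=cloud.colors.copy(),
        labels=labels,
        entity_ids=entity_ids,
    )


def _sample_rows(
    n_available: int, n_points: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample of row indices; with replacement iff too few rows."""
    if n_available >= n_points:
        return rng.choice(n_available, size=n_points, replace=False)
    return rng.choice(n_available, size=n_points, replace=True)


def _canonical_order(cloud: PointCloudFrame, rows: np.ndarray) -> np.ndarray:
    """Reorder candidate rows lexicographically by coordinates and color so
    sampling does not depend on the cloud's storage order."""
    pts, cols = cloud.points[rows], cloud.colors[rows]
    keys = np.concatenate([pts, cols], axis=1)
    return rows[np.lexsort(keys.T[::-1])]


def sample_entity_cloud(
    cloud: PointCloudFrame,
    entity_id: str,
    n_points: int = 4000,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Fixed-size (points, colors) sample of one entity, or ``None`` if the
    entity has no geometry (caller substitutes a missing-geometry embedding)."""
    rng = np.random.default_rng(rng)
    mask = cloud.points_of(entity_id)
    count = int(mask.sum())
    if count == 0:
        return None
    rows = _canonical_order(cloud, np.flatnonzero(mask))
    idx = rows[_sample_rows(count, n_points, rng)]
    return cloud.points[idx], cloud.colors[idx]


def sample_pair_cloud(
    cloud: PointCloudFrame,
    subject_id: str,
    object_id: str,
    n_points: int = 8000,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Sample the union cloud of an ordered pair.

    Returns (points, colors, indicator) where indicator is 0 for subject
    points and 1 for object points; ``None`` when both entities are empty.
    Sampling is proportional to each entity's share of the union.
    """
    rng = np.random.default_rng(rng)
    mask_s = cloud.points_of(subject_id)
    mask_o = cloud.points_of(object_id)
    union = _canonical_order(cloud, np.flatnonzero(mask_s | mask_o))
    if union.size == 0:
        return None
    idx = union[_sample_rows(union.size, n_points, rng)]
    indicator = mask_o[idx].astype(np.float64)
    return cloud.points[idx], cloud.colors[idx], indicator
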