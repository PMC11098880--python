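"""Procedural simulator of knee-surgery takes.

Generates, per 1 Hz frame: a fused colored point cloud with ground-truth
instance labels, orthographic multi-view images, 14-joint skeletons, object
boxes, a ground-truth scene graph, role and phase labels.  The scripted
timeline walks the eight canonical workflow phases; geometric relations
(CloseTo, LyingOn) are derived from the generated geometry so the rule-based
phase engine recovers the script exactly on noiseless takes.

Hand-held tools deliberately stress the multimodal design: they share one
shape, appear in the point cloud only as colorless gray blobs at the acting
hand, and show their identifying color only in the rendered images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import (
    ClinicalRole,
    Entity,
    PHASE_ORDER,
    RelationVocabulary,
    SceneGraph,
    SceneSequence,
    SurgicalPhase,
    Triplet,
    validate_graph,
)
from .instances import (
    BONES,
    HumanPose,
    JOINT_NAMES,
    ObjectBox,
    PointCloudFrame,
    instrument_node_id,
)

__all__ = [
    "NoiseConfig",
    "SimConfig",
    "ORLayout",
    "FrameBundle",
    "default_layout",
    "simulate_timeline",
    "simulate_take",
    "relations_from_geometry",
    "render_frame",
    "inject_noise",
    "attach_roles",
    "bundles_to_sequence",
    "write_take",
]

TOOL_CLOUD_COLOR = (0.55, 0.55, 0.55)  # tools are colorless in the cloud

#: Image-only identifying colors of hand-held tools.
TOOL_IMAGE_COLORS: dict[str, tuple[float, float, float]] = {
    "scalpel": (1.0, 0.9, 0.1),
    "saw": (0.1, 0.8, 0.1),
    "drill": (0.9, 0.1, 0.1),
    "hammer": (0.1, 0.2, 0.9),
    "cement": (1.0, 0.5, 0.0),
    "suture": (0.9, 0.1, 0.9),
}

STAFF_ROLES = (
    ClinicalRole.HEAD_SURGEON,
    ClinicalRole.ASSISTANT_SURGEON,
    ClinicalRole.CIRCULATING_NURSE,
    ClinicalRole.ANAESTHETIST,
)


@dataclass
class NoiseConfig:
    relation_dropout_rate: float = 0.0
    relation_swap_rate: float = 0.0
    pose_jitter_sd_m: float = 0.0

    def __post_init__(self) -> None:
        for rate in (self.relation_dropout_rate, self.relation_swap_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("noise rates must lie in [0, 1]")
        if self.pose_jitter_sd_m < 0:
            raise ValueError("pose_jitter_sd_m must be >= 0")


#: Fraction of the take spent in each of the eight phases.
DEFAULT_PHASE_WEIGHTS = (0.10, 0.08, 0.15, 0.20, 0.12, 0.15, 0.08, 0.12)


@dataclass
class SimConfig:
    seed: int = 0
    take_length_s: float = 660.0
    phase_duration_weights: tuple[float, ...] = DEFAULT_PHASE_WEIGHTS
    n_staff: int = 4
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    points_per_entity: int = 300
    n_views: int = 6
    image_size: int = 48
    render: bool = True  # set False for cheap graph/pose-only simulation
    theta_close: float = 1.5
    render_jitter_sd_m: float = 0.02
    box_margin_m: float = 0.08  # detector boxes are slightly inflated

    def __post_init__(self) -> None:
        weights = np.asarray(self.phase_duration_weights, dtype=float)
        if weights.shape != (8,):
            raise ValueError("phase_duration_weights must have 8 entries")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("phase weights must be nonnegative with positive sum")
        if self.take_length_s <= 0:
            raise ValueError("take_length_s must be positive")
        if not 2 <= self.n_staff <= 4:
            raise ValueError("n_staff must be between 2 and 4")
        if self.points_per_entity < 1 or self.n_views < 1:
            raise ValueError("points_per_entity and n_views must be positive")


@dataclass
class ORLayout:
    """Static room furniture: class -> (center, size, yaw) plus colors.

    All hand-held tools share one shape and differ only in (image) color.
    """

    placements: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]]
    color_map: dict[str, tuple[float, float, float]]

    def box(self, name: str, margin: float = 0.0) -> ObjectBox:
        center, size, yaw = self.placements[name]
        inflated = tuple(s + margin for s in size)
        return ObjectBox(name, np.array(center), np.array(inflated), yaw, node_id=name)


def default_layout() -> ORLayout:
    return ORLayout(
        placements={
            "operating table": ((0.0, 0.0, 0.45), (2.0, 0.8, 0.9), 0.0),
            "instrument table": ((2.5, 1.5, 0.4), (1.2, 0.6, 0.8), 0.0),
            "secondary table": ((-2.5, 1.8, 0.4), (1.0, 0.6, 0.8), 0.0),
            "anesthesia equipment": ((-1.8, -1.6, 0.75), (0.6, 0.6, 1.5), 0.0),
        },
        color_map={
            "operating table": (0.45, 0.50, 0.55),
            "instrument table": (0.30, 0.30, 0.35),
            "secondary table": (0.36, 0.30, 0.28),
            "anesthesia equipment": (0.15, 0.40, 0.60),
        },
    )


STAFF_COLORS = [(0.1, 0.5, 0.6), (0.2, 0.6, 0.3), (0.6, 0.3, 0.5), (0.55, 0.55, 0.2)]
PATIENT_COLOR = (0.85, 0.80, 0.70)

STAFF_XY = [(0.2, -0.60), (0.9, -0.55), (2.2, 0.95), (-1.5, -1.1)]
DOOR_XY = (3.2, -2.8)
BEDSIDE_XY = (1.2, -0.9)

PATIENT_KNEE = np.array([0.5, 0.0, 1.05])
ACTING_WRIST = np.array([0.5, -0.05, 1.40])
ASSIST_WRIST = np.array([0.6, 0.30, 1.35])
TOOL_REACH = 0.20  # tool center sits this far beyond the wrist, along the forearm
TOOL_SIZE = (0.05, 0.05, 0.06)


@dataclass
class FrameBundle:
    """Everything the simulator knows about one frame."""

    frame_id: int
    cloud: Optional[PointCloudFrame]
    images: Optional[np.ndarray]  # (n_views, H, W, 3) float32
    poses: list[HumanPose]
    boxes: list[ObjectBox]
    gt_graph: SceneGraph
    gt_roles: dict[str, ClinicalRole]
    gt_phase: SurgicalPhase


# ---------------------------------------------------------------------------
# Skeletons


def standing_pose(x: float, y: float, height: float = 1.75) -> np.ndarray:
    """A simple upright 14-joint skeleton at (x, y)."""
    z = {
        "head": 0.94 * height,
        "neck": 0.84 * height,
        "shoulder": 0.80 * height,
        "elbow": 0.62 * height,
        "wrist": 0.46 * height,
        "hip": 0.52 * height,
        "knee": 0.28 * height,
        "ankle": 0.04 * height,
    }
    w = {"shoulder": 0.20, "elbow": 0.26, "wrist": 0.28, "hip": 0.10, "knee": 0.11, "ankle": 0.12}
    joints = np.zeros((14, 3))
    joints[0] = (x, y, z["head"])
    joints[1] = (x, y, z["neck"])
    for side, sign in (("left", -1.0), ("right", 1.0)):
        joints[JOINT_NAMES.index(f"{side}_shoulder")] = (x + sign * w["shoulder"], y, z["shoulder"])
        joints[JOINT_NAMES.index(f"{side}_elbow")] = (x + sign * w["elbow"], y, z["elbow"])
        joints[JOINT_NAMES.index(f"{side}_wrist")] = (x + sign * w["wrist"], y, z["wrist"])
        joints[JOINT_NAMES.index(f"{side}_hip")] = (x + sign * w["hip"], y, z["hip"])
        joints[JOINT_NAMES.index(f"{side}_knee")] = (x + sign * w["knee"], y, z["knee"])
        joints[JOINT_NAMES.index(f"{side}_ankle")] = (x + sign * w["ankle"], y, z["ankle"])
    return joints


def lying_pose(x: float, y: float, z: float) -> np.ndarray:
    """A supine 14-joint skeleton, body axis along +x, torso centered at (x, y, z)."""
    joints = np.zeros((14, 3))
    joints[0] = (x - 0.75, y, z + 0.05)  # head
    joints[1] = (x - 0.55, y, z + 0.03)  # neck
    for side, sign in (("left", -1.0), ("right", 1.0)):
        joints[JOINT_NAMES.index(f"{side}_shoulder")] = (x - 0.50, y + sign * 0.18, z + 0.02)
        joints[JOINT_NAMES.index(f"{side}_elbow")] = (x - 0.25, y + sign * 0.22, z)
        joints[JOINT_NAMES.index(f"{side}_wrist")] = (x - 0.02, y + sign * 0.24, z)
        joints[JOINT_NAMES.index(f"{side}_hip")] = (x, y + sign * 0.10, z)
        joints[JOINT_NAMES.index(f"{side}_knee")] = (x + 0.35, y + sign * 0.11, z)
        joints[JOINT_NAMES.index(f"{side}_ankle")] = (x + 0.70, y + sign * 0.12, z)
    return joints


def _torso_centroid(joints: np.ndarray) -> np.ndarray:
    # neck and hips
    return joints[[1, 8, 9]].mean(axis=0)


# ---------------------------------------------------------------------------
# Timeline script


def _phase_durations(weights: Sequence[float], total_frames: int) -> list[int]:
    """Proportional integer allocation; every positive weight gets >= 1 frame."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    if total_frames < int((w > 0).sum()):
        raise ValueError("take too short for the number of active phases")
    raw = w * total_frames
    durations = np.floor(raw).astype(int)
    durations[(w > 0) & (durations == 0)] = 1
    # distribute the remainder by largest fractional part
    while durations.sum() < total_frames:
        frac = np.where(w > 0, raw - durations, -np.inf)
        durations[int(np.argmax(frac))] += 1
    while durations.sum() > total_frames:
        candidates = np.where(durations > 1)[0]
        frac = raw[candidates] - durations[candidates]
        durations[candidates[int(np.argmin(frac))]] -= 1
    return durations.tolist()


@dataclass
class _FrameScript:
    phase: SurgicalPhase
    patient_present: bool
    patient_xyz: Optional[np.ndarray]
    patient_lying: bool
    actions: list[Triplet]
    tools: dict[str, str]  # acting human node id -> tool name


_SURGERY1_CYCLE = [
    ("Cutting", "scalpel"),
    ("Sawing", "saw"),
    ("Drilling", "drill"),
    ("Operating", None),
]


def _script_frame(
    phase_idx: int, t: int, length: int, staff_ids: Sequence[str], patient_id: str
) -> _FrameScript:
    phase = PHASE_ORDER[phase_idx]
    hs = staff_ids[0]
    assistant = staff_ids[1]
    nurse = staff_ids[2] if len(staff_ids) > 2 else None
    anaes = staff_ids[3] if len(staff_ids) > 3 else None

    actions: list[Triplet] = []
    tools: dict[str, str] = {}
    patient_present = phase_idx in range(1, 7)
    patient_xyz: Optional[np.ndarray] = None
    patient_lying = False

    on_table = np.array([0.2, 0.0, 1.02])
    door = np.array([*DOOR_XY, 0.75])
    bedside = np.array([*BEDSIDE_XY, 0.75])
    # intermediate gurney stops keep every per-frame move below the track gate
    hops = [np.array([0.7, -0.75, 0.9]), np.array([0.35, -0.5, 1.0])]
    if phase_idx == 1:  # roll-in: door -> bedside -> hops -> on the table
        tail = hops + [on_table]
        if length <= len(tail):
            patient_xyz = tail[-(length - t)]
        else:
            travel = length - len(tail)
            if t < travel:
                frac = t / max(travel - 1, 1)
                patient_xyz = door + frac * (bedside - door)
            else:
                patient_xyz = tail[t - travel]
        patient_lying = bool(np.allclose(patient_xyz, on_table))
    elif phase_idx in (2, 3, 4, 5):
        patient_xyz = on_table
        patient_lying = True
    elif phase_idx == 6:  # roll-out: reverse of roll-in
        head = hops[::-1] + [bedside]
        if t < len(head):
            patient_xyz = head[min(t, length - 1)] if length > len(head) else head[t]
        else:
            travel = length - len(head)
            frac = (t - len(head) + 1) / max(travel, 1)
            patient_xyz = bedside + min(frac, 1.0) * (door - bedside)

    if nurse is not None and phase_idx in (0, 7):
        actions.append((nurse, "Cleaning", "instrument table"))
    if anaes is not None and phase_idx in range(1, 7):
        actions.append((anaes, "Touching", "anesthesia equipment"))

    if phase_idx == 2:
        actions.append((hs, "Preparing", patient_id))
        actions.append((assistant, "Preparing", patient_id))
    elif phase_idx == 3:
        relation, tool = _SURGERY1_CYCLE[t % len(_SURGERY1_CYCLE)]
        actions.append((hs, relation, patient_id))
        if tool is not None:
            tools[hs] = tool
        actions.append((assistant, "Assisting", hs))
    elif phase_idx == 4:
        actions.append((hs, "Hammering", patient_id))
        tools[hs] = "hammer"
        actions.append((assistant, "Assisting", hs))
    elif phase_idx == 5:
        actions.append((hs, "Cementing", patient_id))
        tools[hs] = "cement"
        actions.append((assistant, "Suturing", patient_id))
        tools[assistant] = "suture"

    for person, _tool in tools.items():
        actions.append((person, "Holding", instrument_node_id(person)))

    return _FrameScript(phase, patient_present, patient_xyz, patient_lying, actions, tools)


# ---------------------------------------------------------------------------
# Geometric relations


def relations_from_geometry(
    centroids: Mapping[str, np.ndarray],
    torso_by_human: Mapping[str, np.ndarray],
    tables: Sequence[ObjectBox],
    scripted: Iterable[Triplet],
    theta_close: float = 1.5,
    lying_height: float = 0.5,
) -> set[Triplet]:
    """Combine scripted action edges with geometric CloseTo / LyingOn edges.

    Precedence per ordered pair: scripted action > LyingOn > CloseTo.
    CloseTo (centroid distance < theta_close) is symmetric and emitted once
    per direction; LyingOn requires the torso horizontally within the table
    footprint and 0 < dz < ``lying_height`` above the table top.
    """
    by_pair: dict[tuple[str, str], str] = {}
    for subj, rel, obj in scripted:
        by_pair[(subj, obj)] = rel

    for human_id, torso in torso_by_human.items():
        for table in tables:
            top = table.center[2] + table.size[2] / 2.0
            dz = torso[2] - top
            probe = np.array([torso[0], torso[1], table.center[2]])
            horizontally_in = bool(table.contains(probe[None, :])[0])
            if horizontally_in and 0.0 < dz < lying_height:
                by_pair.setdefault((human_id, table.node_id), "LyingOn")

    ids = sorted(centroids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if np.linalg.norm(centroids[a] - centroids[b]) < theta_close:
                by_pair.setdefault((a, b), "CloseTo")
                by_pair.setdefault((b, a), "CloseTo")

    return {(s, r, o) for (s, o), r in by_pair.items()}


# ---------------------------------------------------------------------------
# Rendering


def _box_surface_points(
    center: np.ndarray, size: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform-ish points on the surface of an axis-aligned box."""
    half = np.asarray(size) / 2.0
    areas = np.array([size[1] * size[2], size[0] * size[2], size[0] * size[1]])
    areas = np.repeat(areas, 2)  # -x,+x,-y,+y,-z,+z
    face = rng.choice(6, size=n, p=areas / areas.sum())
    uv = rng.uniform(-1.0, 1.0, size=(n, 2))
    pts = np.empty((n, 3))
    for f in range(6):
        mask = face == f
        axis = f // 2
        sign = -1.0 if f % 2 == 0 else 1.0
        other = [a for a in range(3) if a != axis]
        pts[mask, axis] = sign * half[axis]
        pts[mask, other[0]] = uv[mask, 0] * half[other[0]]
        pts[mask, other[1]] = uv[mask, 1] * half[other[1]]
    return pts + np.asarray(center)[None, :]


def _skeleton_points(
    joints: np.ndarray, n: int, rng: np.random.Generator, radius: float = 0.05
) -> np.ndarray:
    """Points on cylinders along the bone segments."""
    per_bone = np.full(len(BONES), n // len(BONES))
    per_bone[: n - per_bone.sum()] += 1
    chunks = []
    for (ja, jb), count in zip(BONES, per_bone):
        if count == 0:
            continue
        a, b = joints[ja], joints[jb]
        t = rng.uniform(0.0, 1.0, size=count)
        axis = b - a
        base = a[None, :] + t[:, None] * axis[None, :]
        # radial offset in a plane orthogonal to the bone
        ref = np.array([0.0, 0.0, 1.0])
        if abs(axis @ ref) > 0.9 * np.linalg.norm(axis):
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(axis, ref)
        u /= np.linalg.norm(u) + 1e-12
        v = np.cross(axis, u)
        v /= np.linalg.norm(v) + 1e-12
        theta = rng.uniform(0.0, 2 * np.pi, size=count)
        offset = radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
        chunks.append(base + offset)
    return np.concatenate(chunks, axis=0)


@dataclass
class RenderItem:
    """One entity to render: geometry source plus cloud/image colors."""

    entity_id: str
    kind: str  # 'box' | 'human' | 'tool'
    center: Optional[np.ndarray] = None
    size: Optional[np.ndarray] = None
    joints: Optional[np.ndarray] = None
    cloud_color: tuple[float, float, float] = (0.5, 0.5, 0.5)
    image_color: Optional[tuple[float, float, float]] = None  # defaults to cloud color
    n_points: int = 300
    in_cloud: bool = True


def _view_axes(n_views: int) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """(right, up, forward) triplets for orthographic views."""
    views = [
        (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, -1.0])),  # top
        (np.array([0, 1.0, 0]), np.array([0, 0, 1.0]), np.array([-1.0, 0, 0])),
        (np.array([0, -1.0, 0]), np.array([0, 0, 1.0]), np.array([1.0, 0, 0])),
        (np.array([1.0, 0, 0]), np.array([0, 0, 1.0]), np.array([0, 1.0, 0])),
        (np.array([-1.0, 0, 0]), np.array([0, 0, 1.0]), np.array([0, -1.0, 0])),
    ]
    oblique_f = np.array([-1.0, -1.0, -1.0]) / np.sqrt(3)
    oblique_r = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
    oblique_u = np.cross(oblique_r, oblique_f)
    views.append((oblique_r, oblique_u, oblique_f))
    out = []
    for i in range(n_views):
        out.append(views[i % len(views)])
    return out


def _rasterize(
    points: np.ndarray, colors: np.ndarray, size: int, n_views: int
) -> np.ndarray:
    """Orthographic point splatting with z-buffering, one image per view."""
    images = np.zeros((n_views, size, size, 3), dtype=np.float32)
    if len(points) == 0:
        return images
    extent = 8.0  # room bounds [-4, 4] in every projected axis
    for vi, (right, up, forward) in enumerate(_view_axes(n_views)):
        u = points @ right
        v = points @ up
        depth = points @ forward
        px = np.clip(((u + extent / 2) / extent * size).astype(int), 0, size - 1)
        py = np.clip(((v + extent / 2) / extent * size).astype(int), 0, size - 1)
        # draw far-to-near so the nearest point wins each pixel
        order = np.argsort(depth, kind="stable")[::-1]
        images[vi, py[order], px[order]] = colors[order]
    return images


def render_frame(
    layout: ORLayout,
    items: Sequence[RenderItem],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[PointCloudFrame, np.ndarray]:
    """Render a frame state into a labeled point cloud and orthographic views.

    Every entity contributes Gaussian-perturbed surface points of its
    primitive; the point -> source-entity map is kept as ground-truth
    instance labels.  Images are rasterized from the full geometry (items
    with ``in_cloud=False`` appear in images only).
    """
    del layout  # placements are already baked into the items
    cloud_pts, cloud_cols, cloud_labels, entity_ids = [], [], [], []
    img_pts, img_cols = [], []

    for item in items:
        if item.kind == "box":
            pts = _box_surface_points(item.center, item.size, item.n_points, rng)
        elif item.kind == "tool":
            pts = _box_surface_points(item.center, item.size, item.n_points, rng)
        elif item.kind == "human":
            pts = _skeleton_points(item.joints, item.n_points, rng)
        else:
            raise ValueError(f"unknown render kind {item.kind!r}")
        pts = pts + rng.normal(0.0, config.render_jitter_sd_m, size=pts.shape)
        cloud_color = np.clip(
            np.asarray(item.cloud_color)[None, :] + rng.normal(0.0, 0.02, (len(pts), 3)),
            0.0,
            1.0,
        )
        image_color = np.asarray(item.image_color or item.cloud_color)
        img_pts.append(pts)
        img_cols.append(np.broadcast_to(image_color, (len(pts), 3)))
        if item.in_cloud:
            if item.entity_id not in entity_ids:
                entity_ids.append(item.entity_id)
            label = entity_ids.index(item.entity_id)
            cloud_pts.append(pts)
            cloud_cols.append(cloud_color)
            cloud_labels.append(np.full(len(pts), label, dtype=np.int64))

    if cloud_pts:
        cloud = PointCloudFrame(
            points=np.concatenate(cloud_pts),
            colors=np.concatenate(cloud_cols),
            labels=np.concatenate(cloud_labels),
            entity_ids=entity_ids,
        )
    else:
        cloud = PointCloudFrame(
            points=np.zeros((0, 3)), colors=np.zeros((0, 3)),
            labels=np.zeros(0, dtype=np.int64), entity_ids=[],
        )
    all_pts = np.concatenate(img_pts) if img_pts else np.zeros((0, 3))
    all_cols = np.concatenate(img_cols) if img_cols else np.zeros((0, 3))
    images = _rasterize(all_pts, all_cols, config.image_size, config.n_views)
    return cloud, images


# ---------------------------------------------------------------------------
# Take assembly


def simulate_timeline(config: SimConfig) -> list[FrameBundle]:
    """Run the scripted workflow and return one FrameBundle per second."""
    rng = np.random.default_rng(config.seed)
    layout = default_layout()
    total_frames = int(round(config.take_length_s))
    durations = _phase_durations(config.phase_duration_weights, total_frames)

    staff_ids = [f"human_{i}" for i in range(config.n_staff)]
    patient_id = f"human_{config.n_staff}"
    roles = {sid: STAFF_ROLES[i] for i, sid in enumerate(staff_ids)}
    roles[patient_id] = ClinicalRole.PATIENT

    boxes = [layout.box(name, config.box_margin_m) for name in layout.placements]
    tables = [b for b in boxes if "table" in b.class_name]
    static_centroids = {
        name: np.asarray(layout.placements[name][0], dtype=float)
        for name in layout.placements
    }

    bundles: list[FrameBundle] = []
    frame_id = 0
    for phase_idx, length in enumerate(durations):
        for t in range(length):
            script = _script_frame(phase_idx, t, length, staff_ids, patient_id)

            # --- skeletons -----------------------------------------------
            poses: dict[str, np.ndarray] = {}
            for i, sid in enumerate(staff_ids):
                joints = standing_pose(*STAFF_XY[i])
                poses[sid] = joints
            if script.patient_present:
                px, py, pz = script.patient_xyz
                poses[patient_id] = lying_pose(px, py, pz)
            # acting hands reach the patient knee
            for person in script.tools:
                wrist = ACTING_WRIST if person == staff_ids[0] else ASSIST_WRIST
                poses[person] = poses[person].copy()
                poses[person][JOINT_NAMES.index("right_wrist")] = wrist
            if any(s == staff_ids[0] and r in ("Preparing", "Operating") for s, r, _ in script.actions):
                poses[staff_ids[0]] = poses[staff_ids[0]].copy()
                poses[staff_ids[0]][JOINT_NAMES.index("right_wrist")] = ACTING_WRIST
            if any(s == staff_ids[1] and r == "Preparing" for s, r, _ in script.actions):
                poses[staff_ids[1]] = poses[staff_ids[1]].copy()
                poses[staff_ids[1]][JOINT_NAMES.index("right_wrist")] = ASSIST_WRIST

            # --- centroids / graph nodes ---------------------------------
            centroids = dict(static_centroids)
            for pid, joints in poses.items():
                centroids[pid] = joints.mean(axis=0)
            tool_centers: dict[str, np.ndarray] = {}
            for person in script.tools:
                wrist = poses[person][JOINT_NAMES.index("right_wrist")]
                elbow = poses[person][JOINT_NAMES.index("right_elbow")]
                forearm = wrist - elbow
                forearm = forearm / (np.linalg.norm(forearm) + 1e-12)
                node = instrument_node_id(person)
                tool_centers[node] = wrist + TOOL_REACH * forearm
                centroids[node] = tool_centers[node]

            torso_by_human = {pid: _torso_centroid(j) for pid, j in poses.items()}
            edges = relations_from_geometry(
                centroids, torso_by_human, tables, script.actions, config.theta_close
            )

            graph = SceneGraph(frame_id)
            for name in layout.placements:
                graph.add_node(Entity(name, name, centroid=tuple(static_centroids[name])))
            for pid, joints in poses.items():
                graph.add_node(Entity(pid, "human", centroid=tuple(joints.mean(axis=0))))
            for person in script.tools:
                node = instrument_node_id(person)
                graph.add_node(Entity(node, "instrument", centroid=tuple(tool_centers[node])))
            for subj, rel, obj in sorted(edges):
                graph.add_edge(subj, rel, obj)
            assert not validate_graph(graph), validate_graph(graph)

            # --- geometry ------------------------------------------------
            cloud = images = None
            if config.render:
                items: list[RenderItem] = []
                for name in layout.placements:
                    center, size, _yaw = layout.placements[name]
                    items.append(
                        RenderItem(
                            entity_id=name,
                            kind="box",
                            center=np.asarray(center),
                            size=np.asarray(size),
                            cloud_color=layout.color_map[name],
                            n_points=config.points_per_entity,
                        )
                    )
                for i, sid in enumerate(staff_ids):
                    items.append(
                        RenderItem(
                            entity_id=sid,
                            kind="human",
                            joints=poses[sid],
                            cloud_color=STAFF_COLORS[i],
                            n_points=config.points_per_entity,
                        )
                    )
                if script.patient_present:
                    items.append(
                        RenderItem(
                            entity_id=patient_id,
                            kind="human",
                            joints=poses[patient_id],
                            cloud_color=PATIENT_COLOR,
                            n_points=config.points_per_entity,
                        )
                    )
                for person, tool in script.tools.items():
                    node = instrument_node_id(person)
                    items.append(
                        RenderItem(
                            entity_id=node,
                            kind="tool",
                            center=tool_centers[node],
                            size=np.asarray(TOOL_SIZE),
                            cloud_color=TOOL_CLOUD_COLOR,
                            image_color=TOOL_IMAGE_COLORS[tool],
                            n_points=max(config.points_per_entity // 4, 25),
                        )
                    )
                    # cameras see the tool clearly even though the fused
                    # cloud captures it poorly: image-only halo
                    items.append(
                        RenderItem(
                            entity_id=node,
                            kind="tool",
                            center=tool_centers[node] + np.array([0.0, 0.0, 0.18]),
                            size=np.asarray(TOOL_SIZE) * (4.0, 4.0, 3.0),
                            cloud_color=TOOL_IMAGE_COLORS[tool],
                            n_points=config.points_per_entity,
                            in_cloud=False,
                        )
                    )
                cloud, images = render_frame(layout, items, config, rng)

            # --- detections (optionally jittered) ------------------------
            detected_poses = []
            for pid, joints in poses.items():
                jittered = joints
                if config.noise.pose_jitter_sd_m > 0:
                    jittered = joints + rng.normal(
                        0.0, config.noise.pose_jitter_sd_m, joints.shape
                    )
                detected_poses.append(HumanPose(person_id=pid, joints=jittered))

            bundles.append(
                FrameBundle(
                    frame_id=frame_id,
                    cloud=cloud,
                    images=images,
                    poses=detected_poses,
                    boxes=list(boxes),
                    gt_graph=graph,
                    gt_roles=dict(roles),
                    gt_phase=script.phase,
                )
            )
            frame_id += 1
    return bundles


def simulate_take(config: SimConfig, take_id: str = "take_0") -> tuple[list[FrameBundle], SceneSequence]:
    bundles = simulate_timeline(config)
    return bundles, bundles_to_sequence(bundles, take_id)


def bundles_to_sequence(bundles: Sequence[FrameBundle], take_id: str = "take_0") -> SceneSequence:
    return SceneSequence(take_id=take_id, graphs=[b.gt_graph for b in bundles], fps=1.0)


def attach_roles(graph: SceneGraph, roles: Mapping[str, ClinicalRole]) -> SceneGraph:
    """Copy of ``graph`` with roles set on the human nodes found in ``roles``."""
    out = graph.copy()
    for node_id, role in roles.items():
        if node_id in out.nodes:
            out.nodes[node_id].role = role
    return out


def inject_noise(
    graphs: Sequence[SceneGraph],
    noise: NoiseConfig,
    seed: int | np.random.Generator | None = None,
    relations: RelationVocabulary | None = None,
) -> list[SceneGraph]:
    """Corrupt graph edges to emulate imperfect predictions.

    Each edge is independently dropped with ``relation_dropout_rate``;
    surviving edges are relabeled to a uniformly random *other* semantic
    relation with ``relation_swap_rate``.  Node sets are untouched.
    """
    rng = np.random.default_rng(seed)
    relations = relations or RelationVocabulary()
    semantic = list(relations.semantic)
    out = []
    for graph in graphs:
        corrupted = SceneGraph(graph.frame_id, nodes=[n.copy() for n in graph.nodes.values()])
        for subj, rel, obj in sorted(graph.edges):
            if rng.random() < noise.relation_dropout_rate:
                continue
            if rng.random() < noise.relation_swap_rate:
                others = [r for r in semantic if r != rel]
                rel = others[int(rng.integers(len(others)))]
            corrupted.add_edge(subj, rel, obj)
        out.append(corrupted)
    return out


# ---------------------------------------------------------------------------
# Disk export (plain-text formats only)


def _write_ascii_ply(path: Path, cloud: PointCloudFrame) -> None:
    n = len(cloud)
    with open(path, "w", encoding="ascii") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {n}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            "end_header\n"
        )
        rgb = np.clip(cloud.colors * 255, 0, 255).astype(int)
        for (x, y, z), (r, g, b) in zip(cloud.points, rgb):
            fh.write(f"{x:.4f} {y:.4f} {z:.4f} {r} {g} {b}\n")


def write_take(bundles: Sequence[FrameBundle], out_dir, take_id: str = "take_0") -> Path:
    """Write one take to disk: PLY + PNG per frame, poses/boxes/labels JSON,
    and the ground-truth scene-graph sequence."""
    import imageio.v3 as iio

    root = Path(out_dir) / take_id
    root.mkdir(parents=True, exist_ok=True)
    from .core import write_sequence

    write_sequence(root / "gt_graphs.json", bundles_to_sequence(bundles, take_id))
    meta = {
        "take_id": take_id,
        "phases": [{"frame_id": b.frame_id, "phase": b.gt_phase.value} for b in bundles],
        "roles": {k: v.value for k, v in bundles[0].gt_roles.items()} if bundles else {},
    }
    (root / "meta.json").write_text(json.dumps(meta, indent=1))
    for bundle in bundles:
        stem = root / f"frame_{bundle.frame_id:05d}"
        payload = {
            "poses": [
                {"person_id": p.person_id, "joints": p.joints.tolist()}
                for p in bundle.poses
            ],
            "boxes": [
                {
                    "node_id": b.node_id,
                    "class": b.class_name,
                    "center": b.center.tolist(),
                    "size": b.size.tolist(),
                    "yaw": b.yaw,
                }
                for b in bundle.boxes
            ],
        }
        (stem.with_suffix(".json")).write_text(json.dumps(payload))
        if bundle.cloud is not None:
            _write_ascii_ply(stem.with_suffix(".ply"), bundle.cloud)
            np.savetxt(
                stem.with_suffix(".labels.txt"),
                bundle.cloud.labels,
                fmt="%d",
                header=" ".join(bundle.cloud.entity_ids),
            )
        if bundle.images is not None:
            for vi in range(bundle.images.shape[0]):
                img = (np.clip(bundle.images[vi], 0, 1) * 255).astype(np.uint8)
                iio.imwrite(f"{stem}_view{vi}.png", img)
    return root
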