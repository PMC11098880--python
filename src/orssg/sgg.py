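"""Multimodal scene-graph generation network.

Candidate entities come from instance labels (upstream detections).  A
shared per-point MLP with symmetric max-pooling encodes each entity's point
set; a second one encodes each ordered pair's union cloud (with a
which-entity indicator channel).  An optional global image feature from a
small convolutional encoder over the concatenated views is fused (by
concatenation) into every node and edge slot.  A graph convolutional
network contextualizes the features before MLP heads score entity classes
and the 15 relation classes (background included).  Training minimizes
class-weighted cross-entropy end-to-end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .augment import AugmentParams, augment_cloud, augment_relation_pair, crop_to_hands
from .core import (
    Entity,
    EntityVocabulary,
    NONE_RELATION,
    RelationVocabulary,
    SceneGraph,
    validate_graph,
)
from .instances import (
    HumanPose,
    LabelParams,
    LabeledCloud,
    compute_instance_labels,
    sample_entity_cloud,
    sample_pair_cloud,
)
from .nn import MLP, Adam, Conv2d, Linear, Module, Tensor, concat, softmax_cross_entropy

__all__ = [
    "SGGConfig",
    "SGGFrame",
    "FrameFeatures",
    "SGGModel",
    "ImageEncoder",
    "frame_from_bundle",
    "class_balanced_weights",
    "sgg_forward",
    "train_sgg",
    "predict_graph",
    "save_model",
    "load_model",
]


@dataclass
class SGGConfig:
    feat_dim: int = 128
    hidden_dim: int = 64
    image_dim: int = 32
    gcn_layers: int = 2
    n_obj_points: int = 4000
    n_rel_points: int = 8000
    learning_rate: float = 3e-5
    epochs: int = 20
    seed: int = 0
    use_images: bool = True
    class_weighting: str = "linear"  # 'none' | 'linear'
    augment: Optional[AugmentParams] = None
    crop_prob: float = 0.25  # crop-to-hand on relation clouds during training

    def __post_init__(self) -> None:
        if min(self.feat_dim, self.hidden_dim, self.gcn_layers) <= 0:
            raise ValueError("dims and layer counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.class_weighting not in ("none", "linear"):
            raise ValueError("class_weighting must be 'none' or 'linear'")


@dataclass
class SGGFrame:
    """One network input: a labeled cloud, optional images, candidates."""

    cloud: LabeledCloud
    images: Optional[np.ndarray]  # (V, H, W, 3)
    entity_ids: list[str]
    gt_graph: Optional[SceneGraph] = None
    poses: list[HumanPose] = field(default_factory=list)
    frame_id: int = 0


@dataclass
class FrameFeatures:
    """Pooled per-slot features with their entity provenance."""

    node_features: np.ndarray  # (n, D)
    edge_features: np.ndarray  # (n*(n-1), D)
    node_ids: list[str]
    pair_ids: list[tuple[str, str]]


def frame_from_bundle(bundle, label_params: LabelParams | None = None) -> SGGFrame:
    """Run instance labeling on a simulator frame to build a network input."""
    if bundle.cloud is None:
        raise ValueError("bundle has no geometry; simulate with render=True")
    labeled = compute_instance_labels(
        bundle.cloud, bundle.poses, bundle.boxes, label_params
    )
    return SGGFrame(
        cloud=labeled,
        images=bundle.images,
        entity_ids=list(labeled.entity_ids),
        gt_graph=bundle.gt_graph,
        poses=list(bundle.poses),
        frame_id=bundle.frame_id,
    )


class ImageEncoder(Module):
    """Default pluggable image encoder: conv + global max-pool + linear.

    Consumes all views concatenated along channels; emits one global vector.
    Any callable mapping a (V, H, W, 3) array to a (1, out_dim) Tensor can
    stand in for it.
    """

    def __init__(self, n_channels: int, out_dim: int, rng: np.random.Generator):
        self.conv = Conv2d(n_channels, 24, kernel=3, stride=2, rng=rng)
        self.head = Linear(24, out_dim, rng)
        self.n_channels = n_channels

    def __call__(self, images: np.ndarray) -> Tensor:
        stacked = np.concatenate(list(images), axis=-1)  # (H, W, 3*V)
        x = self.conv(Tensor(stacked)).relu()
        h, w, c = x.shape
        # global max-pool: each channel flags the presence of a color pattern
        pooled = x.reshape(h * w, c).max(axis=0).reshape(1, c)
        return self.head(pooled)


class SGGModel(Module):
    def __init__(
        self,
        config: SGGConfig,
        entities: EntityVocabulary,
        relations: RelationVocabulary,
        n_image_channels: int = 18,
        image_encoder: Optional[Callable[[np.ndarray], Tensor]] = None,
    ):
        self.config = config
        self.entities = entities
        self.relations = relations
        rng = np.random.default_rng(config.seed)
        f, h = config.feat_dim, config.hidden_dim

        self.obj_pointnet = MLP([6, h, f], rng)
        self.rel_pointnet = MLP([7, h, f], rng)
        self.missing_obj = Tensor(rng.normal(0, 0.1, (1, f)), requires_grad=True)
        self.missing_rel = Tensor(rng.normal(0, 0.1, (1, f)), requires_grad=True)

        img_dim = config.image_dim if config.use_images else 0
        self.image_encoder = None
        if config.use_images:
            self.image_encoder = (
                image_encoder
                if image_encoder is not None
                else ImageEncoder(n_image_channels, config.image_dim, rng)
            )
        d = f + img_dim
        self.edge_updates = [MLP([3 * d, d], rng) for _ in range(config.gcn_layers)]
        self.node_updates = [MLP([2 * d, d], rng) for _ in range(config.gcn_layers)]
        self.node_head = MLP([d, h, len(entities)], rng)
        self.edge_head = MLP([d, h, len(relations)], rng)

    # -- feature extraction ----------------------------------------------

    def _sample_arrays(
        self,
        frame: SGGFrame,
        rng: np.random.Generator,
        training: bool,
    ):
        cfg = self.config
        aug = cfg.augment if training else None
        ids = frame.entity_ids
        n = len(ids)

        obj_arrays = np.zeros((n, cfg.n_obj_points, 6))
        obj_present = np.zeros(n, dtype=bool)
        for i, eid in enumerate(ids):
            sampled = sample_entity_cloud(frame.cloud, eid, cfg.n_obj_points, rng)
            if sampled is None:
                continue
            pts, cols = sampled
            if aug is not None:
                pts, cols = augment_cloud(pts, cols, aug, rng)
            obj_arrays[i] = np.concatenate([pts, cols], axis=1)
            obj_present[i] = True

        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        rel_arrays = np.zeros((len(pairs), cfg.n_rel_points, 7))
        rel_present = np.zeros(len(pairs), dtype=bool)
        for k, (i, j) in enumerate(pairs):
            sampled = sample_pair_cloud(
                frame.cloud, ids[i], ids[j], cfg.n_rel_points, rng
            )
            if sampled is None:
                continue
            pts, cols, ind = sampled
            if aug is not None:
                pts, cols = augment_relation_pair(pts, cols, ind, aug, rng)
                if frame.poses and rng.random() < cfg.crop_prob:
                    crop = replace(aug, crop_to_hand_prob=1.0)
                    pts2, cols2, ind2 = crop_to_hands(
                        pts, cols, frame.poses, crop, rng, labels=ind
                    )
                    if len(pts2) != len(pts):  # re-pad to fixed size
                        take = rng.choice(len(pts2), cfg.n_rel_points, replace=True)
                        pts, cols, ind = pts2[take], cols2[take], ind2[take]
            rel_arrays[k] = np.concatenate([pts, cols, ind[:, None]], axis=1)
            rel_present[k] = True

        return pairs, obj_arrays, obj_present, rel_arrays, rel_present

    def _pool(self, encoder: MLP, arrays: np.ndarray, present: np.ndarray, missing: Tensor) -> Tensor:
        n, p, c = arrays.shape
        if n == 0:
            return Tensor(np.zeros((0, self.config.feat_dim)))
        per_point = encoder(Tensor(arrays.reshape(n * p, c)))
        pooled = per_point.reshape(n, p, self.config.feat_dim).max(axis=1)
        keep = Tensor(np.diag(present.astype(float)))
        fill = Tensor((~present).astype(float)[:, None])
        return keep @ pooled + fill @ missing

    def forward(
        self,
        frame: SGGFrame,
        rng: np.random.Generator | None = None,
        training: bool = False,
    ) -> tuple[Tensor, Tensor, list[tuple[int, int]]]:
        """Return (node logits (n, C_e), edge logits (n(n-1), C_r), pairs)."""
        rng = np.random.default_rng(0) if rng is None else rng
        pairs, obj_arrays, obj_present, rel_arrays, rel_present = self._sample_arrays(
            frame, rng, training
        )
        n = len(frame.entity_ids)
        h = self._pool(self.obj_pointnet, obj_arrays, obj_present, self.missing_obj)
        e = self._pool(self.rel_pointnet, rel_arrays, rel_present, self.missing_rel)

        if self.config.use_images:
            if frame.images is None:
                raise ValueError("use_images=True but frame has no images")
            img = self.image_encoder(frame.images)  # (1, img_dim)
            h = concat([h, Tensor(np.ones((n, 1))) @ img], axis=1)
            if len(pairs):
                e = concat([e, Tensor(np.ones((len(pairs), 1))) @ img], axis=1)
            else:
                e = Tensor(np.zeros((0, self.config.feat_dim + self.config.image_dim)))

        if len(pairs):
            sub_sel = np.zeros((len(pairs), n))
            obj_sel = np.zeros((len(pairs), n))
            incidence = np.zeros((n, len(pairs)))
            for k, (i, j) in enumerate(pairs):
                sub_sel[k, i] = 1.0
                obj_sel[k, j] = 1.0
                incidence[i, k] = 1.0
                incidence[j, k] = 1.0
            incidence /= np.maximum(incidence.sum(axis=1, keepdims=True), 1.0)
            t_sub, t_obj, t_inc = Tensor(sub_sel), Tensor(obj_sel), Tensor(incidence)
            for edge_mlp, node_mlp in zip(self.edge_updates, self.node_updates):
                e = edge_mlp(concat([t_sub @ h, e, t_obj @ h], axis=1)).relu()
                h = node_mlp(concat([h, t_inc @ e], axis=1)).relu()
        else:
            d = h.shape[1]
            for node_mlp in self.node_updates:
                h = node_mlp(concat([h, Tensor(np.zeros((n, d)))], axis=1)).relu()

        node_logits = self.node_head(h)
        edge_logits = self.edge_head(e) if len(pairs) else Tensor(np.zeros((0, len(self.relations))))
        return node_logits, edge_logits, pairs

    def frame_features(self, frame: SGGFrame) -> FrameFeatures:
        """Pooled pre-head features with provenance (diagnostic surface)."""
        rng = np.random.default_rng(0)
        pairs, obj_arrays, obj_present, rel_arrays, rel_present = self._sample_arrays(
            frame, rng, training=False
        )
        h = self._pool(self.obj_pointnet, obj_arrays, obj_present, self.missing_obj)
        e = self._pool(self.rel_pointnet, rel_arrays, rel_present, self.missing_rel)
        ids = frame.entity_ids
        return FrameFeatures(
            node_features=h.data.copy(),
            edge_features=e.data.copy(),
            node_ids=list(ids),
            pair_ids=[(ids[i], ids[j]) for i, j in pairs],
        )


def sgg_forward(
    frame: SGGFrame, model: SGGModel
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Functional inference wrapper: (node scores, pair scores, pair ids)."""
    node_logits, edge_logits, pairs = model.forward(frame)
    ids = frame.entity_ids
    return (
        node_logits.data.copy(),
        edge_logits.data.copy(),
        [(ids[i], ids[j]) for i, j in pairs],
    )


def class_balanced_weights(counts: Sequence[float], mode: str = "linear") -> np.ndarray:
    """Linear class weights w_c proportional to (1 - n_c / sum), mean 1."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if mode == "none":
        return np.ones(len(counts))
    if mode != "linear":
        raise ValueError(f"unknown weighting mode {mode!r}")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one class count must be positive")
    w = 1.0 - counts / total
    mean = w.mean()
    if mean <= 0:
        return np.ones(len(counts))
    return w / mean


def _frame_targets(
    frame: SGGFrame,
    pairs: list[tuple[int, int]],
    entities: EntityVocabulary,
    relations: RelationVocabulary,
) -> tuple[np.ndarray, np.ndarray]:
    gt = frame.gt_graph
    if gt is None:
        raise ValueError("training frames need gt_graph")
    ids = frame.entity_ids
    none_idx = relations.index(NONE_RELATION)
    node_t = np.full(len(ids), -1, dtype=np.int64)
    for i, eid in enumerate(ids):
        if eid in gt.nodes:
            node_t[i] = entities.index(gt.nodes[eid].class_name)
    edge_t = np.full(len(pairs), none_idx, dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        rel = gt.relation_between(ids[i], ids[j]) if ids[i] in gt.nodes and ids[j] in gt.nodes else None
        if rel is not None:
            edge_t[k] = relations.index(rel)
    return node_t, edge_t


def relation_class_counts(
    frames: Sequence[SGGFrame], relations: RelationVocabulary
) -> np.ndarray:
    """Counts of each relation class over all ordered candidate pairs."""
    counts = np.zeros(len(relations))
    for frame in frames:
        n = len(frame.entity_ids)
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        _, edge_t = _frame_targets(frame, pairs, EntityVocabulary(), relations)
        for t in edge_t:
            counts[t] += 1
    return counts


def train_sgg(
    frames: Sequence[SGGFrame],
    config: SGGConfig,
    entities: EntityVocabulary | None = None,
    relations: RelationVocabulary | None = None,
    image_encoder: Optional[Callable[[np.ndarray], Tensor]] = None,
) -> tuple[SGGModel, list[float]]:
    """End-to-end training with weighted cross-entropy; returns per-epoch mean loss."""
    if not frames:
        raise ValueError("need at least one training frame")
    entities = entities or EntityVocabulary()
    relations = relations or RelationVocabulary()
    n_channels = 3 * frames[0].images.shape[0] if (config.use_images and frames[0].images is not None) else 18
    model = SGGModel(config, entities, relations, n_channels, image_encoder)
    rel_weights = class_balanced_weights(
        relation_class_counts(frames, relations),
        mode=config.class_weighting,
    )
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    history: list[float] = []
    order = np.arange(len(frames))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        losses = []
        for fi in order:
            frame = frames[fi]
            node_logits, edge_logits, pairs = model.forward(frame, rng, training=True)
            node_t, edge_t = _frame_targets(frame, pairs, entities, relations)
            loss = softmax_cross_entropy(node_logits, node_t)
            if len(pairs):
                loss = loss + softmax_cross_entropy(edge_logits, edge_t, rel_weights)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, frame {frame.frame_id}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
        history.append(float(np.mean(losses)))
    return model, history


def predict_graph(frame: SGGFrame, model: SGGModel) -> SceneGraph:
    """Argmax decode of one frame into a valid scene graph."""
    node_logits, edge_logits, pairs = model.forward(frame)
    ids = frame.entity_ids
    entities, relations = model.entities, model.relations
    none_idx = relations.index(NONE_RELATION)

    graph = SceneGraph(frame.frame_id)
    for i, eid in enumerate(ids):
        cls = entities.names[int(np.argmax(node_logits.data[i]))]
        mask = frame.cloud.points_of(eid)
        centroid = (
            tuple(frame.cloud.points[mask].mean(axis=0)) if mask.any() else None
        )
        graph.add_node(Entity(eid, cls, centroid=centroid))
    for k, (i, j) in enumerate(pairs):
        best = int(np.argmax(edge_logits.data[k]))
        if best != none_idx:
            graph.add_edge(ids[i], relations.names[best], ids[j])
    assert not validate_graph(graph, entities, relations)
    return graph


def save_model(model: SGGModel, path) -> None:
    cfg = {k: v for k, v in vars(model.config).items() if k != "augment"}
    np.savez(
        path,
        config=json.dumps(cfg),
        entity_names=np.array(model.entities.names),
        relation_names=np.array(model.relations.names),
        **{f"param_{i}": arr for i, arr in enumerate(model.state_arrays())},
    )


def load_model(path) -> SGGModel:
    data = np.load(path, allow_pickle=False)
    cfg = SGGConfig(**json.loads(str(data["config"])))
    entities = EntityVocabulary(tuple(data["entity_names"]))
    relations = RelationVocabulary(tuple(data["relation_names"]))
    model = SGGModel(cfg, entities, relations)
    arrays = [data[f"param_{i}"] for i in range(len(model.parameters()))]
    model.load_state_arrays(arrays)
    return model
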