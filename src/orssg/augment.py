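"""Training-time point-cloud augmentation.

Three families: whole-cloud geometric + color jitter, per-object jitter for
relation pair clouds (each side transformed independently), and crop-to-hand
which restricts a cloud to the vicinity of a randomly chosen wrist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv

from .instances import HumanPose

__all__ = [
    "AugmentParams",
    "augment_cloud",
    "augment_relation_pair",
    "crop_to_hands",
]


@dataclass
class AugmentParams:
    # geometry
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_sd_m: float = 0.1
    rotation_z_range_deg: tuple[float, float] = (-180.0, 180.0)
    # color
    brightness_range: tuple[float, float] = (-0.1, 0.1)  # additive
    hue_range_deg: tuple[float, float] = (-10.0, 10.0)
    # crop-to-hand
    crop_to_hand_prob: float = 0.5
    crop_radius_m: float = 0.6

    def __post_init__(self) -> None:
        for lo, hi in (
            self.scale_range,
            self.rotation_z_range_deg,
            self.brightness_range,
            self.hue_range_deg,
        ):
            if hi < lo:
                raise ValueError("augmentation ranges must be well-ordered")
        if not 0.0 <= self.crop_to_hand_prob <= 1.0:
            raise ValueError("crop_to_hand_prob must be in [0, 1]")
        if self.translate_sd_m < 0 or self.crop_radius_m <= 0:
            raise ValueError("translate_sd_m >= 0 and crop_radius_m > 0 required")

    @classmethod
    def identity(cls) -> "AugmentParams":
        """Degenerate parameters under which every transform is the identity."""
        return cls(
            scale_range=(1.0, 1.0),
            translate_sd_m=0.0,
            rotation_z_range_deg=(0.0, 0.0),
            brightness_range=(0.0, 0.0),
            hue_range_deg=(0.0, 0.0),
            crop_to_hand_prob=0.0,
        )


def _draw_transform(params: AugmentParams, rng: np.random.Generator):
    scale = rng.uniform(*params.scale_range)
    angle = np.deg2rad(rng.uniform(*params.rotation_z_range_deg))
    translation = (
        rng.normal(0.0, params.translate_sd_m, size=3)
        if params.translate_sd_m > 0
        else np.zeros(3)
    )
    brightness = rng.uniform(*params.brightness_range)
    hue = rng.uniform(*params.hue_range_deg) / 360.0
    return scale, angle, translation, brightness, hue


def _apply_geometry(
    points: np.ndarray, scale: float, angle: float, translation: np.ndarray
) -> np.ndarray:
    centroid = points.mean(axis=0, keepdims=True)
    out = (points - centroid) * scale
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    out = out @ rot.T
    return out + centroid + translation[None, :]


def _apply_color(colors: np.ndarray, brightness: float, hue: float) -> np.ndarray:
    out = np.clip(colors + brightness, 0.0, 1.0)
    if hue != 0.0:
        hsv = rgb_to_hsv(out)
        hsv[:, 0] = np.mod(hsv[:, 0] + hue, 1.0)
        out = hsv_to_rgb(hsv)
    return np.clip(out, 0.0, 1.0)


def augment_cloud(
    points: np.ndarray,
    colors: np.ndarray,
    params: AugmentParams,
    seed: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One random scale / translation / z-rotation / brightness / hue draw.

    Scaling is about the cloud centroid; colors are clipped to [0, 1]; point
    order (and therefore any label alignment) is preserved.
    """
    if len(points) == 0:
        raise ValueError("cannot augment an empty cloud")
    rng = np.random.default_rng(seed)
    points = np.asarray(points, dtype=np.float64)
    colors = np.asarray(colors, dtype=np.float64)
    scale, angle, translation, brightness, hue = _draw_transform(params, rng)
    return (
        _apply_geometry(points, scale, angle, translation),
        _apply_color(colors, brightness, hue),
    )


def augment_relation_pair(
    points: np.ndarray,
    colors: np.ndarray,
    indicator: np.ndarray,
    params: AugmentParams,
    seed: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Augment subject (indicator 0) and object (indicator 1) points with two
    independent draws, simulating varying relative sizes and positions.

    The indicator channel itself is untouched by construction (point order
    preserved, groups transformed in place).
    """
    rng = np.random.default_rng(seed)
    points = np.asarray(points, dtype=np.float64).copy()
    colors = np.asarray(colors, dtype=np.float64).copy()
    indicator = np.asarray(indicator)
    for group in (0, 1):
        mask = indicator == group
        if not mask.any():
            # still consume a draw so seeds stay comparable across pairs
            _draw_transform(params, rng)
            continue
        scale, angle, translation, brightness, hue = _draw_transform(params, rng)
        points[mask] = _apply_geometry(points[mask], scale, angle, translation)
        colors[mask] = _apply_color(colors[mask], brightness, hue)
    return points, colors


def crop_to_hands(
    points: np.ndarray,
    colors: np.ndarray,
    poses: Sequence[HumanPose],
    params: AugmentParams,
    seed: np.random.Generator | int | None = None,
    labels: np.ndarray | None = None,
):
    """With probability ``crop_to_hand_prob`` keep only points within
    ``crop_radius_m`` of one uniformly chosen wrist; otherwise pass through.

    Never returns an empty cloud: if the crop sphere contains no points the
    input is returned unchanged.  Optional ``labels`` are subset alongside.
    """
    rng = np.random.default_rng(seed)
    points = np.asarray(points, dtype=np.float64)
    colors = np.asarray(colors, dtype=np.float64)

    def passthrough():
        return (points, colors) if labels is None else (points, colors, labels)

    if not poses:
        warnings.warn("crop_to_hands called without poses; passing through")
        return passthrough()
    if rng.random() >= params.crop_to_hand_prob:
        return passthrough()
    wrists = np.concatenate([p.wrists for p in poses], axis=0)
    wrist = wrists[rng.integers(len(wrists))]
    keep = np.linalg.norm(points - wrist[None, :], axis=1) <= params.crop_radius_m
    if not keep.any():
        return passthrough()
    if labels is None:
        return points[keep], colors[keep]
    return points[keep], colors[keep], np.asarray(labels)[keep]
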