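"""Digit-tracking features: per-gesture touch kinematics.

Five features per gesture: mean point-by-point speed (px/s), area of the
minimal convex polygon over the gesture's points (px^2), total
point-by-point path length (px), duration (s), and vertical extent (px).
The "minimal adaptive polygon" is realised as the convex hull — the
canonical minimal convex polygon containing the points; alternates
(bounding box) are available behind the ``area_method`` switch.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .features import FeatureSeries
from .io import ChallengeRecord, TouchGesture


@dataclasses.dataclass(frozen=True)
class TouchFeatures:
    """The five kinematic features of one touch gesture."""

    speed: float
    area: float
    distance: float
    duration: float
    height: float

    def as_dict(self) -> dict[str, float]:
        return {
            "touch_speed": self.speed,
            "touch_area": self.area,
            "touch_distance": self.distance,
            "touch_duration": self.duration,
            "touch_height": self.height,
        }


def hull_area(points: np.ndarray) -> float:
    """Convex-hull area of a 2-D point set; 0 for < 3 non-collinear points."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is area
    except QhullError:
        return 0.0  # collinear / degenerate


def bounding_box_area(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    ext = pts.max(axis=0) - pts.min(axis=0)
    return float(ext[0] * ext[1])


_AREA_METHODS = {"hull": hull_area, "bbox": bounding_box_area}


def touch_features(gesture: TouchGesture, area_method: str = "hull") -> TouchFeatures:
    """Compute the five digit-tracking features of one gesture.

    Zero-dt repeated samples are collapsed before speed computation, so
    division by zero is impossible on 100 Hz streams that duplicate
    timestamps.  A single-point gesture yields all-zero features.
    """
    pts = np.asarray(gesture.points, dtype=float)
    if pts.shape[0] < 1:
        raise ValueError(f"gesture {gesture.gesture_id}: no points")
    t, xy = pts[:, 0], pts[:, 1:]
    if pts.shape[0] == 1:
        return TouchFeatures(0.0, 0.0, 0.0, 0.0, 0.0)

    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    distance = float(seg.sum())
    duration = float(t[-1] - t[0])
    height = float(xy[:, 1].max() - xy[:, 1].min())
    area = _AREA_METHODS[area_method](xy)

    dt = np.diff(t)
    keep = dt > 0
    speed = float(np.mean(seg[keep] / dt[keep])) if keep.any() else 0.0
    return TouchFeatures(speed, area, distance, duration, height)


def aggregate_touch(
    challenge: ChallengeRecord, area_method: str = "hull"
) -> dict[str, FeatureSeries]:
    """Per-challenge series of the five touch features, one point per
    gesture, indexed by gesture midpoint time and sorted by it.

    A challenge without touch events yields empty series; the binning
    stage's missing-data rule handles those.
    """
    rows = []
    for g in challenge.touches:
        t = g.points[:, 0]
        mid = 0.5 * (float(t[0]) + float(t[-1]))
        rows.append((mid, touch_features(g, area_method=area_method).as_dict()))
    rows.sort(key=lambda r: r[0])
    times = np.array([r[0] for r in rows])
    out = {}
    for name in (
        "touch_speed",
        "touch_area",
        "touch_distance",
        "touch_duration",
        "touch_height",
    ):
        vals = np.array([r[1][name] for r in rows])
        out[name] = FeatureSeries(name, times, vals)
    return out
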