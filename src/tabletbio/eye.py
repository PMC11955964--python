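"""Eye-tracking features: angular kinematics and I-VT event detection.

Four features are computed from gaze direction samples: per-interval
angular distance (degrees), cumulative total angular distance, angular
velocity (degrees/s), and the saccade/fixation indicator produced by
velocity-threshold identification (I-VT).  Fixations are runs of
consecutive intervals with point-to-point velocity strictly below the
threshold; saccades are runs at or above it.  Fixation runs shorter than
the minimum fixation duration are relabelled "undefined" and excluded
from the event list.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .features import FeatureSeries
from .io import ChallengeRecord

FIXATION = "fixation"
SACCADE = "saccade"
UNDEFINED = "undefined"


@dataclasses.dataclass(frozen=True)
class IvtConfig:
    """I-VT parameters: velocity threshold (deg/s) and minimum fixation
    duration (s)."""

    velocity_threshold: float = 100.0
    min_fixation_duration: float = 0.070

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0 or self.min_fixation_duration <= 0:
            raise ValueError("I-VT parameters must be strictly positive")


def angular_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two gaze direction vectors, in degrees.

    arccos of the normalised dot product, clamped to [0, 180]; symmetric
    in its arguments.  Zero vectors are rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angular_distance requires nonzero vectors")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _interval_angles(dirs: np.ndarray) -> np.ndarray:
    """Angular distance (degrees) between consecutive rows of unit vectors."""
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms == 0):
        raise ValueError("gaze contains a zero direction vector")
    unit = dirs / norms[:, None]
    cos = np.clip(np.sum(unit[:-1] * unit[1:], axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def gaze_kinematics(gaze: pd.DataFrame) -> pd.DataFrame:
    """Per-interval angular kinematics of a gaze trace.

    Returns one row per consecutive-sample interval with columns
    ``t_start``, ``t_end``, ``t`` (interval midpoint), ``angular_distance``,
    ``angular_velocity`` and the running ``total_angular_distance``.
    """
    if len(gaze) < 2:
        raise ValueError("gaze kinematics require at least 2 samples")
    t = gaze["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"non-increasing gaze timestamp at row {row}")
    dirs = gaze[["dx", "dy", "dz"]].to_numpy(dtype=float)
    alpha = _interval_angles(dirs)
    return pd.DataFrame(
        {
            "t_start": t[:-1],
            "t_end": t[1:],
            "t": 0.5 * (t[:-1] + t[1:]),
            "angular_distance": alpha,
            "angular_velocity": alpha / dt,
            "total_angular_distance": np.cumsum(np.abs(alpha)),
        }
    )


def ivt_classify(
    kinematics: pd.DataFrame, config: IvtConfig = IvtConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label intervals as fixation/saccade/undefined and list merged events.

    An interval with velocity >= threshold is a saccade interval (a
    velocity exactly at the threshold is not "below" it, hence not a
    fixation); consecutive same-label intervals merge into one event
    spanning [t_start of first, t_end of last].  Fixation events shorter
    than ``min_fixation_duration`` become "undefined": their intervals are
    relabelled and they are dropped from the event list without merging
    their flanking saccades.

    Returns (labelled kinematics copy, events frame with columns
    event, t_start, t_end, duration).
    """
    vel = kinematics["angular_velocity"].to_numpy(dtype=float)
    t_start = kinematics["t_start"].to_numpy(dtype=float)
    t_end = kinematics["t_end"].to_numpy(dtype=float)
    labels = np.where(vel >= config.velocity_threshold, SACCADE, FIXATION).astype(object)

    events = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        start, end = t_start[i], t_end[j]
        duration = end - start
        label = labels[i]
        if label == FIXATION and duration < config.min_fixation_duration:
            labels[i : j + 1] = UNDEFINED
        else:
            events.append((label, start, end, duration))
        i = j + 1

    out = kinematics.copy()
    out["event_label"] = labels
    events_df = pd.DataFrame(
        events, columns=["event", "t_start", "t_end", "duration"]
    )
    return out, events_df


def gaze_features(
    challenge: ChallengeRecord, config: IvtConfig = IvtConfig()
) -> dict[str, FeatureSeries]:
    """The four per-interval eye-tracking feature series of a challenge.

    The saccade indicator is 1 for saccade intervals, 0 for fixations and
    NaN for undefined intervals (treated as missing downstream).  An empty
    or single-sample gaze stream yields empty series.
    """
    names = (
        "angular_distance",
        "total_angular_distance",
        "angular_velocity",
        "saccade",
    )
    if len(challenge.gaze) < 2:
        empty = np.empty(0)
        return {n: FeatureSeries(n, empty, empty) for n in names}
    kin, _ = ivt_classify(gaze_kinematics(challenge.gaze), config)
    t = kin["t"].to_numpy()
    label = kin["event_label"].to_numpy()
    saccade = np.where(
        label == SACCADE, 1.0, np.where(label == FIXATION, 0.0, np.nan)
    )
    return {
        "angular_distance": FeatureSeries(
            "angular_distance", t, kin["angular_distance"].to_numpy()
        ),
        "total_angular_distance": FeatureSeries(
            "total_angular_distance", t, kin["total_angular_distance"].to_numpy()
        ),
        "angular_velocity": FeatureSeries(
            "angular_velocity", t, kin["angular_velocity"].to_numpy()
        ),
        "saccade": FeatureSeries("saccade", t, saccade),
    }
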