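"""Domain types and on-disk session I/O.

A cohort lives in one directory::

    cohort/
      participants.csv          # participant_id, age, sex, <measure columns>
      norms.csv                 # measure, sex, age_lo, age_hi, mean, sd
      <participant_id>/
        challenges.csv          # game, challenge_index, duration
        rocket_01/ ... rocket_11/
        connect_01/ ... connect_06/
          gaze.csv              # t, dx, dy, dz
          touch.csv             # gesture_id, t, x, y
          emotion.csv           # t, anger, ..., surprise

All CSVs are comma-separated UTF-8 with a mandatory header row and '.'
decimal separator.  Timestamps are seconds from challenge start.  Gaze is
stored as unit direction vectors in camera coordinates; touch coordinates
are screen pixels with the origin at the top-left corner, y growing
downward.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .registry import (
    AGE_RANGE,
    EMOTIONS,
    GAME_CHALLENGES,
    MEASURES,
    SEXES,
)

logger = logging.getLogger("tabletbio")

GAZE_COLUMNS = ("t", "dx", "dy", "dz")
TOUCH_COLUMNS = ("gesture_id", "t", "x", "y")
EMOTION_COLUMNS = ("t",) + EMOTIONS

#: fixed float format for every table writer, so identical data yields
#: byte-identical files
FLOAT_FORMAT = "%.17g"


class SessionError(ValueError):
    """A session file violates the documented contract."""


class GazeSample(NamedTuple):
    """One gaze frame: time (s) and unit direction 3-vector."""

    t: float
    direction: np.ndarray


class EmotionFrame(NamedTuple):
    """One video frame's 7-class emotion probability vector."""

    t: float
    probs: np.ndarray


@dataclasses.dataclass
class TouchGesture:
    """One touch gesture: an ordered (t, x, y) polyline in screen pixels."""

    gesture_id: str
    points: np.ndarray  # shape (n, 3): t, x, y

    def validate(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise SessionError(
                f"gesture {self.gesture_id}: expected (n, 3) points with n >= 1"
            )
        if not np.isfinite(pts[:, 1:]).all():
            raise SessionError(f"gesture {self.gesture_id}: non-finite coordinates")
        if np.any(np.diff(pts[:, 0]) < 0):
            row = int(np.argmax(np.diff(pts[:, 0]) < 0)) + 1
            raise SessionError(
                f"gesture {self.gesture_id}: decreasing timestamp at point {row}"
            )
        self.points = pts


@dataclasses.dataclass
class ChallengeRecord:
    """All raw streams of one challenge of one game for one participant.

    ``gaze`` has columns t, dx, dy, dz; ``emotions`` has t plus the seven
    emotion columns.  ``duration`` is the challenge length in seconds and
    bounds every stream timestamp.
    """

    participant_id: str
    game: str
    challenge_index: int
    gaze: pd.DataFrame
    touches: list[TouchGesture]
    emotions: pd.DataFrame
    duration: float

    def validate(self) -> None:
        if self.game not in GAME_CHALLENGES:
            raise SessionError(f"unknown game {self.game!r}")
        n_max = GAME_CHALLENGES[self.game]
        if not 1 <= self.challenge_index <= n_max:
            raise SessionError(
                f"{self.game} challenge_index {self.challenge_index} outside [1, {n_max}]"
            )
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise SessionError(
                f"{self.key()}: duration must be positive, got {self.duration}"
            )
        self.gaze = validate_gaze(self.gaze, where=f"{self.key()} gaze")
        for g in self.touches:
            g.validate()
        self.emotions = validate_emotions(self.emotions, where=f"{self.key()} emotion")
        for name, t in (
            ("gaze", self.gaze["t"].to_numpy()),
            ("emotion", self.emotions["t"].to_numpy()),
            ("touch", np.concatenate([g.points[:, 0] for g in self.touches])
             if self.touches else np.empty(0)),
        ):
            if t.size and (t.min() < 0 or t.max() > self.duration + 1e-9):
                raise SessionError(
                    f"{self.key()}: {name} timestamps outside [0, duration]"
                )

    def key(self) -> tuple[str, str, int]:
        return (self.participant_id, self.game, self.challenge_index)


@dataclasses.dataclass
class ParticipantRecord:
    """Participant metadata and raw assessment scores."""

    participant_id: str
    age: float
    sex: str
    raw_scores: dict[str, float]

    def validate(self) -> None:
        lo, hi = AGE_RANGE
        if not lo <= self.age <= hi:
            raise SessionError(
                f"participant {self.participant_id}: age {self.age} outside [{lo}, {hi}]"
            )
        if self.sex not in SEXES:
            raise SessionError(
                f"participant {self.participant_id}: sex must be one of {SEXES}"
            )
        unknown = set(self.raw_scores) - set(MEASURES)
        if unknown:
            raise SessionError(
                f"participant {self.participant_id}: unknown measures {sorted(unknown)}"
            )


class NormativeTable:
    """Age-band x sex normative means/sds per measure, for z-adjustment.

    Backed by a DataFrame with columns measure, sex, age_lo, age_hi, mean,
    sd.  Age bands are half-open [age_lo, age_hi) except the last band of
    each (measure, sex), which includes its upper edge, and must partition
    the covered age range without overlap.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"measure", "sex", "age_lo", "age_hi", "mean", "sd"}
        missing = required - set(table.columns)
        if missing:
            raise SessionError(f"norms table missing columns {sorted(missing)}")
        if (table["sd"] <= 0).any():
            bad = table.loc[table["sd"] <= 0].iloc[0]
            raise SessionError(
                f"norms: sd must be > 0, got {bad['sd']} for "
                f"({bad['measure']}, {bad['sex']})"
            )
        self.table = table.sort_values(
            ["measure", "sex", "age_lo"], kind="mergesort"
        ).reset_index(drop=True)
        for (measure, sex), grp in self.table.groupby(["measure", "sex"]):
            lo = grp["age_lo"].to_numpy()
            hi = grp["age_hi"].to_numpy()
            if np.any(hi <= lo) or np.any(lo[1:] != hi[:-1]):
                raise SessionError(
                    f"norms: age bands for ({measure}, {sex}) overlap or leave gaps"
                )

    def lookup(self, measure: str, sex: str, age: float) -> tuple[float, float]:
        """Return (mean, sd) of the band containing *age*; error if uncovered."""
        grp = self.table[(self.table["measure"] == measure) & (self.table["sex"] == sex)]
        if len(grp):
            inside = (grp["age_lo"] <= age) & (
                (age < grp["age_hi"]) | (grp["age_hi"] == grp["age_hi"].max())
                & (age <= grp["age_hi"])
            )
            if inside.any():
                row = grp.loc[inside].iloc[0]
                return float(row["mean"]), float(row["sd"])
        raise SessionError(
            f"no normative cell for measure={measure!r}, sex={sex!r}, age={age}"
        )


@dataclasses.dataclass
class Cohort:
    """A fully loaded cohort: participants, norms, and all challenges."""

    participants: list[ParticipantRecord]
    norms: NormativeTable | None
    challenges: list[ChallengeRecord]

    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]


# ---------------------------------------------------------------------------
# stream validation


def validate_gaze(gaze: pd.DataFrame, where: str = "gaze") -> pd.DataFrame:
    """Check timestamps and renormalise near-unit direction vectors.

    Vectors within 1e-3 of unit length are renormalised; anything further
    off is rejected.  Timestamps must be non-negative and strictly
    increasing.
    """
    gaze = gaze.reset_index(drop=True)
    missing = set(GAZE_COLUMNS) - set(gaze.columns)
    if missing:
        raise SessionError(f"{where}: missing columns {sorted(missing)}")
    if len(gaze) == 0:
        return gaze
    t = gaze["t"].to_numpy(dtype=float)
    if t[0] < 0:
        raise SessionError(f"{where}: negative timestamp at row 0")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise SessionError(f"{where}: non-increasing timestamp at row {row}")
    dirs = gaze[["dx", "dy", "dz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(dirs, axis=1)
    off = np.abs(norms - 1.0)
    if np.any(off > 1e-3):
        row = int(np.argmax(off > 1e-3))
        raise SessionError(
            f"{where}: direction at row {row} has norm {norms[row]:.6f}, "
            "more than 1e-3 from unit length"
        )
    if np.any(off > 1e-6):
        dirs = dirs / norms[:, None]
        gaze = gaze.copy()
        gaze[["dx", "dy", "dz"]] = dirs
    return gaze


def validate_emotions(em: pd.DataFrame, where: str = "emotion") -> pd.DataFrame:
    em = em.reset_index(drop=True)
    missing = set(EMOTION_COLUMNS) - set(em.columns)
    if missing:
        raise SessionError(f"{where}: missing columns {sorted(missing)}")
    if len(em) == 0:
        return em
    t = em["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 1
        raise SessionError(f"{where}: non-increasing timestamp at row {row}")
    probs = em[list(EMOTIONS)].to_numpy(dtype=float)
    bad = (probs < -1e-6) | (probs > 1 + 1e-6)
    if bad.any():
        row = int(np.argmax(bad.any(axis=1)))
        raise SessionError(
            f"{where}: probability outside [0, 1] at frame {row}"
        )
    return em


# ---------------------------------------------------------------------------
# readers


def _challenge_dir(game: str, index: int) -> str:
    return f"{game.lower()}_{index:02d}"


def read_session(path: str | Path) -> list[ChallengeRecord]:
    """Read every challenge under a cohort root (or one participant directory).

    Returns challenges sorted by (participant_id, game, challenge_index),
    with all type invariants validated.  An empty stream file yields an
    empty stream with a logged warning; a missing stream file is a hard
    error.
    """
    path = Path(path)
    if not path.is_dir():
        raise SessionError(f"session path {path} is not a directory")
    if (path / "challenges.csv").exists():
        participant_dirs = [path]
    else:
        participant_dirs = sorted(
            p for p in path.iterdir()
            if p.is_dir() and (p / "challenges.csv").exists()
        )
        if not participant_dirs:
            raise SessionError(f"no participant directories under {path}")
    records: list[ChallengeRecord] = []
    for pdir in participant_dirs:
        manifest = pd.read_csv(pdir / "challenges.csv")
        for _, row in manifest.iterrows():
            game = str(row["game"])
            idx = int(row["challenge_index"])
            cdir = pdir / _challenge_dir(game, idx)
            streams = {}
            for stream, cols in (
                ("gaze", GAZE_COLUMNS),
                ("touch", TOUCH_COLUMNS),
                ("emotion", EMOTION_COLUMNS),
            ):
                f = cdir / f"{stream}.csv"
                if not f.exists():
                    raise SessionError(f"missing stream file: {f}")
                df = pd.read_csv(f)
                if len(df) == 0:
                    logger.warning("empty %s stream in %s", stream, cdir)
                streams[stream] = df
            touches = [
                TouchGesture(gesture_id=str(gid), points=g[["t", "x", "y"]].to_numpy(float))
                for gid, g in streams["touch"].groupby("gesture_id", sort=True)
            ]
            rec = ChallengeRecord(
                participant_id=pdir.name,
                game=game,
                challenge_index=idx,
                gaze=streams["gaze"],
                touches=touches,
                emotions=streams["emotion"],
                duration=float(row["duration"]),
            )
            rec.validate()
            records.append(rec)
    records.sort(key=lambda r: r.key())
    return records


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    df = pd.read_csv(path)
    out = []
    measure_cols = [c for c in df.columns if c in MEASURES]
    for _, row in df.iterrows():
        rec = ParticipantRecord(
            participant_id=str(row["participant_id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            raw_scores={
                m: float(row[m]) for m in measure_cols if pd.notna(row[m])
            },
        )
        rec.validate()
        out.append(rec)
    return out


def read_norms(path: str | Path) -> NormativeTable:
    return NormativeTable(pd.read_csv(path))


def read_cohort(path: str | Path) -> Cohort:
    """Load a full cohort directory: participants, norms (optional), streams."""
    path = Path(path)
    participants = read_participants(path / "participants.csv")
    norms_file = path / "norms.csv"
    norms = read_norms(norms_file) if norms_file.exists() else None
    return Cohort(
        participants=participants,
        norms=norms,
        challenges=read_session(path),
    )


# ---------------------------------------------------------------------------
# writers


def write_table(
    rows: pd.DataFrame,
    path: str | Path,
    allow_empty: bool = False,
    index: bool = False,
) -> None:
    """Write any tabular result as CSV; round-trips losslessly via read_csv."""
    if len(rows) == 0 and not allow_empty:
        raise SessionError(f"refusing to write empty table to {path}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def write_participants(participants: Iterable[ParticipantRecord], path: str | Path) -> None:
    rows = []
    for p in participants:
        row = {"participant_id": p.participant_id, "age": p.age, "sex": p.sex}
        row.update({m: p.raw_scores.get(m, np.nan) for m in MEASURES})
        rows.append(row)
    write_table(pd.DataFrame(rows), path)


def write_challenge(rec: ChallengeRecord, participant_dir: str | Path) -> None:
    cdir = Path(participant_dir) / _challenge_dir(rec.game, rec.challenge_index)
    cdir.mkdir(parents=True, exist_ok=True)
    write_table(rec.gaze[list(GAZE_COLUMNS)], cdir / "gaze.csv", allow_empty=True)
    if rec.touches:
        touch = pd.concat(
            [
                pd.DataFrame(
                    {
                        "gesture_id": g.gesture_id,
                        "t": g.points[:, 0],
                        "x": g.points[:, 1],
                        "y": g.points[:, 2],
                    }
                )
                for g in rec.touches
            ],
            ignore_index=True,
        )
    else:
        touch = pd.DataFrame(columns=list(TOUCH_COLUMNS))
    write_table(touch, cdir / "touch.csv", allow_empty=True)
    write_table(rec.emotions[list(EMOTION_COLUMNS)], cdir / "emotion.csv", allow_empty=True)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the canonical directory layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_participants(cohort.participants, path / "participants.csv")
    if cohort.norms is not None:
        write_table(cohort.norms.table, path / "norms.csv")
    by_participant: dict[str, list[ChallengeRecord]] = {}
    for rec in cohort.challenges:
        by_participant.setdefault(rec.participant_id, []).append(rec)
    for pid, recs in by_participant.items():
        pdir = path / pid
        pdir.mkdir(exist_ok=True)
        manifest = pd.DataFrame(
            {
                "game": [r.game for r in recs],
                "challenge_index": [r.challenge_index for r in recs],
                "duration": [r.duration for r in recs],
            }
        ).sort_values(["game", "challenge_index"])
        write_table(manifest, pdir / "challenges.csv")
        for rec in recs:
            write_challenge(rec, pdir)
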