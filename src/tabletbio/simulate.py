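"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates tablet sessions: gaze traces alternating fixation
segments (small-amplitude jitter, velocity far below the I-VT threshold)
with ballistic saccades following a raised-cosine velocity profile; touch
gestures as smoothed random polylines; per-frame emotion probability
vectors drawn from a Dirichlet whose concentration drifts with a latent
arousal factor; and raw assessment scores built as the age/sex normative
mean plus a linear combination of per-participant latent session factors
plus Gaussian noise.  Per-challenge random shifts perturb the stream
intensities, giving the mixed-model stage a true challenge effect.

Ground truth (latent factors, challenge effects, generating coefficients,
per-challenge saccade counts) is stored alongside every simulated cohort
and is never consumed by the pipeline itself.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ChallengeRecord,
    Cohort,
    NormativeTable,
    ParticipantRecord,
    TouchGesture,
    write_cohort,
)
from .registry import EMOTIONS, GAME_CHALLENGES, GAMES, MEASURES, SEXES

N_LATENTS = 3  # oculomotor, motor, arousal

#: age bands of the synthetic normative table, partitioning [7, 15]
AGE_BANDS: tuple[tuple[float, float], ...] = ((7, 9), (9, 11), (11, 13), (13, 15))


def default_loadings() -> dict[str, tuple[float, float, float]]:
    """Default linear dependence of each measure on the three latent
    session factors (oculomotor, motor, arousal); unlisted measures load
    on nothing."""
    zero = (0.0, 0.0, 0.0)
    table: dict[str, tuple[float, float, float]] = {m: zero for m in MEASURES}
    table.update(
        {
            "digit_span": (0.8, 0.0, 0.0),
            "letter_number_sequencing": (0.7, 0.0, 0.1),
            "coding": (0.0, 0.8, 0.0),
            "symbol_search": (0.0, 0.7, 0.0),
            "cancellation": (0.0, 0.6, 0.0),
            "block_design": (0.4, 0.3, 0.0),
            "inattention": (0.3, 0.0, 0.3),
            "achievement": (0.2, 0.0, 0.2),
            "social_problems": (0.0, 0.0, 0.5),
        }
    )
    return table


@dataclasses.dataclass
class SimulationConfig:
    """Generator parameters; the defaults are the study conditions.

    ``n_participants`` and ``n_reference`` default to the analysed cohort
    (24 children) and the internal PCA reference cohort (63 children).
    Rates are the tablet's: ~28 video frames/s for gaze and emotion,
    ~100 Hz touch sampling.  ``saccade_peak_velocity`` (deg/s) must exceed
    the downstream I-VT threshold so saccades are detectable.
    """

    n_participants: int = 24
    n_reference: int = 63
    seed: int = 0
    gaze_rate: float = 28.0
    touch_rate: float = 100.0
    fixation_dwell: float = 0.4  # mean fixation duration, s
    fixation_jitter: float = 0.03  # per-sample fixation wander, deg
    saccade_amplitude: float = 10.0  # mean saccade amplitude, deg
    saccade_amplitude_sd: float = 1.0  # amplitude spread; 0 = deterministic
    saccade_peak_velocity: float = 300.0  # raised-cosine peak, deg/s
    gesture_rate: float = 0.25  # touch gestures per second
    touch_speed: float = 600.0  # mean gesture speed, px/s
    screen: tuple[int, int] = (1920, 1200)  # px
    rocket_duration: float = 15.0  # s per Rocket challenge
    connect_duration: float = 25.0  # s per Connect challenge
    emotion_concentration: float = 1.0
    latent_loadings: dict[str, tuple[float, float, float]] = dataclasses.field(
        default_factory=default_loadings
    )
    noise_sd: float = 0.6  # residual sd of z-scale scores
    challenge_effect_sd: float = 0.5  # sd of per-challenge stream shifts

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if min(self.gaze_rate, self.touch_rate) <= 0:
            raise ValueError("sampling rates must be positive")
        if min(self.rocket_duration, self.connect_duration) <= 0:
            raise ValueError("challenge durations must be positive")

    def duration(self, game: str) -> float:
        return self.rocket_duration if game == "Rocket" else self.connect_duration


@dataclasses.dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    latents: pd.DataFrame  # index participant_id, columns factor names
    challenge_effects: dict[str, float]  # "game:index" -> shift
    loadings: dict[str, tuple[float, float, float]]
    saccade_counts: dict[str, int]  # "pid:game:index" -> segments generated
    noise_sd: float

    def save(self, path: str | Path) -> None:
        payload = {
            "latents": {
                pid: [float(v) for v in row]
                for pid, row in self.latents.iterrows()
            },
            "challenge_effects": self.challenge_effects,
            "loadings": {k: list(v) for k, v in self.loadings.items()},
            "saccade_counts": self.saccade_counts,
            "noise_sd": self.noise_sd,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# stream generators


def _angles_to_unit(theta: np.ndarray) -> np.ndarray:
    """Map (azimuth, elevation) in degrees to unit direction vectors."""
    ax = np.radians(theta[:, 0])
    el = np.radians(theta[:, 1])
    return np.column_stack(
        [np.sin(ax) * np.cos(el), np.sin(el), np.cos(ax) * np.cos(el)]
    )


def simulate_gaze(
    rng: np.random.Generator, duration: float, cfg: SimulationConfig, activity: float = 0.0
) -> tuple[pd.DataFrame, int]:
    """One gaze trace: alternating fixations and raised-cosine saccades.

    ``activity`` shortens fixation dwell (more saccades for higher
    values).  Returns the gaze frame (t, dx, dy, dz) and the number of
    complete saccade segments generated — the oracle for I-VT recovery on
    noise-free traces.

    Sampling at the gaze rate bounds what I-VT can see: however fast the
    underlying profile, a sample landing mid-saccade halves the
    point-to-point displacement, so only amplitudes of at least
    2 * threshold / gaze_rate (about 7.2 deg at 100 deg/s and 28 Hz) are
    guaranteed detectable.  With ``saccade_amplitude_sd`` 0 and the
    default amplitude every saccade is above that bound.
    """
    dwell = max(0.15, cfg.fixation_dwell * np.exp(-0.3 * activity))
    # segment schedule: (t0, t1, is_saccade, theta0, theta1)
    segments: list[tuple[float, float, bool, np.ndarray, np.ndarray]] = []
    t_cur = 0.0
    theta = np.zeros(2)
    n_saccades = 0
    while t_cur < duration:
        fdur = max(0.15, rng.exponential(dwell))
        t1 = min(t_cur + fdur, duration)
        segments.append((t_cur, t1, False, theta.copy(), theta.copy()))
        t_cur = t1
        if t_cur >= duration:
            break
        if cfg.saccade_amplitude_sd > 0:
            k = (cfg.saccade_amplitude / cfg.saccade_amplitude_sd) ** 2
            amp = max(2.0, rng.gamma(k, cfg.saccade_amplitude / k))
        else:
            amp = cfg.saccade_amplitude
        sdur = 2.0 * amp / cfg.saccade_peak_velocity
        if t_cur + sdur + 0.15 > duration:
            break  # keep the trace ending on a fixation
        heading = rng.uniform(0, 2 * np.pi)
        target = theta + amp * np.array([np.cos(heading), np.sin(heading)])
        if np.linalg.norm(target) > 15.0:  # steer back toward centre
            target = theta - amp * (theta / max(np.linalg.norm(theta), 1e-9))
        segments.append((t_cur, t_cur + sdur, True, theta.copy(), target.copy()))
        n_saccades += 1
        theta = target
        t_cur += sdur

    times = np.arange(0.0, duration + 1e-9, 1.0 / cfg.gaze_rate)
    times = times[times <= duration]
    starts = np.array([s[0] for s in segments])
    seg_idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(segments) - 1)
    pos = np.empty((len(times), 2))
    for i, (si, t) in enumerate(zip(seg_idx, times)):
        t0, t1, is_sac, th0, th1 = segments[si]
        if is_sac and t1 > t0:
            u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
            frac = u - np.sin(2 * np.pi * u) / (2 * np.pi)  # raised-cosine displacement
            pos[i] = th0 + frac * (th1 - th0)
        else:
            pos[i] = th0
    # smooth fixation wander, far below the velocity threshold
    jitter = np.cumsum(rng.normal(0.0, cfg.fixation_jitter, size=pos.shape), axis=0)
    jitter -= jitter.mean(axis=0)
    in_saccade = np.array([segments[si][2] for si in seg_idx])
    pos = pos + np.where(in_saccade[:, None], 0.0, jitter)
    dirs = _angles_to_unit(pos)
    return (
        pd.DataFrame(
            {"t": times, "dx": dirs[:, 0], "dy": dirs[:, 1], "dz": dirs[:, 2]}
        ),
        n_saccades,
    )


def simulate_touches(
    rng: np.random.Generator, duration: float, cfg: SimulationConfig, activity: float = 0.0
) -> list[TouchGesture]:
    """Touch gestures as smoothed random polylines at the touch rate."""
    n = 1 + rng.poisson(cfg.gesture_rate * duration)
    speed = cfg.touch_speed * np.exp(0.25 * activity)
    w, h = cfg.screen
    gestures = []
    starts = np.sort(rng.uniform(0.0, max(duration - 1.0, 0.1), size=n))
    for k, start in enumerate(starts):
        gdur = rng.uniform(0.2, min(0.9, duration - start))
        npts = max(2, int(round(gdur * cfg.touch_rate)))
        t = start + np.linspace(0.0, gdur, npts)
        heading = rng.uniform(0, 2 * np.pi) + np.cumsum(
            rng.normal(0.0, 0.25, size=npts)
        )
        step = speed / cfg.touch_rate
        dx = np.cos(heading) * step
        dy = np.sin(heading) * step
        x = np.clip(rng.uniform(0.15 * w, 0.85 * w) + np.cumsum(dx), 0, w)
        y = np.clip(rng.uniform(0.15 * h, 0.85 * h) + np.cumsum(dy), 0, h)
        gestures.append(
            TouchGesture(
                gesture_id=f"g{k + 1:03d}", points=np.column_stack([t, x, y])
            )
        )
    return gestures


#: baseline Dirichlet concentration, neutral-dominated
_EMOTION_ALPHA = np.array([1.0, 0.8, 0.8, 2.5, 8.0, 1.0, 1.2])
#: how arousal tilts each emotion's concentration
_AROUSAL_TILT = np.array([0.2, 0.0, 0.0, 0.5, -0.6, 0.0, 0.5])


def simulate_emotions(
    rng: np.random.Generator, duration: float, cfg: SimulationConfig, arousal: float = 0.0
) -> pd.DataFrame:
    """Per-frame 7-class emotion simplices from an arousal-tilted Dirichlet."""
    times = np.arange(0.0, duration + 1e-9, 1.0 / cfg.gaze_rate)
    times = times[times <= duration]
    alpha = cfg.emotion_concentration * _EMOTION_ALPHA * np.exp(
        _AROUSAL_TILT * arousal * 0.4
    )
    probs = rng.dirichlet(alpha, size=len(times))
    out = pd.DataFrame(probs, columns=list(EMOTIONS))
    out.insert(0, "t", times)
    return out


# ---------------------------------------------------------------------------
# norms and scores


def simulate_norms(config: SimulationConfig) -> NormativeTable:
    """Synthetic normative table: smooth, monotone-in-age means per
    measure, sd > 0 in every cell, small sex offsets."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    rows = []
    for m in MEASURES:
        base = rng.uniform(20.0, 60.0)
        slope = rng.uniform(1.0, 4.0)  # raw-score points per year: monotone in age
        sd = rng.uniform(4.0, 10.0)
        sex_off = rng.uniform(-1.0, 1.0)
        for sex in SEXES:
            for lo, hi in AGE_BANDS:
                mid = 0.5 * (lo + hi)
                rows.append(
                    {
                        "measure": m,
                        "sex": sex,
                        "age_lo": float(lo),
                        "age_hi": float(hi),
                        "mean": base + slope * (mid - 7.0)
                        + (sex_off if sex == "boy" else 0.0),
                        "sd": sd,
                    }
                )
    return NormativeTable(pd.DataFrame(rows))


def _simulate_participants(
    rng: np.random.Generator,
    n: int,
    prefix: str,
    norms: NormativeTable,
    config: SimulationConfig,
) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Participants with latent factors and raw scores generated on the
    raw scale (normative mean + sd * (loadings . latents + noise))."""
    latents = rng.standard_normal((n, N_LATENTS))
    participants = []
    for i in range(n):
        pid = f"{prefix}{i + 1:03d}"
        age = float(np.clip(rng.normal(10.5, 1.7), 7.0, 12.9))
        sex = SEXES[int(rng.integers(0, 2))]
        raw = {}
        for m in MEASURES:
            load = np.asarray(config.latent_loadings.get(m, (0.0, 0.0, 0.0)))
            z_true = float(load @ latents[i] + rng.normal(0.0, config.noise_sd))
            mean, sd = norms.lookup(m, sex, age)
            raw[m] = mean + sd * z_true
        participants.append(
            ParticipantRecord(participant_id=pid, age=age, sex=sex, raw_scores=raw)
        )
    lat_df = pd.DataFrame(
        latents,
        index=[p.participant_id for p in participants],
        columns=["oculomotor", "motor", "arousal"],
    )
    return participants, lat_df


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort_records(
    config: SimulationConfig, prefix: str = "p", seed_offset: int = 0
) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort in memory: participants, norms and all 11 Rocket
    + 6 Connect challenges per participant."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 11, seed_offset])
    )
    norms = simulate_norms(config)
    participants, latents = _simulate_participants(
        rng, config.n_participants, prefix, norms, config
    )
    challenge_effects = {
        f"{game}:{ci}": float(rng.normal(0.0, config.challenge_effect_sd))
        for game in GAMES
        for ci in range(1, GAME_CHALLENGES[game] + 1)
    }
    challenges = []
    saccade_counts: dict[str, int] = {}
    for p in participants:
        lat = latents.loc[p.participant_id]
        for game in GAMES:
            for ci in range(1, GAME_CHALLENGES[game] + 1):
                eff = challenge_effects[f"{game}:{ci}"]
                duration = config.duration(game)
                gaze, n_sac = simulate_gaze(
                    rng, duration, config, activity=lat["oculomotor"] + eff
                )
                touches = simulate_touches(
                    rng, duration, config, activity=lat["motor"] + eff
                )
                emotions = simulate_emotions(
                    rng, duration, config, arousal=lat["arousal"] + eff
                )
                rec = ChallengeRecord(
                    participant_id=p.participant_id,
                    game=game,
                    challenge_index=ci,
                    gaze=gaze,
                    touches=touches,
                    emotions=emotions,
                    duration=duration,
                )
                rec.validate()
                challenges.append(rec)
                saccade_counts[f"{p.participant_id}:{game}:{ci}"] = n_sac
    truth = GroundTruth(
        latents=latents,
        challenge_effects=challenge_effects,
        loadings=dict(config.latent_loadings),
        saccade_counts=saccade_counts,
        noise_sd=config.noise_sd,
    )
    return Cohort(participants=participants, norms=norms, challenges=challenges), truth


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path, prefix: str = "p",
    seed_offset: int = 0,
) -> tuple[Path, GroundTruth]:
    """Write a simulated cohort in the canonical on-disk layout, together
    with its ground_truth.json.  Same config and seed give byte-identical
    output."""
    cohort, truth = simulate_cohort_records(config, prefix=prefix, seed_offset=seed_offset)
    out_dir = Path(out_dir)
    write_cohort(cohort, out_dir)
    truth.save(out_dir / "ground_truth.json")
    return out_dir, truth


def simulate_study(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the analysis cohort and the PCA reference cohort side by side
    (out_dir/cohort with n_participants children, out_dir/reference with
    n_reference)."""
    out_dir = Path(out_dir)
    simulate_cohort(config, out_dir / "cohort", prefix="p")
    ref_cfg = dataclasses.replace(config, n_participants=config.n_reference)
    simulate_cohort(ref_cfg, out_dir / "reference", prefix="r", seed_offset=1)
    return out_dir / "cohort", out_dir / "reference"
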