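"""From feature series to biometric constructs.

Each challenge's feature series are optionally smoothed with a causal
moving average, averaged into 100 equal-width time bins, and stacked —
one row per (participant, challenge), columns feature-major over bins —
into a binned feature matrix per game and modality set.  A PCA is fitted
once on a reference cohort (column standardisation, then eigenvectors of
the top three components by explained variance); its eigenvectors and the
reference means/sds are then applied unchanged to any target cohort, so
target-cohort statistics never leak into the standardisation or the
components.  The three projected scores per row are the multimodal
biometric constructs MBC1-MBC3 (or their unimodal counterparts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .emotion import load_emotions
from .eye import IvtConfig, gaze_features
from .features import FeatureSeries
from .io import ChallengeRecord
from .registry import (
    CONSTRUCT_NAMES,
    GAME_CHALLENGES,
    MODALITY_FEATURES,
    N_BINS,
    N_COMPONENTS,
    matrix_columns,
)
from .touch import aggregate_touch

logger = logging.getLogger("tabletbio")

ROW_INDEX = ("participant_id", "game", "challenge_index")


def smooth_series(series: FeatureSeries, window: int) -> FeatureSeries:
    """Causal moving average over the last ``window`` observations.

    The average is shorter at the head of the series; window 1 is the
    identity.  Models the assumption that past feature values relate
    linearly to the current one.
    """
    if window < 1:
        raise ValueError("smoothing window must be >= 1")
    if window == 1 or len(series) == 0:
        return FeatureSeries(series.name, series.t.copy(), series.values.copy())
    v = series.values
    csum = np.cumsum(np.nan_to_num(v, nan=0.0))
    cnt = np.cumsum(np.isfinite(v).astype(float))
    out = np.empty_like(v)
    for i in range(len(v)):
        lo = max(0, i - window + 1)
        s = csum[i] - (csum[lo - 1] if lo > 0 else 0.0)
        c = cnt[i] - (cnt[lo - 1] if lo > 0 else 0.0)
        out[i] = s / c if c > 0 else np.nan
    return FeatureSeries(series.name, series.t.copy(), out)


def bin_series(
    series: FeatureSeries, duration: float, n_bins: int = N_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Average a feature series into equal-width time bins over [0, duration].

    Bins are half-open [lo, hi) except the final bin, which is closed.
    Empty interior bins are linearly interpolated between the nearest
    non-empty bins; leading/trailing empty bins carry the nearest
    non-empty value.  Returns (values, missing) where ``missing`` is all
    True only when the series has no finite observation.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    values = np.full(n_bins, np.nan)
    finite = np.isfinite(series.values)
    t = series.t[finite]
    v = series.values[finite]
    if len(t) == 0:
        return values, np.ones(n_bins, dtype=bool)
    idx = np.floor(t / duration * n_bins).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # closes the final bin at t == duration
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    filled = counts > 0
    values[filled] = sums[filled] / counts[filled]
    if not filled.all():
        pos = np.flatnonzero(filled)
        values = np.interp(np.arange(n_bins), pos, values[pos])
    return values, np.zeros(n_bins, dtype=bool)


@dataclasses.dataclass
class BinnedFeatureMatrix:
    """Rows = (participant, challenge) of one game; columns = feature x bin.

    ``missing`` marks cells whose feature series had no observation for
    the whole challenge (the PCA fit imputes them by reference column
    mean).
    """

    values: pd.DataFrame
    missing: pd.DataFrame
    game: str
    modality: str

    def __post_init__(self) -> None:
        expected = matrix_columns(self.modality, self.values.shape[1] // len(MODALITY_FEATURES[self.modality]))
        if list(self.values.columns) != expected:
            raise ValueError("binned matrix columns out of canonical order")


def challenge_features(
    challenge: ChallengeRecord,
    modality: str = "multimodal",
    ivt: IvtConfig = IvtConfig(),
    normalise_emotions: bool = False,
) -> dict[str, FeatureSeries]:
    """Extract the feature series of one challenge for a modality set."""
    feats: dict[str, FeatureSeries] = {}
    wanted = MODALITY_FEATURES[modality]
    if any(f in wanted for f in MODALITY_FEATURES["eye"]):
        feats.update(gaze_features(challenge, ivt))
    if any(f in wanted for f in MODALITY_FEATURES["touch"]):
        feats.update(aggregate_touch(challenge))
    if any(f in wanted for f in MODALITY_FEATURES["emotion"]):
        feats.update(load_emotions(challenge, normalise=normalise_emotions))
    return {name: feats[name] for name in wanted}


def assemble_matrix(
    challenges: list[ChallengeRecord],
    game: str,
    modality: str = "multimodal",
    n_bins: int = N_BINS,
    smooth_window: int = 1,
    ivt: IvtConfig = IvtConfig(),
    normalise_emotions: bool = False,
) -> BinnedFeatureMatrix:
    """Build the binned feature matrix of one game for a modality set.

    Every participant seen in ``challenges`` contributes one row per
    challenge index of the game; a missing challenge yields an all-missing
    row with a logged warning.  Row order is the canonical sort on
    (participant_id, game, challenge_index).
    """
    feats = MODALITY_FEATURES[modality]
    columns = matrix_columns(modality, n_bins)
    by_key = {c.key(): c for c in challenges if c.game == game}
    participants = sorted({c.participant_id for c in challenges})
    rows, masks, index = [], [], []
    for pid in participants:
        for ci in range(1, GAME_CHALLENGES[game] + 1):
            index.append((pid, game, ci))
            rec = by_key.get((pid, game, ci))
            if rec is None:
                logger.warning("participant %s missing %s challenge %d", pid, game, ci)
                rows.append(np.full(len(columns), np.nan))
                masks.append(np.ones(len(columns), dtype=bool))
                continue
            series = challenge_features(
                rec, modality, ivt=ivt, normalise_emotions=normalise_emotions
            )
            row = np.empty(len(columns))
            mask = np.empty(len(columns), dtype=bool)
            for i, f in enumerate(feats):
                s = smooth_series(series[f], smooth_window)
                vals, miss = bin_series(s, rec.duration, n_bins)
                row[i * n_bins : (i + 1) * n_bins] = vals
                mask[i * n_bins : (i + 1) * n_bins] = miss
            rows.append(row)
            masks.append(mask)
    mi = pd.MultiIndex.from_tuples(index, names=ROW_INDEX)
    return BinnedFeatureMatrix(
        values=pd.DataFrame(rows, index=mi, columns=columns),
        missing=pd.DataFrame(masks, index=mi, columns=columns),
        game=game,
        modality=modality,
    )


@dataclasses.dataclass
class ConstructModel:
    """A reference-fitted PCA: standardisation constants plus eigenvectors.

    ``columns`` are the retained matrix columns (zero-variance reference
    columns are dropped and recorded); ``components`` has one orthonormal
    eigenvector per row, signed so the largest-magnitude loading is
    positive.
    """

    game: str
    modality: str
    columns: list[str]
    dropped_columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    components: np.ndarray  # (n_components, n_columns)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def save(self, path: str | Path) -> None:
        payload = {
            "game": self.game,
            "modality": self.modality,
            "columns": self.columns,
            "dropped_columns": self.dropped_columns,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ConstructModel":
        d = json.loads(Path(path).read_text())
        return cls(
            game=d["game"],
            modality=d["modality"],
            columns=d["columns"],
            dropped_columns=d["dropped_columns"],
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            components=np.asarray(d["components"]),
            explained_variance=np.asarray(d["explained_variance"]),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
        )


@dataclasses.dataclass
class ConstructScores:
    """Per-row construct scores (MBC1-3), tagged by game and modality set."""

    scores: pd.DataFrame  # index = ROW_INDEX, columns = CONSTRUCT_NAMES
    game: str
    modality: str


def fit_reference(
    matrix: BinnedFeatureMatrix, n_components: int = N_COMPONENTS
) -> ConstructModel:
    """Fit the construct PCA on a reference cohort's binned matrix.

    Missing cells are imputed by column mean; columns are standardised to
    mean 0, sd 1 (zero-variance columns dropped and recorded); the top
    ``n_components`` eigenvectors by explained variance are retained with
    a deterministic sign convention.
    """
    X = matrix.values.to_numpy(dtype=float).copy()
    X[matrix.missing.to_numpy(dtype=bool)] = np.nan
    if X.shape[0] < n_components:
        raise ValueError(
            f"reference matrix has {X.shape[0]} rows; need >= {n_components}"
        )
    col_mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)  # all-missing column
    nan_mask = ~np.isfinite(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sds = X.std(axis=0, ddof=0)
    keep = sds > 1e-12
    dropped = [c for c, k in zip(matrix.values.columns, keep) if not k]
    columns = [c for c, k in zip(matrix.values.columns, keep) if k]
    Z = (X[:, keep] - col_mean[keep]) / sds[keep]
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Z)
    components = pca.components_.copy()
    for i in range(components.shape[0]):  # sign convention
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    return ConstructModel(
        game=matrix.game,
        modality=matrix.modality,
        columns=columns,
        dropped_columns=dropped,
        means=col_mean[keep],
        sds=sds[keep],
        components=components,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def project(model: ConstructModel, matrix: BinnedFeatureMatrix) -> ConstructScores:
    """Project a binned matrix onto the reference eigenvectors.

    Standardisation uses the REFERENCE means/sds, never the target
    cohort's; missing target cells fall back to the reference column mean.
    Matrix columns must match the model's retained columns exactly (in
    order, after dropping the recorded zero-variance columns).
    """
    cols = [c for c in matrix.values.columns if c not in set(model.dropped_columns)]
    if cols != model.columns:
        offending = sorted(set(cols).symmetric_difference(model.columns))
        raise ValueError(f"matrix columns do not match model columns: {offending[:10]}")
    X = matrix.values[model.columns].to_numpy(dtype=float).copy()
    X[matrix.missing[model.columns].to_numpy(dtype=bool)] = np.nan
    nan_mask = ~np.isfinite(X)
    X[nan_mask] = np.take(model.means, np.nonzero(nan_mask)[1])
    Z = (X - model.means) / model.sds
    scores = Z @ model.components.T
    names = list(CONSTRUCT_NAMES[: model.n_components])
    if model.n_components > len(CONSTRUCT_NAMES):
        names = [f"MBC{i + 1}" for i in range(model.n_components)]
    df = pd.DataFrame(scores, index=matrix.values.index, columns=names)
    return ConstructScores(scores=df, game=matrix.game, modality=matrix.modality)


def build_constructs(
    reference_challenges: list[ChallengeRecord],
    target_challenges: list[ChallengeRecord],
    game: str,
    modality: str = "multimodal",
    n_components: int = N_COMPONENTS,
    **matrix_kwargs,
) -> tuple[ConstructModel, ConstructScores]:
    """Fit the PCA on the reference cohort, project the target cohort."""
    ref = assemble_matrix(reference_challenges, game, modality, **matrix_kwargs)
    tgt = assemble_matrix(target_challenges, game, modality, **matrix_kwargs)
    model = fit_reference(ref, n_components=n_components)
    return model, project(model, tgt)


def write_matrix(matrix: BinnedFeatureMatrix, path: str | Path) -> None:
    """CSV round-trip for a binned matrix (missing cells become empty)."""
    vals = matrix.values.copy()
    vals[matrix.missing] = np.nan
    vals.to_csv(path, float_format="%.17g")


def read_matrix(path: str | Path, game: str, modality: str) -> BinnedFeatureMatrix:
    df = pd.read_csv(path, index_col=[0, 1, 2])
    df.index.names = ROW_INDEX
    return BinnedFeatureMatrix(
        values=df, missing=df.isna(), game=game, modality=modality
    )
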