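"""Multimodal vs unimodal model comparison by mean absolute error.

For each measure and game, one association model is fitted per modality
set (multimodal, eye, touch, emotion).  In-sample predictions use the
fixed effects plus the estimated per-challenge effects; the mean absolute
error (MAE) of each unimodal model is expressed as a percentage change
relative to the multimodal baseline, which is reported as 1.  Positive
percentages mean the unimodal model predicts worse than the multimodal
one.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .associations import _join_scores_target
from .constructs import ConstructScores
from .registry import MODALITIES

logger = logging.getLogger("tabletbio")


@dataclasses.dataclass
class FittedPredictor:
    """A fitted mixed model packaged for prediction on design rows."""

    fe_params: pd.Series
    challenge_effects: dict[int, float]
    component_names: list[str]

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Fixed-effect prediction plus the estimated effect of each row's
        challenge (0 for challenges unseen at fit time)."""
        X = sm.add_constant(rows[self.component_names], has_constant="add")
        pred = np.asarray(X @ self.fe_params)
        pred += rows["challenge_index"].map(
            lambda c: self.challenge_effects.get(int(c), 0.0)
        ).to_numpy()
        return pred


def fit_predictor(scores: ConstructScores, target: pd.Series) -> tuple[FittedPredictor, pd.DataFrame]:
    """REML mixed fit of target on the construct scores, returned with the
    design rows used."""
    df = _join_scores_target(scores, target)
    names = list(scores.scores.columns)
    exog = sm.add_constant(df[names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell"):
            try:
                fit = sm.MixedLM(df["y"], exog, groups=df["challenge_index"]).fit(
                    reml=True, method=method
                )
                effects = {
                    int(g): float(np.asarray(re).ravel()[0])
                    for g, re in fit.random_effects.items()
                }
                return FittedPredictor(fit.fe_params, effects, names), df
            except (np.linalg.LinAlgError, ValueError):
                continue
        # boundary fallback: no challenge effects
        ols = sm.OLS(df["y"], exog).fit()
    return FittedPredictor(ols.params, {}, names), df


def prediction_mae(predictor: FittedPredictor, rows: pd.DataFrame) -> float:
    """Mean absolute error of the predictor over evaluation rows.

    Rows must carry the component columns, ``challenge_index`` and the
    observed target ``y``.
    """
    if len(rows) == 0:
        raise ValueError("empty evaluation set")
    pred = predictor.predict(rows)
    return float(np.mean(np.abs(rows["y"].to_numpy() - pred)))


@dataclasses.dataclass
class ComparisonTable:
    """MAE per (measure, modality) with percent change vs the multimodal
    baseline; the baseline column is identically 1."""

    game: str
    mae: pd.DataFrame  # index measure, columns modality
    percent_change: pd.DataFrame  # unrounded; multimodal column = 0

    def report(self) -> pd.DataFrame:
        """Presentation table: baseline 1, unimodal integer percentages."""
        out = self.percent_change.round(0).astype(int).astype(str) + "%"
        out["multimodal"] = "1"
        return out[[c for c in MODALITIES if c in out.columns]]


def compare_modalities(
    scores_by_modality: dict[str, ConstructScores],
    adjusted: pd.DataFrame,
    measures: list[str] | None = None,
) -> ComparisonTable:
    """The MAE comparison across modality sets for one game.

    ``scores_by_modality`` maps each modality set to its construct scores
    (all from the same game, projected through reference-fitted PCAs).
    MAE is in-sample: each model is fitted and evaluated on the same
    cohort.  Percent change = 100 (MAE_unimodal - MAE_multimodal) /
    MAE_multimodal.
    """
    if "multimodal" not in scores_by_modality:
        raise ValueError("the multimodal modality set is the required baseline")
    games = {s.game for s in scores_by_modality.values()}
    if len(games) != 1:
        raise ValueError(f"scores mix games: {sorted(games)}")
    measures = measures or list(adjusted.columns)
    modalities = [m for m in MODALITIES if m in scores_by_modality]
    mae = pd.DataFrame(index=measures, columns=modalities, dtype=float)
    for modality in modalities:
        scores = scores_by_modality[modality]
        for measure in measures:
            try:
                predictor, rows = fit_predictor(scores, adjusted[measure])
            except ValueError as exc:
                logger.warning(
                    "compare_modalities: %s/%s skipped (%s)", modality, measure, exc
                )
                continue
            mae.loc[measure, modality] = prediction_mae(predictor, rows)
    base = mae["multimodal"]
    percent = 100.0 * mae.sub(base, axis=0).div(base, axis=0)
    mae.index.name = percent.index.name = "measure"
    return ComparisonTable(game=games.pop(), mae=mae, percent_change=percent)
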