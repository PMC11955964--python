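"""Associating biometric constructs with neuropsychological measures.

Raw assessment scores are z-adjusted for age and sex against a normative
table.  Each adjusted measure is then regressed on the three construct
scores with the game's challenges as a random intercept (linear mixed
model, REML) or, as a robustness check, with an M-estimated (Huber)
linear model in which challenges enter as fixed indicator terms.
P-values are corrected with the Holm-Bonferroni step-down rule within a
family of all (measure x component) tests of one game and model flavour;
Cohen's D effect sizes accompany each component via a median split of its
scores.  Sex-difference screening of participant characteristics uses
Student's t (Shapiro-Wilk normal at 0.05 in both groups), Mann-Whitney U
otherwise, and chi-squared for categorical variables.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .constructs import ConstructScores
from .io import NormativeTable, ParticipantRecord
from .registry import CONSTRUCT_NAMES, MEASURES

logger = logging.getLogger("tabletbio")


# ---------------------------------------------------------------------------
# z-adjustment


def z_adjust(
    participants: list[ParticipantRecord], norms: NormativeTable
) -> pd.DataFrame:
    """Age/sex-adjusted z-scores, one row per participant, one column per
    measure present in the raw scores.

    z = (raw - normative mean for the participant's age band and sex) /
    normative sd.  A missing normative cell is a hard error naming the
    (measure, sex, age band); a missing raw score propagates as NaN.
    """
    measures = sorted(
        {m for p in participants for m in p.raw_scores}, key=MEASURES.index
    )
    rows = {}
    for p in participants:
        row = {}
        for m in measures:
            raw = p.raw_scores.get(m)
            if raw is None:
                row[m] = np.nan
                continue
            mean, sd = norms.lookup(m, p.sex, p.age)
            row[m] = (raw - mean) / sd
        rows[p.participant_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")[measures]
    out.index.name = "participant_id"
    return out


# ---------------------------------------------------------------------------
# model fits


@dataclasses.dataclass
class AssociationResult:
    """One fitted target ~ constructs model and its per-component statistics."""

    game: str
    measure: str
    modality: str
    flavour: str  # "mixed" | "robust"
    estimates: dict[str, float]
    std_errors: dict[str, float]
    pvalues: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    random_effect_variance: float
    residual_variance: float
    log_likelihood: float
    r_squared: float
    singular: bool
    residuals_normal: bool
    residuals_homoscedastic: bool
    cohens_d: dict[str, float] = dataclasses.field(default_factory=dict)
    adjusted_pvalues: dict[str, float] = dataclasses.field(default_factory=dict)
    n_rows: int = 0


def _join_scores_target(
    scores: ConstructScores, target: pd.Series
) -> pd.DataFrame:
    """Join a target onto the score rows.

    ``target`` is either participant-level (indexed by participant_id,
    e.g. an adjusted measure) or row-level (indexed by the scores' own
    (participant, game, challenge) MultiIndex).
    """
    df = scores.scores.reset_index()
    if isinstance(target.index, pd.MultiIndex):
        df["y"] = target.reindex(scores.scores.index).to_numpy()
    else:
        df["y"] = df["participant_id"].map(target)
    df = df.dropna(subset=["y"] + list(scores.scores.columns))
    if df["challenge_index"].nunique() < 2:
        raise ValueError("need >= 2 challenges to fit")
    if df["participant_id"].nunique() < 2:
        raise ValueError("need >= 2 participants to fit")
    return df


def _diagnostics(resid: np.ndarray, fitted: np.ndarray) -> tuple[bool, bool]:
    """Normality (Shapiro-Wilk) and homoscedasticity (|resid| vs fitted
    Spearman) screens at alpha = 0.05."""
    normal = bool(stats.shapiro(resid).pvalue > 0.05) if len(resid) >= 3 else True
    if len(resid) >= 3 and np.std(fitted) > 0:
        rho = stats.spearmanr(np.abs(resid), fitted)
        homo = bool(rho.pvalue > 0.05)
    else:
        homo = True
    return normal, homo


def fit_mixed(
    scores: ConstructScores,
    target: pd.Series,
    measure: str | None = None,
) -> AssociationResult:
    """Linear mixed model: target ~ MBC1 + MBC2 + MBC3 with a random
    intercept per challenge, estimated by REML.

    ``target`` is an age/sex-adjusted measure indexed by participant_id.
    A singular fit (random-intercept variance at the boundary) is flagged
    and reported with variance 0, never raised.
    """
    df = _join_scores_target(scores, target)
    names = list(scores.scores.columns)
    exog = sm.add_constant(df[names])
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell"):
            try:
                model = sm.MixedLM(df["y"], exog, groups=df["challenge_index"])
                cand = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            wald_ok = all(
                np.isfinite(cand.bse[k]) and np.isfinite(cand.pvalues[k])
                for k in ["const"] + names
            )
            if wald_ok:
                fit = cand
                break
    if fit is None:
        # degenerate random-intercept likelihood: report the boundary fit
        ols = sm.OLS(df["y"], exog).fit()
        resid = np.asarray(ols.resid)
        normal, homo = _diagnostics(resid, np.asarray(ols.fittedvalues))
        ci = ols.conf_int()
        terms = ["const"] + names
        return AssociationResult(
            game=scores.game,
            measure=measure or target.name or "",
            modality=scores.modality,
            flavour="mixed",
            estimates={k: float(ols.params[k]) for k in terms},
            std_errors={k: float(ols.bse[k]) for k in terms},
            pvalues={k: float(ols.pvalues[k]) for k in terms},
            conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in terms},
            random_effect_variance=0.0,
            residual_variance=float(ols.scale),
            log_likelihood=float(ols.llf),
            r_squared=float(ols.rsquared),
            singular=True,
            residuals_normal=normal,
            residuals_homoscedastic=homo,
            cohens_d=_component_effect_sizes(df, names),
            n_rows=len(df),
        )
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    singular = re_var < 1e-8 * max(float(fit.scale), 1e-300)
    fixed_pred = np.asarray(exog @ fit.fe_params)
    resid = df["y"].to_numpy() - np.asarray(fit.fittedvalues)
    denom = np.var(df["y"].to_numpy())
    r2 = float(1 - np.var(resid) / denom) if denom > 0 else 0.0
    normal, homo = _diagnostics(resid, fixed_pred)
    terms = ["const"] + names
    # small-sample fixed-effect inference: t reference distribution with a
    # residual df approximation (rows - fixed effects - grouping levels),
    # rather than the asymptotic normal
    ddf = max(len(df) - len(terms) - df["challenge_index"].nunique(), 1)
    tcrit = stats.t.ppf(0.975, ddf)
    pvalues, conf_int = {}, {}
    for k in terms:
        est, se = float(fit.fe_params[k]), float(fit.bse[k])
        pvalues[k] = float(2 * stats.t.sf(abs(est / se), ddf)) if se > 0 else np.nan
        conf_int[k] = (est - tcrit * se, est + tcrit * se)
    return AssociationResult(
        game=scores.game,
        measure=measure or target.name or "",
        modality=scores.modality,
        flavour="mixed",
        estimates={k: float(fit.fe_params[k]) for k in terms},
        std_errors={k: float(fit.bse[k]) for k in terms},
        pvalues=pvalues,
        conf_int=conf_int,
        random_effect_variance=0.0 if singular else re_var,
        residual_variance=float(fit.scale),
        log_likelihood=float(fit.llf),
        r_squared=r2,
        singular=singular,
        residuals_normal=normal,
        residuals_homoscedastic=homo,
        cohens_d=_component_effect_sizes(df, names),
        n_rows=len(df),
    )


def fit_robust(
    scores: ConstructScores,
    target: pd.Series,
    measure: str | None = None,
) -> AssociationResult:
    """Huber M-estimated linear model of target on the constructs, with
    challenges as fixed indicator terms (robust mixed models are not
    standard; this approximates the random-intercept specification)."""
    df = _join_scores_target(scores, target)
    names = list(scores.scores.columns)
    dummies = pd.get_dummies(
        df["challenge_index"].astype("category"), prefix="ch", drop_first=True,
        dtype=float,
    )
    exog = sm.add_constant(pd.concat([df[names], dummies], axis=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.RLM(df["y"], exog, M=sm.robust.norms.HuberT()).fit()
    resid = np.asarray(fit.resid)
    fitted = np.asarray(fit.fittedvalues)
    denom = np.var(df["y"].to_numpy())
    r2 = float(1 - np.var(resid) / denom) if denom > 0 else 0.0
    normal, homo = _diagnostics(resid, fitted)
    ci = fit.conf_int()
    terms = ["const"] + names
    return AssociationResult(
        game=scores.game,
        measure=measure or target.name or "",
        modality=scores.modality,
        flavour="robust",
        estimates={k: float(fit.params[k]) for k in terms},
        std_errors={k: float(fit.bse[k]) for k in terms},
        pvalues={k: float(fit.pvalues[k]) for k in terms},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in terms},
        random_effect_variance=0.0,
        residual_variance=float(np.var(resid, ddof=exog.shape[1])),
        log_likelihood=float("nan"),
        r_squared=r2,
        singular=False,
        residuals_normal=normal,
        residuals_homoscedastic=homo,
        cohens_d=_component_effect_sizes(df, names),
        n_rows=len(df),
    )


def _component_effect_sizes(df: pd.DataFrame, names: list[str]) -> dict[str, float]:
    """Cohen's D of the target between rows above/below each component's
    median score."""
    out = {}
    y = df["y"].to_numpy()
    for name in names:
        s = df[name].to_numpy()
        hi, lo = y[s > np.median(s)], y[s <= np.median(s)]
        if len(hi) >= 2 and len(lo) >= 2:
            try:
                out[name] = cohens_d(hi, lo)
            except ValueError:
                out[name] = np.nan
        else:
            out[name] = np.nan
    return out


# ---------------------------------------------------------------------------
# multiple testing and effect sizes


def holm_bonferroni(
    pvalues: np.ndarray | list[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Bonferroni step-down adjustment.

    Sorted ascending, adjusted_(i) = max_{j <= i} min(1, (m - j + 1) p_(j));
    hypotheses are rejected while the adjusted value is <= alpha.
    Returns (adjusted p-values, reject flags), in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.isfinite(p).all()):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 0.0
    for rank, j in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[j]))
        adjusted[j] = running
    reject = np.zeros(m, dtype=bool)
    for rank, j in enumerate(order):
        if adjusted[j] <= alpha:
            reject[j] = True
        else:
            break
    return adjusted, reject


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Standardised mean difference (mean_a - mean_b) / pooled sd, pooled
    by degrees-of-freedom weighting."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------------------
# screening grids


def association_grid(
    scores: ConstructScores,
    adjusted: pd.DataFrame,
    measures: list[str] | None = None,
    flavour: str = "mixed",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[AssociationResult]]:
    """Fit one model per measure and Holm-correct the construct p-values.

    The multiple-testing family is all (measure x component) tests within
    this game and flavour.  Returns a long-format table with raw and
    adjusted p-values plus the per-fit results.
    """
    measures = measures or list(adjusted.columns)
    fitter = {"mixed": fit_mixed, "robust": fit_robust}[flavour]
    results = [fitter(scores, adjusted[m], measure=m) for m in measures]
    comp_names = [c for c in scores.scores.columns]
    keys, pvals = [], []
    for res in results:
        for c in comp_names:
            keys.append((res.measure, c))
            pvals.append(res.pvalues[c])
    pvals = np.asarray(pvals, dtype=float)
    finite = np.isfinite(pvals)
    if not finite.all():  # singular fits can yield undefined Wald p-values
        logger.warning(
            "association_grid: %d of %d p-values undefined; excluded from the "
            "Holm family", int((~finite).sum()), len(pvals),
        )
    adj, reject = holm_bonferroni(pvals[finite], alpha=alpha)
    adj_map = {k: (np.nan, False) for k in keys}
    for k, a, r in zip(np.array(keys, dtype=object)[finite], adj, reject):
        adj_map[tuple(k)] = (a, r)
    rows = []
    for res in results:
        res.adjusted_pvalues = {c: adj_map[(res.measure, c)][0] for c in comp_names}
        for c in comp_names:
            rows.append(
                {
                    "game": res.game,
                    "modality": res.modality,
                    "flavour": res.flavour,
                    "measure": res.measure,
                    "component": c,
                    "estimate": res.estimates[c],
                    "std_error": res.std_errors[c],
                    "pvalue": res.pvalues[c],
                    "pvalue_holm": adj_map[(res.measure, c)][0],
                    "reject": adj_map[(res.measure, c)][1],
                    "cohens_d": res.cohens_d[c],
                    "random_effect_variance": res.random_effect_variance,
                    "residual_variance": res.residual_variance,
                    "r_squared": res.r_squared,
                    "singular": res.singular,
                }
            )
    return pd.DataFrame(rows), results


def group_compare(
    participants: pd.DataFrame,
    by: str = "sex",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group comparison of participant characteristics.

    Continuous measures use Student's t when Shapiro-Wilk accepts
    normality in both groups (alpha 0.05), Mann-Whitney U otherwise;
    categorical variables use the chi-squared contingency test.  Groups
    of size < 2 (or single-level categoricals) are skipped with a warning.
    """
    levels = participants[by].dropna().unique()
    if len(levels) != 2:
        raise ValueError(f"grouping column {by!r} must have exactly 2 levels")
    g0 = participants[participants[by] == levels[0]]
    g1 = participants[participants[by] == levels[1]]
    if continuous is None:
        continuous = [
            c
            for c in participants.columns
            if c not in (by, "participant_id")
            and pd.api.types.is_numeric_dtype(participants[c])
        ]
    categorical = categorical or []
    rows = []
    for m in continuous:
        a = g0[m].dropna().to_numpy(dtype=float)
        b = g1[m].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("group_compare: skipping %s (group too small)", m)
            continue
        normal = (
            stats.shapiro(a).pvalue > 0.05
            and stats.shapiro(b).pvalue > 0.05
            and a.std() > 0
            and b.std() > 0
        )
        if normal:
            res = stats.ttest_ind(a, b)
            test = "t"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mannwhitney"
        rows.append(
            {
                "measure": m,
                "test": test,
                "statistic": float(res.statistic),
                "pvalue": float(res.pvalue),
            }
        )
    for m in categorical:
        tab = pd.crosstab(participants[by], participants[m])
        if tab.shape[1] < 2:
            logger.warning("group_compare: skipping %s (single level)", m)
            continue
        chi2, p, _, _ = stats.chi2_contingency(tab)
        rows.append(
            {"measure": m, "test": "chi2", "statistic": float(chi2), "pvalue": float(p)}
        )
    return pd.DataFrame(rows, columns=["measure", "test", "statistic", "pvalue"])
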