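"""z-adjustment, mixed/robust fits, Holm correction, effect sizes, group tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import tabletbio as tb
from tabletbio.io import SessionError


# --- z-adjustment ------------------------------------------------------------


def norms_for(measure="coding", mean=30.0, sd=5.0):
    rows = [
        {"measure": measure, "sex": sex, "age_lo": 7.0, "age_hi": 15.0,
         "mean": mean, "sd": sd}
        for sex in ("girl", "boy")
    ]
    return tb.NormativeTable(pd.DataFrame(rows))


def participant(raw, pid="p1", age=10.0, sex="girl", measure="coding"):
    return tb.ParticipantRecord(
        participant_id=pid, age=age, sex=sex, raw_scores={measure: raw}
    )


def test_z_adjust_mean_and_sd_units():
    norms = norms_for(mean=30, sd=5)
    adj = tb.z_adjust([participant(30.0), participant(35.0, pid="p2")], norms)
    assert adj.loc["p1", "coding"] == pytest.approx(0.0)
    assert adj.loc["p2", "coding"] == pytest.approx(1.0)


def test_z_adjust_missing_cell_is_error():
    norms = norms_for(measure="coding")
    with pytest.raises(SessionError, match="digit_span"):
        tb.z_adjust([participant(10.0, measure="digit_span")], norms)


# --- Holm-Bonferroni ---------------------------------------------------------


def oracle_holm(p):
    """Brute-force evaluation of the step-down definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank, j in enumerate(order):
        adj[j] = max(
            min(1.0, (m - r) * p[order[r]]) for r in range(rank + 1)
        )
    return adj


def test_holm_hand_example():
    adj, reject = tb.holm_bonferroni([0.01, 0.03, 0.04], alpha=0.05)
    np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])
    assert list(reject) == [True, False, False]


def test_holm_trivial_cases():
    adj, reject = tb.holm_bonferroni([0.2])
    assert adj[0] == pytest.approx(0.2)
    adj, reject = tb.holm_bonferroni([1.0, 1.0, 1.0])
    assert (adj == 1.0).all() and not reject.any()
    with pytest.raises(ValueError):
        tb.holm_bonferroni([0.5, 1.5])


def test_holm_matches_bruteforce_and_statsmodels():
    """Equivalence with the step-down definition and with the library
    implementation on 1,000 random p-vectors; adjusted >= raw always."""
    rng = np.random.default_rng(17)
    for _ in range(1000):
        m = int(rng.integers(1, 12))
        p = rng.uniform(0, 1, m)
        adj, reject = tb.holm_bonferroni(p)
        np.testing.assert_allclose(adj, oracle_holm(p), atol=1e-12)
        assert (adj >= p - 1e-15).all()
        sm_reject, sm_adj, _, _ = multipletests(p, alpha=0.05, method="holm")
        np.testing.assert_allclose(adj, sm_adj, atol=1e-12)
        assert (reject == sm_reject).all()


# --- Cohen's D ---------------------------------------------------------------


def test_cohens_d_definition():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 500)
    assert tb.cohens_d(a, a) == pytest.approx(0.0)
    b = rng.normal(0, 1, 400)
    assert tb.cohens_d(a + 1.0, b) == pytest.approx(1.0, abs=0.2)
    with pytest.raises(ValueError):
        tb.cohens_d(np.ones(5), np.ones(5))


def test_cohens_d_recovers_programmed_shift():
    rng = np.random.default_rng(6)
    a = rng.normal(0.5, 1.0, 200)
    b = rng.normal(0.0, 1.0, 200)
    assert tb.cohens_d(a, b) == pytest.approx(0.5, abs=0.15)


# --- mixed and robust fits ---------------------------------------------------


@pytest.fixture(scope="module")
def scores_and_rng(connect_scores):
    _, scores = connect_scores
    return scores, np.random.default_rng(12)


def row_target(scores, rng, beta1=0.8, ch_sd=0.5, noise_sd=1.0):
    idx = scores.scores.index
    ch = idx.get_level_values("challenge_index").to_numpy()
    intercepts = {c: rng.normal(0, ch_sd) for c in np.unique(ch)}
    y = (
        beta1 * scores.scores["MBC1"].to_numpy()
        + np.array([intercepts[c] for c in ch])
        + rng.normal(0, noise_sd, len(idx))
    )
    return pd.Series(y, index=idx, name="target")


def test_mixed_fit_recovers_known_coefficient(scores_and_rng):
    scores, rng = scores_and_rng
    covered = 0
    for _ in range(30):
        res = tb.fit_mixed(scores, row_target(scores, rng))
        lo, hi = res.conf_int["MBC1"]
        covered += lo <= 0.8 <= hi
    assert covered >= 25


def test_mixed_fit_reports_variances_and_fit_stats(scores_and_rng):
    scores, rng = scores_and_rng
    res = tb.fit_mixed(scores, row_target(scores, rng))
    assert res.random_effect_variance >= 0
    assert res.residual_variance > 0
    assert np.isfinite(res.log_likelihood)
    assert 0 <= res.r_squared <= 1
    assert set(res.pvalues) == {"const", "MBC1", "MBC2", "MBC3"}
    assert all(0 <= p <= 1 for p in res.pvalues.values())


def test_mixed_fit_zero_challenge_effect_boundary(scores_and_rng):
    """With no true challenge effect the random-intercept variance
    estimate sits near the boundary."""
    scores, rng = scores_and_rng
    ratios = []
    for _ in range(20):
        res = tb.fit_mixed(scores, row_target(scores, rng, ch_sd=0.0))
        ratios.append(res.random_effect_variance / res.residual_variance)
    assert np.median(ratios) <= 0.05


def test_robust_agrees_with_mixed_on_clean_data(scores_and_rng):
    scores, rng = scores_and_rng
    y = row_target(scores, rng, ch_sd=0.0, noise_sd=0.1)
    mixed = tb.fit_mixed(scores, y)
    robust = tb.fit_robust(scores, y)
    assert robust.estimates["MBC1"] == pytest.approx(
        mixed.estimates["MBC1"], rel=0.05
    )


def test_robust_resists_gross_outliers(scores_and_rng):
    """With 10% gross outliers the Huber fit stays closer to the truth
    than the mixed (least-squares) fit in most repeats."""
    scores, rng = scores_and_rng
    wins = 0
    n_rep = 30
    for _ in range(n_rep):
        y = row_target(scores, rng, ch_sd=0.0, noise_sd=0.5)
        n_out = max(1, len(y) // 10)
        pos = rng.choice(len(y), n_out, replace=False)
        y.iloc[pos] += rng.choice([-1, 1], n_out) * 25.0
        err_rob = abs(tb.fit_robust(scores, y).estimates["MBC1"] - 0.8)
        err_ols = abs(tb.fit_mixed(scores, y).estimates["MBC1"] - 0.8)
        wins += err_rob < err_ols
    assert wins >= int(0.75 * n_rep)


def test_constant_target_gives_zero_coefficients(scores_and_rng):
    scores, _ = scores_and_rng
    y = pd.Series(1.0, index=scores.scores.index, name="const_target")
    res = tb.fit_robust(scores, y)
    for c in ("MBC1", "MBC2", "MBC3"):
        assert res.estimates[c] == pytest.approx(0.0, abs=1e-8)


# --- grids and group comparisons ---------------------------------------------


def test_association_grid_full_shape(connect_scores, small_cohort):
    """The full measures x components grid fits without error and Holm
    correction is applied across the whole game family."""
    _, scores = connect_scores
    cohort, _ = small_cohort
    adjusted = tb.z_adjust(cohort.participants, cohort.norms)
    table, results = tb.association_grid(scores, adjusted, flavour="mixed")
    assert len(table) == len(adjusted.columns) * 3
    ok = table["pvalue"].notna()
    assert ok.sum() >= 0.8 * len(table)  # singular small-sample fits may drop out
    assert (table.loc[ok, "pvalue_holm"] >= table.loc[ok, "pvalue"] - 1e-12).all()
    assert table.loc[ok, "pvalue"].between(0, 1).all()
    rob, _ = tb.association_grid(scores, adjusted, flavour="robust")
    assert len(rob) == len(table)


def test_group_compare_detects_separated_groups():
    rng = np.random.default_rng(23)
    n = 30
    df = pd.DataFrame(
        {
            "sex": ["girl"] * n + ["boy"] * n,
            "coding": np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)]),
            "vocabulary": rng.normal(0, 1, 2 * n),
        }
    )
    out = tb.group_compare(df, by="sex")
    assert out.set_index("measure").loc["coding", "pvalue"] < 0.05
    assert set(out["test"]).issubset({"t", "mannwhitney"})


def test_group_compare_null_calibration():
    rng = np.random.default_rng(29)
    hits = 0
    n_sims = 60
    for _ in range(n_sims):
        df = pd.DataFrame(
            {
                "sex": ["girl"] * 50 + ["boy"] * 50,
                "coding": rng.normal(0, 1, 100),
            }
        )
        out = tb.group_compare(df, by="sex")
        hits += out["pvalue"].iloc[0] > 0.05
    assert hits >= int(0.9 * n_sims)


def test_group_compare_categorical_and_degenerate(caplog):
    import logging

    df = pd.DataFrame(
        {
            "sex": ["girl"] * 20 + ["boy"] * 20,
            "handed": ["right"] * 15 + ["left"] * 5 + ["right"] * 10 + ["left"] * 10,
            "single": ["x"] * 40,
        }
    )
    out = tb.group_compare(df, by="sex", continuous=[], categorical=["handed"])
    assert out.loc[0, "test"] == "chi2"
    with caplog.at_level(logging.WARNING, logger="tabletbio"):
        out2 = tb.group_compare(df, by="sex", continuous=[], categorical=["single"])
    assert len(out2) == 0
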